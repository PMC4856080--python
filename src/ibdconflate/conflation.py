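"""Conflation of nearby true IBD segments.

Two IBD segments of one diploid pair, each at least ``w`` cM long and
separated by at most ``max_gap`` cM, jointly span an end-to-end stretch that
an IBS-based caller would report as a single IBD segment once that stretch
reaches the calling threshold (1 cM by default).  This module detects such
conflation events, classifies them *cis* (both segments on the same two
haplotypes) or *trans* (three or four haplotypes involved), computes their
rate, compares it against a permutation null in which segments are placed
independently and uniformly, and builds the biased "apparent" length
distribution in which each conflated pair is counted at its merged length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import DEFAULT_MAP, GeneticMap
from .true_ibd import IBDSegment, _as_frame, frame_to_segments

__all__ = [
    "ConflationEvent",
    "LengthHistogram",
    "find_conflation_events",
    "classify_phase",
    "conflation_rate",
    "permutation_null",
    "apparent_length_distribution",
    "write_events",
]


@dataclass(frozen=True)
class ConflationEvent:
    """An unordered pair of nearby IBD segments of one diploid pair.

    ``seg1`` starts at or before ``seg2``.  ``gap_cm`` is zero when the two
    segments overlap; ``combined_cm`` is the end-to-end span.  ``idx1`` and
    ``idx2`` are the positions of the two segments in the input collection.
    """

    seg1: IBDSegment
    seg2: IBDSegment
    idx1: int
    idx2: int
    gap_cm: float
    combined_cm: float
    phase_class: str

    def __post_init__(self) -> None:
        if self.seg1.diploid_pair != self.seg2.diploid_pair:
            raise ValueError("both segments must belong to one diploid pair")


def classify_phase(event_or_segments) -> str:
    """Classify a conflation event as ``cis`` or ``trans``.

    *cis*: both segments are shared by the same two haplotypes (so the two
    segments descend from recent but different common ancestors of the same
    haplotype pair).  *trans*: the union of haplotypes involves three or
    four of the four possible haplotypes of the diploid pair.
    """
    if isinstance(event_or_segments, ConflationEvent):
        s1, s2 = event_or_segments.seg1, event_or_segments.seg2
    else:
        s1, s2 = event_or_segments
    if s1.diploid_pair != s2.diploid_pair:
        raise ValueError("segments belong to different diploid pairs")
    return "cis" if {s1.hap_a, s1.hap_b} == {s2.hap_a, s2.hap_b} else "trans"


def _event_scan(
    pair_key: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    length: np.ndarray,
    w: float,
    max_gap: float,
    min_combined: float,
):
    """All qualifying unordered segment pairs, as index pairs.

    Segments are scanned in (pair, start) order; because starts are sorted
    within a pair, candidates for segment i are exactly the following
    segments whose start lies within ``end_i + max_gap``.
    """
    order = np.lexsort((start, pair_key))
    pk = pair_key[order]
    st = start[order]
    en = end[order]
    ln = length[order]
    out_i: list[int] = []
    out_j: list[int] = []
    gaps: list[float] = []
    combined: list[float] = []
    n = len(order)
    for a in range(n):
        lim = en[a] + max_gap
        for b in range(a + 1, n):
            if pk[b] != pk[a] or st[b] > lim + 1e-12:
                break
            if ln[a] < w - 1e-12 or ln[b] < w - 1e-12:
                continue
            comb = max(en[a], en[b]) - st[a]
            if comb < min_combined - 1e-12:
                continue
            out_i.append(order[a])
            out_j.append(order[b])
            gaps.append(max(0.0, st[b] - en[a]))
            combined.append(comb)
    return (
        np.asarray(out_i, dtype=np.int64),
        np.asarray(out_j, dtype=np.int64),
        np.asarray(gaps),
        np.asarray(combined),
    )


def find_conflation_events(
    segments,
    w_cm: float = 0.2,
    max_gap_cm: float = 0.0,
    min_combined_cm: float = 1.0,
    include_within_individual: bool = False,
    genmap: GeneticMap = DEFAULT_MAP,
) -> list[ConflationEvent]:
    """Detect all conflation events among ``segments``.

    Every unordered pair of segments of one diploid pair with both lengths
    >= ``w_cm``, gap <= ``max_gap_cm`` and end-to-end span >=
    ``min_combined_cm`` is returned exactly once.  Chains of three or more
    mutually close segments contribute every qualifying pair.  Segments
    shared within one individual are excluded by default.
    """
    if w_cm < 0 or max_gap_cm < 0:
        raise ValueError("w_cm and max_gap_cm must be non-negative")
    frame = _as_frame(segments)
    if not len(frame):
        return []
    if not include_within_individual:
        frame = frame[frame["ind_a"] != frame["ind_b"]]
    if not len(frame):
        return []
    frame = frame.reset_index(drop=True)
    lo = np.minimum(frame["ind_a"], frame["ind_b"]).to_numpy()
    hi = np.maximum(frame["ind_a"], frame["ind_b"]).to_numpy()
    pair_key = lo * (hi.max() + 1) + hi
    start_cm = np.asarray(genmap.bp_to_cm(frame["start_bp"].to_numpy(float)))
    end_cm = np.asarray(genmap.bp_to_cm(frame["end_bp"].to_numpy(float)))
    length_cm = frame["length_cm"].to_numpy(float)
    ii, jj, gaps, comb = _event_scan(
        pair_key,
        start_cm,
        end_cm,
        length_cm,
        w_cm,
        max_gap_cm,
        min_combined_cm,
    )
    segs = frame_to_segments(frame)
    events = []
    for i, j, g, c in zip(ii, jj, gaps, comb):
        s1, s2 = segs[i], segs[j]
        events.append(
            ConflationEvent(
                seg1=s1,
                seg2=s2,
                idx1=int(i),
                idx2=int(j),
                gap_cm=round(float(g), 9),
                combined_cm=round(float(c), 9),
                phase_class=classify_phase((s1, s2)),
            )
        )
    return events


def conflation_rate(
    events, n_diploids: int, total_region_mb: float
) -> float:
    """Conflation events per 1000 pairs of individuals per 100 Mb."""
    if n_diploids < 2:
        raise ValueError("need at least two diploids")
    if total_region_mb <= 0:
        raise ValueError("total_region_mb must be positive")
    n_events = len(events) if not np.isscalar(events) else int(events)
    n_pairs = n_diploids * (n_diploids - 1) // 2
    return n_events / n_pairs / (total_region_mb / 100.0) * 1000.0


@dataclass
class PermutationResult:
    """Null distribution of conflation under independent placement."""

    rates: np.ndarray            # per replicate, per 1000 pairs per 100 Mb
    n_events: np.ndarray         # raw event counts per replicate
    cis_counts: np.ndarray
    trans_counts: np.ndarray

    @property
    def cis_fraction(self) -> float:
        tot = self.cis_counts.sum() + self.trans_counts.sum()
        return float(self.cis_counts.sum() / tot) if tot else np.nan


def permutation_null(
    segments,
    region_length_bp: float,
    n_diploids: int,
    n_reps: int = 100,
    rng: np.random.Generator | None = None,
    w_cm: float = 0.2,
    max_gap_cm: float = 0.0,
    min_combined_cm: float = 1.0,
    genmap: GeneticMap = DEFAULT_MAP,
) -> PermutationResult:
    """Conflation rates when segments are placed independently at random.

    Each replicate resamples the observed segment lengths with replacement,
    assigns every segment a uniform start position, two uniformly chosen
    distinct individuals, and one uniformly chosen haplotype within each,
    then recomputes the conflation rate.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    frame = _as_frame(segments)
    lengths_bp = (frame["end_bp"] - frame["start_bp"]).to_numpy(float)
    if np.any(lengths_bp > region_length_bp):
        raise ValueError("segment longer than the region")
    n_seg = len(lengths_bp)
    region_cm = float(genmap.bp_to_cm(region_length_bp))
    seg_cm = np.asarray(genmap.bp_to_cm(lengths_bp))
    rates = np.empty(n_reps)
    counts = np.empty(n_reps, dtype=np.int64)
    cis = np.empty(n_reps, dtype=np.int64)
    trans = np.empty(n_reps, dtype=np.int64)
    total_mb = region_length_bp / 1e6
    for rep in range(n_reps):
        pick = rng.integers(0, n_seg, size=n_seg)
        ln = seg_cm[pick]
        st = rng.random(n_seg) * (region_cm - ln)
        en = st + ln
        ia = rng.integers(0, n_diploids, size=n_seg)
        ib = rng.integers(0, n_diploids - 1, size=n_seg)
        ib = np.where(ib >= ia, ib + 1, ib)
        lo = np.minimum(ia, ib)
        hi = np.maximum(ia, ib)
        hap_a = 2 * lo + rng.integers(0, 2, size=n_seg)
        hap_b = 2 * hi + rng.integers(0, 2, size=n_seg)
        pair_key = lo.astype(np.int64) * n_diploids + hi
        ii, jj, _, _ = _event_scan(
            pair_key, st, en, ln, w_cm, max_gap_cm, min_combined_cm
        )
        counts[rep] = len(ii)
        is_cis = (hap_a[ii] == hap_a[jj]) & (hap_b[ii] == hap_b[jj])
        cis[rep] = int(is_cis.sum())
        trans[rep] = counts[rep] - cis[rep]
        rates[rep] = conflation_rate(int(counts[rep]), n_diploids, total_mb)
    return PermutationResult(rates=rates, n_events=counts, cis_counts=cis, trans_counts=trans)


@dataclass
class LengthHistogram:
    """True vs apparent IBD length distributions.

    ``true_counts`` histograms every segment at its true length;
    ``apparent_counts`` histograms the collection in which each greedily
    merged conflated pair is replaced by one segment of its combined
    length; ``conflated_counts`` is the subset of apparent counts that are
    merged pairs.
    """

    edges: np.ndarray
    true_counts: np.ndarray
    apparent_counts: np.ndarray
    conflated_counts: np.ndarray

    @property
    def proportion(self) -> np.ndarray:
        """Per-bin fraction of apparent segments that are conflations."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.apparent_counts > 0,
                self.conflated_counts / self.apparent_counts,
                np.nan,
            )

    def proportion_in_range(self, lo_cm: float, hi_cm: float) -> float:
        """Conflated fraction of apparent segments with length in [lo, hi)."""
        sel = (self.edges[:-1] >= lo_cm - 1e-9) & (self.edges[1:] <= hi_cm + 1e-9)
        app = self.apparent_counts[sel].sum()
        if app == 0:
            return np.nan
        return float(self.conflated_counts[sel].sum() / app)

    def proportion_lookup(self, lengths_cm: np.ndarray) -> np.ndarray:
        """Conflation proportion of the bin containing each length (0 outside)."""
        lengths_cm = np.asarray(lengths_cm, dtype=float)
        idx = np.searchsorted(self.edges, lengths_cm, side="right") - 1
        idx = np.clip(idx, 0, len(self.true_counts) - 1)
        prop = np.nan_to_num(self.proportion, nan=0.0)
        out = prop[idx]
        out[(lengths_cm < self.edges[0]) | (lengths_cm >= self.edges[-1])] = 0.0
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low_cm": self.edges[:-1],
                "bin_high_cm": self.edges[1:],
                "true_count": self.true_counts,
                "apparent_count": self.apparent_counts,
                "conflated_count": self.conflated_counts,
                "conflation_prop": self.proportion,
            }
        )

    def write_tsv(self, path, header_lines=()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def read_tsv(cls, path) -> "LengthHistogram":
        frame = pd.read_csv(path, sep="\t", comment="#")
        edges = np.append(
            frame["bin_low_cm"].to_numpy(), frame["bin_high_cm"].iloc[-1]
        )
        return cls(
            edges=edges,
            true_counts=frame["true_count"].to_numpy(),
            apparent_counts=frame["apparent_count"].to_numpy(),
            conflated_counts=frame["conflated_count"].to_numpy(),
        )


def greedy_apparent_lengths(
    segments, events: list[ConflationEvent]
) -> tuple[np.ndarray, np.ndarray]:
    """Apparent lengths under greedy left-to-right merging of events.

    Returns ``(lengths_cm, is_conflated)``: merged pairs contribute one
    length (their combined span, flagged True), every unmerged segment its
    true length.  Each segment participates in at most one merge.
    """
    frame = _as_frame(segments)
    lengths = frame["length_cm"].to_numpy(float)
    used = np.zeros(len(frame), dtype=bool)
    merged_lengths = []
    order = sorted(
        events, key=lambda e: (e.seg1.diploid_pair, e.seg1.start_bp, e.seg2.start_bp)
    )
    for ev in order:
        if used[ev.idx1] or used[ev.idx2]:
            continue
        used[ev.idx1] = True
        used[ev.idx2] = True
        merged_lengths.append(ev.combined_cm)
    merged = np.asarray(merged_lengths)
    out = np.concatenate([lengths[~used], merged])
    flags = np.concatenate(
        [np.zeros(int((~used).sum()), dtype=bool), np.ones(len(merged), dtype=bool)]
    )
    return out, flags


def apparent_length_distribution(
    segments,
    events: list[ConflationEvent],
    bin_width_cm: float = 0.1,
) -> LengthHistogram:
    """Histogram of apparent lengths under greedy left-to-right merging.

    Events are consumed in genomic order; each segment participates in at
    most one merged apparent segment, so the apparent collection is a
    proper (smaller or equal) set of counts.  Unmerged segments contribute
    their true length.
    """
    frame = _as_frame(segments)
    lengths = frame["length_cm"].to_numpy(float)
    apparent, flags = greedy_apparent_lengths(segments, events)
    merged_lengths = apparent[flags]
    all_vals = np.concatenate([lengths, merged_lengths]) if len(merged_lengths) else lengths
    lo = np.floor(lengths.min() / bin_width_cm) * bin_width_cm if len(lengths) else 0.0
    hi = np.ceil((all_vals.max() + 1e-9) / bin_width_cm) * bin_width_cm if len(all_vals) else bin_width_cm
    edges = np.round(np.arange(lo, hi + bin_width_cm / 2, bin_width_cm), 9)
    true_counts, _ = np.histogram(lengths, bins=edges)
    apparent_single, _ = np.histogram(apparent[~flags], bins=edges)
    conflated_counts, _ = np.histogram(merged_lengths, bins=edges)
    return LengthHistogram(
        edges=edges,
        true_counts=true_counts,
        apparent_counts=apparent_single + conflated_counts,
        conflated_counts=conflated_counts,
    )


def write_events(path, events: list[ConflationEvent], header_lines=()) -> None:
    """Write conflation events as a tab-delimited table."""
    rows = [
        (
            e.seg1.diploid_pair[0],
            e.seg1.diploid_pair[1],
            e.seg1.start_bp,
            e.seg1.end_bp,
            e.seg2.start_bp,
            e.seg2.end_bp,
            e.gap_cm,
            e.combined_cm,
            e.phase_class,
        )
        for e in events
    ]
    frame = pd.DataFrame(
        rows,
        columns=[
            "ind_a",
            "ind_b",
            "seg1_start_bp",
            "seg1_end_bp",
            "seg2_start_bp",
            "seg2_end_bp",
            "gap_cm",
            "combined_cm",
            "phase_class",
        ],
    )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6f")
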