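"""Comparison of called IBD segments against ground truth.

Parsers for the output of two widely used IBD callers (Refined IBD ``.ibd``
and GERMLINE ``.match`` files), a minimal seed-and-extend haploid IBS
matcher so the comparison pipeline can be exercised without external tools,
and the decomposition of each called segment into its overlapping true
subsegments: the longest intersecting true segment, the extension of the
call beyond it attributable to other subsegments of at least 0.2 cM
(conflation), and the residual unattributed length (minor endpoint error).

Reference caller settings for error-free simulated array data (recorded
for provenance, not executed here): Refined IBD with ibdtrim/overlap set
to the marker count of 0.15 / 1.5 cM windows and LOD >= 3; GERMLINE v1.5.1
with -bits 32, -err_hom 0 -err_het 0, -min_m 1 and haploid extension;
fastIBD with ten combined runs; IBDLD with -method GIBDLD -length 1000.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .demography import ArrayDataset
from .genmap import DEFAULT_MAP, GeneticMap
from .true_ibd import IBDSegment, _as_frame

__all__ = [
    "CalledSegment",
    "CompositionRecord",
    "ConflationSummary",
    "read_refined_ibd",
    "read_germline_match",
    "simple_ibs_caller",
    "decompose_called",
    "summarize_conflation",
    "trim_and_summarize",
    "write_composition_records",
]

#: Length bins (cM) used for the stratified summaries.
SUMMARY_BINS = (1.0, 1.2, 1.4, 1.6, 1.8, 2.0, 2.2, 20.0)


@dataclass(frozen=True)
class CalledSegment:
    """A segment reported by an IBD caller between two individuals."""

    ind_a: str
    ind_b: str
    start_bp: int
    end_bp: int
    length_cm: float
    source: str = "unknown"
    score: float | None = None

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError("end_bp must exceed start_bp")

    @property
    def pair_key(self) -> tuple[str, str]:
        a, b = str(self.ind_a), str(self.ind_b)
        return (a, b) if a <= b else (b, a)


def _parse_error(path, lineno, msg):
    raise ValueError(f"{path}:{lineno}: {msg}")


def read_refined_ibd(path, genmap: GeneticMap = DEFAULT_MAP) -> list[CalledSegment]:
    """Parse Refined IBD output.

    Columns: sample1, hap1, sample2, hap2, chrom, start, end, LOD.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 8:
                _parse_error(path, lineno, f"expected 8 columns, got {len(parts)}")
            try:
                start, end = int(parts[5]), int(parts[6])
                lod = float(parts[7])
            except ValueError as exc:
                _parse_error(path, lineno, f"bad numeric field: {exc}")
            out.append(
                CalledSegment(
                    ind_a=parts[0],
                    ind_b=parts[2],
                    start_bp=start,
                    end_bp=end,
                    length_cm=float(genmap.bp_to_cm(end - start)),
                    source="refined_ibd",
                    score=lod,
                )
            )
    return out


def read_germline_match(path, genmap: GeneticMap = DEFAULT_MAP) -> list[CalledSegment]:
    """Parse a GERMLINE ``.match`` file.

    Columns: fam1, ind1, fam2, ind2, chrom, start, end, startSNP, endSNP,
    totalSNP, dist, unit, mismatches, hom1, hom2.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 15:
                _parse_error(path, lineno, f"expected 15 columns, got {len(parts)}")
            try:
                start, end = int(parts[5]), int(parts[6])
            except ValueError as exc:
                _parse_error(path, lineno, f"bad numeric field: {exc}")
            out.append(
                CalledSegment(
                    ind_a=parts[1],
                    ind_b=parts[3],
                    start_bp=start,
                    end_bp=end,
                    length_cm=float(genmap.bp_to_cm(end - start)),
                    source="germline",
                )
            )
    return out


def simple_ibs_caller(
    array: ArrayDataset,
    min_length_cm: float = 1.0,
    seed_markers: int = 32,
    genmap: GeneticMap | None = None,
) -> list[CalledSegment]:
    """Minimal seed-and-extend haploid IBS matcher.

    Haplotype pairs sharing an exact match across a window of
    ``seed_markers`` consecutive markers are extended marker-by-marker in
    both directions; maximal identical stretches spanning at least
    ``min_length_cm`` are projected onto diploid pairs.  Requires phased
    data.  This is deliberately simple — a stand-in for dictionary-based
    callers so the decomposition pipeline is testable end to end.
    """
    if not array.phased:
        raise ValueError("the IBS matcher requires phased haplotypes")
    genmap = genmap or array.genmap
    H = array.haplotypes
    pos = array.positions
    n_mark, n_hap = H.shape
    if n_mark == 0:
        return []
    # seed windows -> candidate haplotype pairs
    candidates: set[tuple[int, int]] = set()
    windows: dict[tuple[int, int], set[int]] = {}
    for w0 in range(0, n_mark, seed_markers):
        block = H[w0 : w0 + seed_markers]
        buckets: dict[bytes, list[int]] = {}
        for hap in range(n_hap):
            buckets.setdefault(block[:, hap].tobytes(), []).append(hap)
        for haps in buckets.values():
            for i in range(len(haps)):
                for j in range(i + 1, len(haps)):
                    pair = (haps[i], haps[j])
                    candidates.add(pair)
                    windows.setdefault(pair, set()).add(w0)
    out = []
    min_bp = float(genmap.cm_to_bp(min_length_cm))
    for (a, b) in sorted(candidates):
        eq = H[:, a] == H[:, b]
        # maximal runs of equality covering at least one seed window
        runs = []
        start = None
        for idx in range(n_mark):
            if eq[idx] and start is None:
                start = idx
            elif not eq[idx] and start is not None:
                runs.append((start, idx))
                start = None
        if start is not None:
            runs.append((start, n_mark))
        for lo, hi in runs:
            covers_seed = any(
                lo <= w0 and hi >= min(w0 + seed_markers, n_mark)
                for w0 in windows[(a, b)]
            )
            if not covers_seed:
                continue
            span = int(pos[hi - 1]) + 1 - int(pos[lo])
            if span < min_bp:
                continue
            ia, ib = int(array.pairing[a]), int(array.pairing[b])
            if ia == ib:
                continue
            out.append(
                CalledSegment(
                    ind_a=str(min(ia, ib)),
                    ind_b=str(max(ia, ib)),
                    start_bp=int(pos[lo]),
                    end_bp=int(pos[hi - 1]) + 1,
                    length_cm=float(genmap.bp_to_cm(span)),
                    source="ibs",
                )
            )
    # collapse duplicate diploid-pair intervals from multiple hap configs
    seen = set()
    unique = []
    for seg in out:
        key = (seg.pair_key, seg.start_bp, seg.end_bp)
        if key not in seen:
            seen.add(key)
            unique.append(seg)
    return unique


@dataclass
class CompositionRecord:
    """Decomposition of one called segment into true subsegments.

    ``overlap_cm`` is the called-interval overlap of the longest
    intersecting true segment; ``extension_cm`` the flanking called length
    covered by other qualifying subsegments (>= ``min_sub_cm``, not fully
    inside the longest's span); ``endpoint_error_cm`` the rest.  The three
    parts sum to the called length.
    """

    called: CalledSegment
    longest: IBDSegment | None
    second: IBDSegment | None
    n_subsegments: int
    overlap_cm: float
    extension_cm: float
    endpoint_error_cm: float

    @property
    def conflated(self) -> bool:
        return self.n_subsegments >= 2

    @property
    def extended(self) -> bool:
        return self.extension_cm >= 0.2 - 1e-12


def _interval_overlap(a_lo, a_hi, b_lo, b_hi):
    return max(0.0, min(a_hi, b_hi) - max(a_lo, b_lo))


def decompose_called(
    called: Sequence[CalledSegment],
    true_segments,
    min_sub_cm: float = 0.2,
    clip: bool = True,
    genmap: GeneticMap = DEFAULT_MAP,
) -> list[CompositionRecord]:
    """Decompose each called segment into overlapping true subsegments.

    Subsegments are ranked by overlap with the called interval (ties:
    earlier start, then older TMRCA).  A subsegment qualifies if its
    (clipped, unless ``clip=False``) length is at least ``min_sub_cm`` and
    it is not fully contained within the longest subsegment's span — a
    fully overlapped second segment (possible through the other haplotype
    configuration of a diploid pair) cannot mislead a caller.  A record is
    conflated when two or more subsegments qualify.
    """
    frame = _as_frame(true_segments)
    by_pair: dict[tuple[str, str], list] = {}
    for row in frame.itertuples(index=False):
        a, b = str(row.ind_a), str(row.ind_b)
        key = (a, b) if a <= b else (b, a)
        by_pair.setdefault(key, []).append(row)
    records = []
    for seg in called:
        c_lo, c_hi = float(seg.start_bp), float(seg.end_bp)
        subs = []
        for row in by_pair.get(seg.pair_key, ()):
            ov = _interval_overlap(c_lo, c_hi, row.start_bp, row.end_bp)
            if ov > 0:
                subs.append((ov, row))
        if not subs:
            records.append(
                CompositionRecord(
                    called=seg,
                    longest=None,
                    second=None,
                    n_subsegments=0,
                    overlap_cm=0.0,
                    extension_cm=0.0,
                    endpoint_error_cm=seg.length_cm,
                )
            )
            continue
        subs.sort(key=lambda t: (-t[0], t[1].start_bp, -t[1].tmrca_gen))
        best_ov, best = subs[0]
        best_lo = max(c_lo, best.start_bp)
        best_hi = min(c_hi, best.end_bp)
        qualifying = []
        second = None
        for ov, row in subs[1:]:
            lo = max(c_lo, row.start_bp)
            hi = min(c_hi, row.end_bp)
            fully_inside = lo >= best_lo and hi <= best_hi
            measured = ov if clip else (row.end_bp - row.start_bp)
            if fully_inside:
                continue
            if second is None:
                second = row
            if float(genmap.bp_to_cm(measured)) >= min_sub_cm - 1e-12:
                qualifying.append((lo, hi))
        # extension: flank coverage by qualifying other subsegments
        ext_bp = 0.0
        for f_lo, f_hi in ((c_lo, best_lo), (best_hi, c_hi)):
            if f_hi <= f_lo:
                continue
            ivs = sorted(
                (max(f_lo, lo), min(f_hi, hi))
                for lo, hi in qualifying
                if min(f_hi, hi) > max(f_lo, lo)
            )
            cur_lo, cur_hi = None, None
            for lo, hi in ivs:
                if cur_lo is None:
                    cur_lo, cur_hi = lo, hi
                elif lo <= cur_hi:
                    cur_hi = max(cur_hi, hi)
                else:
                    ext_bp += cur_hi - cur_lo
                    cur_lo, cur_hi = lo, hi
            if cur_lo is not None:
                ext_bp += cur_hi - cur_lo
        overlap_cm = float(genmap.bp_to_cm(best_ov))
        extension_cm = float(genmap.bp_to_cm(ext_bp))
        n_quality = len(qualifying) + (
            1 if float(genmap.bp_to_cm(best_ov if clip else best.end_bp - best.start_bp)) >= min_sub_cm - 1e-12 else 0
        )
        longest_seg = IBDSegment(
            int(best.hap_a),
            int(best.hap_b),
            int(best.ind_a),
            int(best.ind_b),
            int(best.start_bp),
            int(best.end_bp),
            float(best.length_cm),
            float(best.tmrca_gen),
        )
        second_seg = None
        if second is not None:
            second_seg = IBDSegment(
                int(second.hap_a),
                int(second.hap_b),
                int(second.ind_a),
                int(second.ind_b),
                int(second.start_bp),
                int(second.end_bp),
                float(second.length_cm),
                float(second.tmrca_gen),
            )
        records.append(
            CompositionRecord(
                called=seg,
                longest=longest_seg,
                second=second_seg,
                n_subsegments=n_quality,
                overlap_cm=overlap_cm,
                extension_cm=extension_cm,
                endpoint_error_cm=max(0.0, seg.length_cm - overlap_cm - extension_cm),
            )
        )
    return records


@dataclass
class ConflationSummary:
    """Aggregate decomposition statistics."""

    n_records: int
    prop_conflated: float
    prop_extended: float
    mean_extension_when_extended: float
    by_length_bin: pd.DataFrame = field(repr=False, default=None)


def summarize_conflation(records: Sequence[CompositionRecord]) -> ConflationSummary:
    """Summary over records, stratified into the standard 7 length bins."""
    if not len(records):
        raise ValueError("no records to summarize")
    ext = np.array([r.extension_cm for r in records])
    err = np.array([r.endpoint_error_cm for r in records])
    lengths = np.array([r.called.length_cm for r in records])
    conflated = np.array([r.conflated for r in records])
    extended = np.array([r.extended for r in records])
    rows = []
    edges = SUMMARY_BINS
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (lengths >= lo) & (lengths < hi)
        rows.append(
            (
                lo,
                hi,
                int(sel.sum()),
                float(conflated[sel].mean()) if sel.any() else np.nan,
                float(ext[sel].mean()) if sel.any() else np.nan,
                float(err[sel].mean()) if sel.any() else np.nan,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "bin_low_cm",
            "bin_high_cm",
            "n",
            "prop_conflated",
            "mean_extension_cm",
            "mean_endpoint_error_cm",
        ],
    )
    return ConflationSummary(
        n_records=len(records),
        prop_conflated=float(conflated.mean()),
        prop_extended=float(extended.mean()),
        mean_extension_when_extended=(
            float(ext[extended].mean()) if extended.any() else 0.0
        ),
        by_length_bin=table,
    )


def trim_and_summarize(
    called: Sequence[CalledSegment],
    true_segments,
    trim_cm: float = 0.1,
    min_sub_cm: float = 0.2,
    clip: bool = True,
    genmap: GeneticMap = DEFAULT_MAP,
) -> ConflationSummary:
    """Trim ``trim_cm`` off both ends of each call, then decompose.

    Calls not longer than twice the trim are dropped with a warning.
    """
    trim_bp = float(genmap.cm_to_bp(trim_cm))
    trimmed = []
    dropped = 0
    for seg in called:
        new_lo = seg.start_bp + trim_bp
        new_hi = seg.end_bp - trim_bp
        if new_hi <= new_lo:
            dropped += 1
            continue
        trimmed.append(
            CalledSegment(
                ind_a=seg.ind_a,
                ind_b=seg.ind_b,
                start_bp=int(round(new_lo)),
                end_bp=int(round(new_hi)),
                length_cm=float(genmap.bp_to_cm(new_hi - new_lo)),
                source=seg.source,
                score=seg.score,
            )
        )
    if dropped:
        warnings.warn(f"dropped {dropped} called segments shorter than 2 x trim")
    records = decompose_called(
        trimmed, true_segments, min_sub_cm=min_sub_cm, clip=clip, genmap=genmap
    )
    return summarize_conflation(records)


def write_composition_records(path, records: Sequence[CompositionRecord], header_lines=()) -> None:
    rows = []
    for r in records:
        rows.append(
            (
                r.called.ind_a,
                r.called.ind_b,
                r.called.start_bp,
                r.called.end_bp,
                r.called.length_cm,
                r.called.source,
                r.n_subsegments,
                r.overlap_cm,
                r.extension_cm,
                r.endpoint_error_cm,
                int(r.conflated),
            )
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "ind_a",
            "ind_b",
            "start_bp",
            "end_bp",
            "length_cm",
            "source",
            "n_subsegments",
            "overlap_cm",
            "extension_cm",
            "endpoint_error_cm",
            "conflated",
        ],
    )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6f")
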