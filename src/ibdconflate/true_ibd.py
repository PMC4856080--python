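"""Ground-truth IBD segment extraction from the simulated genealogies.

A pair of haplotypes is IBD over a stretch of sequence if their time to most
recent common ancestor (TMRCA) is unchanged across that stretch — i.e. no
recombination has occurred on the lineage connecting them since their common
ancestor.  Enumerating these segments exactly over every marginal tree of an
ancestral recombination graph is expensive, so the extractor applies two
tractability approximations:

* the genealogy is sampled only on a regular grid (default every 0.01 cM),
  so segment boundaries are resolved to within one grid step;
* only pairs whose TMRCA is below a maximum age (default 3000 generations)
  are followed, which bounds the number of open segments held in memory.

Segments produced this way are guaranteed to be genuine IBD stretches free
of conflation; very short segments (below ``min_length_cm``) are discarded.

The primary container for large segment sets is a pandas DataFrame with
columns ``hap_a, hap_b, ind_a, ind_b, start_bp, end_bp, length_cm,
tmrca_gen``; :class:`IBDSegment` is the record-level view used by the
conflation and comparison machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tskit

from .demography import SimulatedRegion
from .genmap import DEFAULT_MAP, GeneticMap

__all__ = [
    "IBDSegment",
    "extract_ibd_segments",
    "extract_ibd_table",
    "segments_to_frame",
    "frame_to_segments",
    "ibd_rate",
    "write_segment_table",
    "read_segment_table",
]

SEGMENT_COLUMNS = [
    "hap_a",
    "hap_b",
    "ind_a",
    "ind_b",
    "start_bp",
    "end_bp",
    "length_cm",
    "tmrca_gen",
]


@dataclass(frozen=True)
class IBDSegment:
    """One ground-truth IBD segment between two haplotypes.

    ``hap_a < hap_b`` canonically; ``ind_a``/``ind_b`` are the diploid
    individuals carrying the two haplotypes (equal for within-individual
    sharing).  The interval is 0-based half-open in bp.
    """

    hap_a: int
    hap_b: int
    ind_a: int
    ind_b: int
    start_bp: int
    end_bp: int
    length_cm: float
    tmrca_gen: float

    def __post_init__(self) -> None:
        if self.hap_a >= self.hap_b:
            raise ValueError("hap_a must be < hap_b")
        if self.end_bp <= self.start_bp:
            raise ValueError("end_bp must exceed start_bp")

    @property
    def within_individual(self) -> bool:
        return self.ind_a == self.ind_b

    @property
    def diploid_pair(self) -> tuple[int, int]:
        return (self.ind_a, self.ind_b) if self.ind_a <= self.ind_b else (
            self.ind_b,
            self.ind_a,
        )


def segments_to_frame(segments: Iterable[IBDSegment]) -> pd.DataFrame:
    rows = [
        (
            s.hap_a,
            s.hap_b,
            s.ind_a,
            s.ind_b,
            s.start_bp,
            s.end_bp,
            s.length_cm,
            s.tmrca_gen,
        )
        for s in segments
    ]
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def frame_to_segments(frame: pd.DataFrame) -> list[IBDSegment]:
    return [
        IBDSegment(
            int(r.hap_a),
            int(r.hap_b),
            int(r.ind_a),
            int(r.ind_b),
            int(r.start_bp),
            int(r.end_bp),
            float(r.length_cm),
            float(r.tmrca_gen),
        )
        for r in frame.itertuples(index=False)
    ]


def _as_frame(segments) -> pd.DataFrame:
    if isinstance(segments, pd.DataFrame):
        return segments
    return segments_to_frame(segments)


def _recent_pairs_at(
    tree: tskit.Tree,
    node_time: np.ndarray,
    sample_mask: np.ndarray,
    node_pos: np.ndarray,
    n_hap: int,
    max_age: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sorted pair ids and TMRCAs of all pairs younger than ``max_age``.

    Exploits the postorder layout of the tree: the sample descendants of any
    node form a contiguous block of the postorder sample sequence, and the
    blocks of a node's children partition its own block in order.  Pairs
    whose MRCA is node ``u`` are exactly the cross-child pairs of ``u``.
    """
    post = tree.postorder()
    is_samp = sample_mask[post]
    sample_seq = post[is_samp].astype(np.int64)
    pref = np.cumsum(is_samp)
    node_pos[post] = np.arange(len(post))
    recent = np.flatnonzero((node_time[post] < max_age) & ~is_samp)
    pid_parts: list[np.ndarray] = []
    t_parts: list[np.ndarray] = []
    for p in recent:
        u = int(post[p])
        hi_u = int(pref[p])
        lo_u = hi_u - tree.num_samples(u)
        children = tree.children(u)
        for c in children[1:]:
            pc = int(node_pos[c])
            hi_c = int(pref[pc])
            lo_c = hi_c - tree.num_samples(c)
            left = sample_seq[lo_u:lo_c]
            right = sample_seq[lo_c:hi_c]
            if len(left) == 0 or len(right) == 0:
                continue
            a = np.repeat(left, len(right))
            b = np.tile(right, len(left))
            lo = np.minimum(a, b)
            hi = np.maximum(a, b)
            pid_parts.append(lo * n_hap + hi)
            t_parts.append(np.full(len(a), node_time[u]))
    if not pid_parts:
        return np.empty(0, dtype=np.int64), np.empty(0)
    pids = np.concatenate(pid_parts)
    times = np.concatenate(t_parts)
    order = np.argsort(pids, kind="stable")
    return pids[order], times[order]


def extract_ibd_table(
    region: SimulatedRegion,
    grid_step_cm: float = 0.01,
    max_age_gen: float = 3000.0,
    min_length_cm: float = 0.2,
    genmap: GeneticMap | None = None,
) -> pd.DataFrame:
    """Extract ground-truth IBD segments as a DataFrame.

    For every haplotype pair, maximal runs of consecutive grid points with
    identical TMRCA (below ``max_age_gen``) are emitted as one segment
    spanning from the first grid point of the run to one past the last;
    segments shorter than ``min_length_cm`` are dropped.
    """
    if grid_step_cm <= 0:
        raise ValueError("grid_step_cm must be positive")
    if region.ts.num_trees == 0:
        raise ValueError("region carries no genealogy")
    genmap = genmap or region.genmap
    ts = region.ts
    n_hap = ts.num_samples
    L = ts.sequence_length
    step_bp = float(genmap.cm_to_bp(grid_step_cm))
    # grid points at k * step_bp strictly inside [0, L)
    n_grid = int(np.ceil(L / step_bp - 1e-9))

    node_time = ts.tables.nodes.time
    sample_mask = np.zeros(ts.num_nodes, dtype=bool)
    sample_mask[ts.samples()] = True
    node_pos = np.zeros(ts.num_nodes, dtype=np.int64)

    open_pid = np.empty(0, dtype=np.int64)
    open_time = np.empty(0)
    open_start = np.empty(0, dtype=np.int64)
    out_pid: list[np.ndarray] = []
    out_t: list[np.ndarray] = []
    out_s: list[np.ndarray] = []
    out_e: list[np.ndarray] = []

    tree = tskit.Tree(ts)
    tree.first()
    for g in range(n_grid):
        pos = g * step_bp
        while tree.interval.right <= pos:
            tree.next()
        cur_pid, cur_time = _recent_pairs_at(
            tree, node_time, sample_mask, node_pos, n_hap, max_age_gen
        )
        common, ia, ib = np.intersect1d(
            open_pid, cur_pid, assume_unique=True, return_indices=True
        )
        same = open_time[ia] == cur_time[ib]
        # close runs that ended or changed TMRCA
        closing = np.ones(len(open_pid), dtype=bool)
        closing[ia[same]] = False
        if closing.any():
            out_pid.append(open_pid[closing])
            out_t.append(open_time[closing])
            out_s.append(open_start[closing])
            out_e.append(np.full(int(closing.sum()), g, dtype=np.int64))
        new_start = np.full(len(cur_pid), g, dtype=np.int64)
        new_start[ib[same]] = open_start[ia[same]]
        open_pid, open_time, open_start = cur_pid, cur_time, new_start
    if len(open_pid):
        out_pid.append(open_pid)
        out_t.append(open_time)
        out_s.append(open_start)
        out_e.append(np.full(len(open_pid), n_grid, dtype=np.int64))

    if not out_pid:
        return pd.DataFrame(columns=SEGMENT_COLUMNS)
    pid = np.concatenate(out_pid)
    tmrca = np.concatenate(out_t)
    gs = np.concatenate(out_s)
    ge = np.concatenate(out_e)
    length_cm = (ge - gs) * grid_step_cm
    keep = length_cm >= min_length_cm - 1e-12
    pid, tmrca, gs, ge, length_cm = (
        arr[keep] for arr in (pid, tmrca, gs, ge, length_cm)
    )
    hap_a = pid // n_hap
    hap_b = pid % n_hap
    start_bp = np.round(gs * step_bp).astype(np.int64)
    end_bp = np.minimum(np.round(ge * step_bp), L).astype(np.int64)
    frame = pd.DataFrame(
        {
            "hap_a": hap_a,
            "hap_b": hap_b,
            "ind_a": region.pairing[hap_a],
            "ind_b": region.pairing[hap_b],
            "start_bp": start_bp,
            "end_bp": end_bp,
            "length_cm": length_cm,
            "tmrca_gen": tmrca,
        }
    )
    frame.sort_values(
        ["hap_a", "hap_b", "start_bp"], inplace=True, ignore_index=True
    )
    return frame


def extract_ibd_segments(
    region: SimulatedRegion,
    grid_step_cm: float = 0.01,
    max_age_gen: float = 3000.0,
    min_length_cm: float = 0.2,
    genmap: GeneticMap | None = None,
) -> list[IBDSegment]:
    """Record-level variant of :func:`extract_ibd_table`."""
    return frame_to_segments(
        extract_ibd_table(
            region, grid_step_cm, max_age_gen, min_length_cm, genmap
        )
    )


def ibd_rate(
    segments,
    n_diploids: int,
    total_region_mb: float,
    min_length_cm: float = 1.0,
) -> float:
    """IBD segment rate per pair of individuals per 100 Mb.

    Counts between-individual segments with length >= ``min_length_cm``
    among all C(n_diploids, 2) pairs, normalised per pair and per 100 Mb.
    """
    if n_diploids < 2:
        raise ValueError("need at least two diploid individuals")
    if total_region_mb <= 0:
        raise ValueError("total_region_mb must be positive")
    frame = _as_frame(segments)
    if len(frame):
        mask = (frame["length_cm"] >= min_length_cm) & (
            frame["ind_a"] != frame["ind_b"]
        )
        count = int(mask.sum())
    else:
        count = 0
    n_pairs = n_diploids * (n_diploids - 1) // 2
    return count / n_pairs / (total_region_mb / 100.0)


def write_segment_table(path, segments, chrom: str = "1", header_lines: Sequence[str] = ()) -> None:
    """Write segments as a BED-like tab-delimited table with a header row."""
    frame = _as_frame(segments).copy()
    frame.insert(0, "chrom", chrom)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_segment_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#")
    return frame[SEGMENT_COLUMNS]
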