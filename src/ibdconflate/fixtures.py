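"""Deterministic miniature inputs for tests and demonstrations.

Everything here is synthetic and hand-computed: a three-tree genealogy with
known per-pair TMRCA change points, a five-segment conflation toy set with
exactly two events at the default thresholds, caller-output fixture files,
and a seeded gamma-mixture sample with known parameters.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tskit

from .demography import SimulatedRegion, SimulationConfig
from .true_ibd import IBDSegment

__all__ = [
    "build_three_tree_region",
    "THREE_TREE_EXPECTED",
    "toy_conflation_segments",
    "refined_ibd_lines",
    "germline_match_lines",
    "make_fixtures",
]


def build_three_tree_region() -> SimulatedRegion:
    """A 3 Mb region of 4 haplotypes with three hand-built marginal trees.

    Tree 1 on [0, 1 Mb): ((0,1):100, (2,3):200):5000
    Tree 2 on [1, 2 Mb): ((0,1):100, (2,3):400):6000   (node for (0,1) persists)
    Tree 3 on [2, 3 Mb): ((0,2):150, (1,3):300):7000

    Haplotypes are paired (0,1) -> individual 0 and (2,3) -> individual 1.
    """
    tables = tskit.TableCollection(sequence_length=3_000_000)
    for _ in range(4):
        tables.nodes.add_row(flags=tskit.NODE_IS_SAMPLE, time=0.0)
    a = tables.nodes.add_row(time=100.0)   # (0,1), trees 1-2
    b = tables.nodes.add_row(time=200.0)   # (2,3), tree 1
    c = tables.nodes.add_row(time=400.0)   # (2,3), tree 2
    r1 = tables.nodes.add_row(time=5000.0)
    r2 = tables.nodes.add_row(time=6000.0)
    d = tables.nodes.add_row(time=150.0)   # (0,2), tree 3
    e = tables.nodes.add_row(time=300.0)   # (1,3), tree 3
    r3 = tables.nodes.add_row(time=7000.0)
    M = 1_000_000
    edges = [
        (0, 2 * M, a, 0),
        (0, 2 * M, a, 1),
        (0, M, b, 2),
        (0, M, b, 3),
        (M, 2 * M, c, 2),
        (M, 2 * M, c, 3),
        (0, M, r1, a),
        (0, M, r1, b),
        (M, 2 * M, r2, a),
        (M, 2 * M, r2, c),
        (2 * M, 3 * M, d, 0),
        (2 * M, 3 * M, d, 2),
        (2 * M, 3 * M, e, 1),
        (2 * M, 3 * M, e, 3),
        (2 * M, 3 * M, r3, d),
        (2 * M, 3 * M, r3, e),
    ]
    for left, right, parent, child in edges:
        tables.edges.add_row(left=left, right=right, parent=parent, child=child)
    tables.sort()
    ts = tables.tree_sequence()
    return SimulatedRegion(
        ts=ts,
        pairing=np.array([0, 0, 1, 1]),
        config=SimulationConfig(
            region_length_bp=3_000_000, n_haplotypes=4, mu_per_bp_gen=0.0, seed=0
        ),
    )


#: Hand-computed segments of the three-tree genealogy at max_age 3000,
#: min_length 0.5 cM (grid-independent since boundaries fall on the grid).
THREE_TREE_EXPECTED = [
    IBDSegment(0, 1, 0, 0, 0, 2_000_000, 2.0, 100.0),
    IBDSegment(2, 3, 1, 1, 0, 1_000_000, 1.0, 200.0),
    IBDSegment(2, 3, 1, 1, 1_000_000, 2_000_000, 1.0, 400.0),
    IBDSegment(0, 2, 0, 1, 2_000_000, 3_000_000, 1.0, 150.0),
    IBDSegment(1, 3, 0, 1, 2_000_000, 3_000_000, 1.0, 300.0),
]


def toy_conflation_segments() -> list[IBDSegment]:
    """Five segments of one diploid pair with exactly two conflation events.

    At w = 0.2 cM, gap = 0, combined >= 1 cM: segments 1+2 conflate in
    trans (combined 1.1 cM) and segments 4+5 conflate in cis (overlapping,
    combined 1.1 cM); segment 3 is too short to participate.
    """
    Mb = 1_000_000

    def seg(h1, h2, lo_cm, hi_cm, age):
        return IBDSegment(
            h1, h2, 0, 1,
            int(lo_cm * Mb), int(hi_cm * Mb), round(hi_cm - lo_cm, 9), age,
        )

    return [
        seg(0, 2, 0.0, 0.6, 500.0),
        seg(1, 3, 0.6, 1.1, 800.0),
        seg(0, 3, 2.0, 2.15, 400.0),
        seg(0, 2, 3.0, 3.5, 900.0),
        seg(0, 2, 3.45, 4.1, 1200.0),
    ]


def refined_ibd_lines() -> list[str]:
    """Three Refined IBD output records (sample hap sample hap chrom start end LOD)."""
    return [
        "ind0\t1\tind1\t1\t1\t1000000\t2200000\t4.5",
        "ind0\t2\tind2\t1\t1\t5000000\t6500000\t7.1",
        "ind1\t2\tind2\t2\t1\t8000000\t9100000\t3.2",
    ]


def germline_match_lines() -> list[str]:
    """Three GERMLINE .match records."""
    return [
        "0 ind0 0 ind1 1 1000000 2200000 rs1 rs120 600 1.2 cM 0 0 0",
        "0 ind0 0 ind2 1 5000000 6500000 rs500 rs650 750 1.5 cM 1 0 0",
        "0 ind1 0 ind2 1 8000000 9100000 rs800 rs910 550 1.1 cM 0 0 0",
    ]


def make_fixtures(outdir, seed: int = 0) -> Path:
    """Write the fixture files into ``outdir`` and return its path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    region = build_three_tree_region()
    region.ts.dump(str(out / "three_tree.trees"))
    from .true_ibd import write_segment_table

    write_segment_table(
        out / "toy_conflation_segments.tsv",
        toy_conflation_segments(),
        header_lines=[f"seed={seed}", "toy conflation fixture"],
    )
    (out / "refined_fixture.ibd").write_text("\n".join(refined_ibd_lines()) + "\n")
    (out / "germline_fixture.match").write_text(
        "\n".join(germline_match_lines()) + "\n"
    )
    rng = np.random.default_rng(seed)
    comp = rng.random(200) < 0.6
    draws = np.where(comp, rng.gamma(6.0, 120.0, 200), rng.gamma(2.0, 40.0, 200))
    np.savetxt(
        out / "gamma_mixture_sample.tsv",
        draws,
        header=f"seed={seed} mixture 0.4*Gamma(2,40)+0.6*Gamma(6,120)",
    )
    return out
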