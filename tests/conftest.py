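"""Shared fixtures: small seeded simulations and brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ibdconflate import (
    DemographicModel,
    Epoch,
    SimulationConfig,
    simulate_region,
)
from ibdconflate.fixtures import build_three_tree_region


@pytest.fixture(scope="session")
def european_model():
    return DemographicModel.default_european()


@pytest.fixture(scope="session")
def constant_model():
    return DemographicModel(epochs=(Epoch(0.0, 5000.0, 0.0),))


@pytest.fixture(scope="session")
def toy_region(constant_model):
    """1 Mb, 10 haplotypes, constant N=5000 — small enough for brute force."""
    cfg = SimulationConfig(
        region_length_bp=1_000_000,
        n_haplotypes=10,
        mu_per_bp_gen=1.2e-8,
        recomb_per_bp_gen=1e-8,
        seed=42,
    )
    return simulate_region(constant_model, cfg)


@pytest.fixture(scope="session")
def three_tree_region():
    return build_three_tree_region()


def tmrca_walker(ts, max_age=np.inf):
    """Full-resolution per-pair TMRCA change-point oracle.

    Walks every marginal tree and returns, for each haplotype pair, the
    maximal runs of constant TMRCA as ``{(i, j): [(left, right, t), ...]}``.
    """
    pairs = list(itertools.combinations(range(ts.num_samples), 2))
    cur = {p: None for p in pairs}
    runs = {p: [] for p in pairs}
    for tree in ts.trees():
        left = tree.interval.left
        for p in pairs:
            t = tree.tmrca(*p)
            c = cur[p]
            if c is None:
                cur[p] = [left, t]
            elif c[1] != t:
                runs[p].append((c[0], left, c[1]))
                cur[p] = [left, t]
    for p in pairs:
        c = cur[p]
        runs[p].append((c[0], ts.sequence_length, c[1]))
    if np.isfinite(max_age):
        runs = {
            p: [r for r in lst if r[2] < max_age] for p, lst in runs.items()
        }
    return runs


def brute_force_events(segments, w_cm, max_gap_cm, min_combined_cm):
    """O(n^2) all-pairs conflation-event oracle over IBDSegment records."""
    out = []
    for i, s1 in enumerate(segments):
        for j in range(i + 1, len(segments)):
            s2 = segments[j]
            if s1.diploid_pair != s2.diploid_pair:
                continue
            a, b = (s1, s2) if s1.start_bp <= s2.start_bp else (s2, s1)
            if a.length_cm < w_cm - 1e-12 or b.length_cm < w_cm - 1e-12:
                continue
            gap = max(0.0, (b.start_bp - a.end_bp) * 1e-6)
            if gap > max_gap_cm + 1e-12:
                continue
            combined = (max(a.end_bp, b.end_bp) - a.start_bp) * 1e-6
            if combined < min_combined_cm - 1e-12:
                continue
            out.append((a.start_bp, a.end_bp, b.start_bp, b.end_bp, round(combined, 9)))
    return sorted(out)
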