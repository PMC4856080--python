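"""The IBD mutation-rate estimator and the conflation bias experiment."""

import numpy as np
import pytest

from ibdconflate import (
    AgeLengthModel,
    GammaMixture,
    MuEstimateSummary,
    SyntheticSegment,
    estimate_mu,
    mu_bias_experiment,
    mu_vs_length_cutoff,
    simulate_segment_set,
)

MU = 1.2e-8


def synthetic_model(max_len_cm=6.0):
    """Age model in which longer segments are (stochastically) younger:
    within bin midpoint l, ages ~ Gamma(shape 4, scale 12.5/l), so the mean
    age is 50/l generations — the coalescent scaling E[T | L=l] ~ 1/(2l)."""
    edges = np.round(np.arange(0.2, max_len_cm + 0.1, 0.1), 9)
    mixtures = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid = (lo + hi) / 2 / 100.0  # Morgans
        mixtures.append(
            GammaMixture(
                weights=np.array([1.0]),
                shapes=np.array([4.0]),
                scales=np.array([1.0 / (8.0 * mid)]),
            )
        )
    return AgeLengthModel(edges=edges, mixtures=mixtures)


@pytest.fixture(scope="module")
def model():
    return synthetic_model()


@pytest.fixture(scope="module")
def length_distributions():
    rng = np.random.default_rng(100)
    # peaked-near-zero true lengths; apparent lengths above the 1 cM cutoff
    true_lengths = 0.2 + rng.exponential(0.35, 20_000)
    apparent = true_lengths[true_lengths >= 1.0]
    return apparent, true_lengths


class TestEstimateMu:
    def test_single_segment_arithmetic(self):
        seg = SyntheticSegment(
            apparent_length_cm=1.0,
            is_conflated=False,
            sub_lengths_cm=(1.0,),
            true_ages_gen=(1000.0,),
            mismatch_count=24,
            apparent_age_gen=1000.0,
            sequenced_length_bp=1e6,
        )
        assert estimate_mu([seg]) == pytest.approx(1.2e-8)

    def test_zero_mismatches_give_zero_estimate(self):
        seg = SyntheticSegment(1.0, False, (1.0,), (500.0,), 0, 500.0, 1e6)
        assert estimate_mu([seg]) == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_mu([])

    def test_unbiased_with_known_ages(self):
        rng = np.random.default_rng(1)
        n = 10_000
        L = rng.uniform(1e6, 3e6, n)
        T = rng.gamma(4, 100, n)
        lam = 2 * L * T * MU
        m = rng.poisson(lam)
        segs = [
            SyntheticSegment(
                L[i] * 1e-6, False, (L[i] * 1e-6,), (T[i],), int(m[i]), T[i], L[i]
            )
            for i in range(n)
        ]
        mu_hat = estimate_mu(segs)
        se = np.sqrt(lam.sum()) / (2 * L * T).sum()
        assert abs(mu_hat - MU) < 3 * se


class TestSimulateSegments:
    def test_no_conflation_and_zero_mu_gives_zero_mismatches(self, model, length_distributions):
        apparent, true_lengths = length_distributions
        segs = simulate_segment_set(
            model, apparent, None, true_lengths, mu=0.0, set_size=500,
            rng=np.random.default_rng(2),
        )
        assert all(s.mismatch_count == 0 for s in segs)
        assert not any(s.is_conflated for s in segs)

    def test_poisson_mean_matches_mu(self, model, length_distributions):
        apparent, true_lengths = length_distributions
        segs = simulate_segment_set(
            model, apparent, None, true_lengths, mu=MU, set_size=100_000,
            rng=np.random.default_rng(3),
        )
        ratios = [
            s.mismatch_count
            / (2 * s.sequenced_length_bp * s.true_ages_gen[0] * MU)
            for s in segs
        ]
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.02)

    def test_conflated_sub_lengths_sum_exactly(self, model, length_distributions):
        apparent, true_lengths = length_distributions
        segs = simulate_segment_set(
            model, apparent, 1.0, true_lengths, mu=MU, set_size=2000,
            rng=np.random.default_rng(4),
        )
        for s in segs:
            assert s.is_conflated
            assert sum(s.sub_lengths_cm) == pytest.approx(
                s.apparent_length_cm, abs=1e-9
            )
            assert min(s.sub_lengths_cm) > 0


class TestBiasExperiment:
    def test_true_ages_recover_mu_in_every_scenario(self, model, length_distributions):
        # the bias is attributable entirely to apparent-age misassignment:
        # substituting the true per-subsegment ages recovers the input rate
        apparent, true_lengths = length_distributions
        for scenario in ("nonconflated", "all_conflated", "mixture"):
            summ = mu_bias_experiment(
                model, apparent, 0.5, true_lengths, mu=MU,
                n_sets=60, set_size=2000, scenario=scenario,
                rng=np.random.default_rng(5), use_true_ages=True,
            )
            assert summ.median == pytest.approx(MU, rel=0.02)

    def test_scenario_ordering(self, model, length_distributions):
        apparent, true_lengths = length_distributions
        medians = {}
        for scenario in ("nonconflated", "all_conflated", "mixture"):
            medians[scenario] = mu_bias_experiment(
                model, apparent, 0.5, true_lengths, mu=MU,
                n_sets=60, set_size=2000, scenario=scenario,
                rng=np.random.default_rng(6),
            ).median
        assert medians["nonconflated"] < medians["mixture"] < medians["all_conflated"]

    def test_estimate_scales_linearly_in_mu(self, model, length_distributions):
        apparent, true_lengths = length_distributions
        m1 = mu_bias_experiment(
            model, apparent, 0.5, true_lengths, mu=MU,
            n_sets=40, set_size=2000, scenario="mixture",
            rng=np.random.default_rng(7),
        ).median
        m2 = mu_bias_experiment(
            model, apparent, 0.5, true_lengths, mu=2 * MU,
            n_sets=40, set_size=2000, scenario="mixture",
            rng=np.random.default_rng(7),
        ).median
        assert m2 / m1 == pytest.approx(2.0, rel=0.03)

    def test_invalid_scenario_rejected(self, model, length_distributions):
        apparent, true_lengths = length_distributions
        with pytest.raises(ValueError):
            mu_bias_experiment(
                model, apparent, 0.5, true_lengths, scenario="bogus",
                rng=np.random.default_rng(8),
            )

    def test_percentile_invariants(self, model, length_distributions):
        apparent, true_lengths = length_distributions
        summ = mu_bias_experiment(
            model, apparent, 0.5, true_lengths, mu=MU, n_sets=50,
            set_size=1000, scenario="mixture", rng=np.random.default_rng(9),
        )
        assert summ.p5 <= summ.median <= summ.p95
        assert summ.p5 > 0


class TestLengthCutoffs:
    def test_first_cutoff_equals_base_experiment(self, model, length_distributions):
        apparent, true_lengths = length_distributions
        table = mu_vs_length_cutoff(
            model, apparent, 0.5, true_lengths, cutoffs_cm=[1.0],
            n_sets=30, set_size=1000, rng=np.random.default_rng(10),
        )
        base = mu_bias_experiment(
            model, apparent, 0.5, true_lengths, n_sets=30, set_size=1000,
            scenario="mixture", rng=np.random.default_rng(10),
            min_length_cm=1.0,
        )
        assert table.iloc[0]["median"] == pytest.approx(base.median)

    def test_inflation_decreases_and_interval_widens_with_cutoff(
        self, model, length_distributions
    ):
        apparent, true_lengths = length_distributions
        # conflation probability declining with length, as in the measured
        # per-bin proportions
        def prop(lengths):
            return np.clip(0.8 - 0.3 * (np.asarray(lengths) - 1.0), 0.0, 1.0)

        table = mu_vs_length_cutoff(
            model, apparent, prop, true_lengths, cutoffs_cm=[1.0, 1.5, 2.0],
            n_sets=80, set_size=2000, rng=np.random.default_rng(11),
        )
        medians = table["median"].to_numpy()
        widths = (table["p95"] - table["p5"]).to_numpy()
        assert medians[0] > medians[1] > medians[2]
        assert widths[2] >= widths[0]

    def test_non_increasing_cutoffs_rejected(self, model, length_distributions):
        apparent, true_lengths = length_distributions
        with pytest.raises(ValueError):
            mu_vs_length_cutoff(
                model, apparent, 0.5, true_lengths, cutoffs_cm=[1.0, 1.0]
            )

    def test_cutoff_beyond_all_lengths_rejected(self, model, length_distributions):
        apparent, true_lengths = length_distributions
        with pytest.raises(ValueError):
            mu_vs_length_cutoff(
                model, apparent, 0.5, true_lengths, cutoffs_cm=[50.0],
                n_sets=5, set_size=100, rng=np.random.default_rng(12),
            )


def test_summary_invariant_enforced():
    with pytest.raises(ValueError):
        MuEstimateSummary(
            scenario="mixture", median=1.0, p5=2.0, p95=3.0, n_sets=1, set_size=1
        )
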