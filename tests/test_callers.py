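"""Caller-output parsing, the built-in IBS matcher, and decomposition."""

import numpy as np
import pytest

from ibdconflate import (
    CalledSegment,
    IBDSegment,
    SimulationConfig,
    decompose_called,
    downsample_to_array,
    read_germline_match,
    read_refined_ibd,
    simple_ibs_caller,
    simulate_region,
    summarize_conflation,
    trim_and_summarize,
)
from ibdconflate.demography import ArrayDataset
from ibdconflate.fixtures import germline_match_lines, refined_ibd_lines


def true_seg(lo_cm, hi_cm, haps=(0, 2), inds=(0, 1), age=500.0):
    Mb = 1_000_000
    return IBDSegment(
        haps[0], haps[1], inds[0], inds[1],
        int(lo_cm * Mb), int(hi_cm * Mb), round(hi_cm - lo_cm, 9), age,
    )


def called(lo_cm, hi_cm, inds=("0", "1")):
    Mb = 1_000_000
    return CalledSegment(
        inds[0], inds[1], int(lo_cm * Mb), int(hi_cm * Mb),
        round(hi_cm - lo_cm, 9), source="test",
    )


class TestParsers:
    def test_refined_ibd_fixture(self, tmp_path):
        path = tmp_path / "fixture.ibd"
        path.write_text("\n".join(refined_ibd_lines()) + "\n")
        records = read_refined_ibd(path)
        assert len(records) == 3
        assert records[0].ind_a == "ind0" and records[0].ind_b == "ind1"
        assert records[0].start_bp == 1_000_000
        assert records[0].length_cm == pytest.approx(1.2)
        assert records[0].score == 4.5  # LOD preserved

    def test_germline_fixture(self, tmp_path):
        path = tmp_path / "fixture.match"
        path.write_text("\n".join(germline_match_lines()) + "\n")
        records = read_germline_match(path)
        assert len(records) == 3
        assert records[1].ind_b == "ind2"
        assert records[2].length_cm == pytest.approx(1.1)

    @pytest.mark.parametrize("reader", [read_refined_ibd, read_germline_match])
    def test_empty_file(self, tmp_path, reader):
        path = tmp_path / "empty"
        path.write_text("")
        assert reader(path) == []

    @pytest.mark.parametrize("reader", [read_refined_ibd, read_germline_match])
    def test_malformed_line_reports_line_number(self, tmp_path, reader):
        path = tmp_path / "bad"
        path.write_text("only three fields\n")
        with pytest.raises(ValueError, match=":1:"):
            reader(path)


class TestIBSCaller:
    def make_array(self, haplotypes, spacing_bp=10_000):
        haplotypes = np.asarray(haplotypes, dtype=np.int8)
        n_mark, n_hap = haplotypes.shape
        return ArrayDataset(
            positions=np.arange(n_mark) * spacing_bp,
            haplotypes=haplotypes,
            pairing=np.repeat(np.arange(n_hap // 2), 2),
            phased=True,
        )

    def test_identical_haplotypes_called_full_length(self):
        rng = np.random.default_rng(0)
        h = rng.integers(0, 2, size=(200, 4), dtype=np.int8)
        h[:, 2] = h[:, 0]  # hap 0 (ind 0) identical to hap 2 (ind 1)
        calls = simple_ibs_caller(self.make_array(h), min_length_cm=1.0)
        assert any(
            c.start_bp == 0 and c.end_bp == 199 * 10_000 + 1 for c in calls
        )

    def test_everywhere_different_haplotypes_give_no_calls(self):
        h = np.zeros((200, 4), dtype=np.int8)
        h[:, 1] = 1
        h[::2, 2] = 1
        h[1::2, 3] = 1
        # make every pair differ at every second marker at least
        h[::2, 0] = 0
        calls = simple_ibs_caller(self.make_array(h), min_length_cm=0.5)
        assert calls == []

    def test_planted_tract_recovered_to_marker_resolution(self):
        rng = np.random.default_rng(1)
        n_mark = 400
        h = rng.integers(0, 2, size=(n_mark, 6), dtype=np.int8)
        lo, hi = 100, 250  # 1.5 cM at 10 kb spacing
        h[lo:hi, 4] = h[lo:hi, 0]
        # break identity right outside the tract
        h[lo - 1, 4] = 1 - h[lo - 1, 0]
        h[hi, 4] = 1 - h[hi, 0]
        calls = simple_ibs_caller(self.make_array(h), min_length_cm=1.0)
        tract = [c for c in calls if c.pair_key == ("0", "2")]
        assert len(tract) == 1
        assert tract[0].start_bp == lo * 10_000
        assert tract[0].end_bp == (hi - 1) * 10_000 + 1

    def test_unphased_input_rejected(self):
        arr = self.make_array(np.zeros((64, 4), dtype=np.int8))
        arr.phased = False
        with pytest.raises(ValueError):
            simple_ibs_caller(arr)


class TestDecompose:
    def test_exact_match_is_single_subsegment(self):
        truth = [true_seg(1.0, 2.5)]
        rec = decompose_called([called(1.0, 2.5)], truth)[0]
        assert rec.n_subsegments == 1
        assert not rec.conflated
        assert rec.overlap_cm == pytest.approx(1.5)
        assert rec.extension_cm == 0.0
        assert rec.endpoint_error_cm == pytest.approx(0.0, abs=1e-9)

    def test_adjacent_subsegments_flag_conflation(self):
        truth = [true_seg(1.0, 1.6), true_seg(1.6, 2.1, haps=(1, 3))]
        rec = decompose_called([called(1.0, 2.1)], truth)[0]
        assert rec.conflated
        assert rec.overlap_cm == pytest.approx(0.6)
        assert rec.extension_cm == pytest.approx(0.5)
        assert rec.endpoint_error_cm == pytest.approx(0.0, abs=1e-9)

    def test_fully_overlapped_second_subsegment_ignored(self):
        truth = [true_seg(1.0, 2.5), true_seg(1.4, 1.9, haps=(1, 3))]
        rec = decompose_called([called(1.0, 2.5)], truth)[0]
        assert rec.n_subsegments == 1
        assert not rec.conflated
        assert rec.extension_cm == 0.0

    def test_no_overlap_is_pure_endpoint_error(self):
        truth = [true_seg(8.0, 9.0)]
        rec = decompose_called([called(1.0, 2.2)], truth)[0]
        assert rec.longest is None
        assert rec.endpoint_error_cm == pytest.approx(1.2)

    def test_partition_invariant_on_random_sets(self):
        rng = np.random.default_rng(2)
        truth = []
        for _ in range(40):
            lo = rng.uniform(0, 18)
            truth.append(
                true_seg(
                    lo, lo + rng.uniform(0.1, 1.5),
                    haps=(rng.integers(0, 2), 2 + rng.integers(0, 2)),
                )
            )
        calls = []
        for _ in range(15):
            lo = rng.uniform(0, 17)
            calls.append(called(lo, lo + rng.uniform(1.0, 2.5)))
        for rec in decompose_called(calls, truth):
            total = rec.overlap_cm + rec.extension_cm + rec.endpoint_error_cm
            assert total == pytest.approx(rec.called.length_cm, abs=1e-6)
            assert min(rec.overlap_cm, rec.extension_cm, rec.endpoint_error_cm) >= 0


class TestSummaries:
    def test_zero_extension_means_zero_proportions(self):
        truth = [true_seg(1.0, 2.5)]
        summary = summarize_conflation(decompose_called([called(1.0, 2.5)], truth))
        assert summary.prop_conflated == 0.0
        assert summary.prop_extended == 0.0

    def test_two_record_arithmetic(self):
        truth = [
            true_seg(1.0, 2.5),
            true_seg(5.0, 6.0),
            true_seg(6.0, 6.4, haps=(1, 3)),
        ]
        calls = [called(1.0, 2.5), called(5.0, 6.4)]
        summary = summarize_conflation(decompose_called(calls, truth))
        assert summary.prop_extended == pytest.approx(0.5)
        assert summary.mean_extension_when_extended == pytest.approx(0.4)

    def test_bin_table_covers_seven_bins(self):
        truth = [true_seg(1.0, 2.5)]
        summary = summarize_conflation(decompose_called([called(1.0, 2.5)], truth))
        assert len(summary.by_length_bin) == 7
        assert summary.by_length_bin["n"].sum() == 1

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            summarize_conflation([])


class TestTrimming:
    def test_zero_trim_matches_untrimmed(self):
        truth = [true_seg(1.0, 2.5), true_seg(5.0, 6.0)]
        calls = [called(1.0, 2.5), called(4.9, 6.1)]
        a = summarize_conflation(decompose_called(calls, truth))
        b = trim_and_summarize(calls, truth, trim_cm=0.0)
        assert a.prop_conflated == b.prop_conflated
        assert a.prop_extended == b.prop_extended

    def test_extension_within_trim_zone_removed(self):
        # second subsegment pokes 0.2 cM into the call; after trimming
        # 0.1 cM its clipped overlap drops below the 0.2 cM qualifying
        # threshold and the extension disappears
        truth = [true_seg(1.0, 2.0), true_seg(2.0, 2.9, haps=(1, 3))]
        calls = [called(1.0, 2.2)]
        untrimmed = decompose_called(calls, truth)[0]
        assert untrimmed.extension_cm > 0
        trimmed = trim_and_summarize(calls, truth, trim_cm=0.1)
        assert trimmed.prop_extended == 0.0

    def test_short_calls_dropped_with_warning(self):
        truth = [true_seg(1.0, 2.5)]
        calls = [called(1.0, 1.15), called(3.0, 4.5)]
        with pytest.warns(UserWarning):
            summary = trim_and_summarize(calls, truth, trim_cm=0.1)
        assert summary.n_records == 1


def test_ibs_calls_decompose_against_truth_at_toy_scale(constant_model):
    """End-to-end smoke: simulate, down-sample, call IBS, decompose."""
    from ibdconflate import extract_ibd_table

    cfg = SimulationConfig(
        region_length_bp=2_000_000, n_haplotypes=20, mu_per_bp_gen=2e-8, seed=77
    )
    region = simulate_region(constant_model, cfg)
    arr = downsample_to_array(
        region, target_density=10**6, maf_min=0.05, rng=np.random.default_rng(0)
    )
    calls = simple_ibs_caller(arr, min_length_cm=0.5, seed_markers=16)
    truth = extract_ibd_table(region, max_age_gen=np.inf, min_length_cm=0.05)
    truth = truth[truth.ind_a != truth.ind_b]
    if calls:
        records = decompose_called(calls, truth, min_sub_cm=0.1)
        for rec in records:
            total = rec.overlap_cm + rec.extension_cm + rec.endpoint_error_cm
            assert total == pytest.approx(rec.called.length_cm, abs=1e-6)
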