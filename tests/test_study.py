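import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import waterpet as wp
from waterpet.kinetics import MBFResult
from waterpet.study import (
    DeviationReport,
    MBF_THRESHOLD,
    bland_altman,
    interpret,
    interpretation_change,
    relative_deviation,
    run_study,
    significance_band,
    signed_rank_deviation_test,
)
from tests.conftest import TEST_SHAPE


def _result(lad, rca, lcx):
    vals = {"LAD": lad, "RCA": rca, "LCx": lcx}
    return MBFResult(territory_mbf=vals, global_mbf=float(np.mean(list(vals.values()))),
                     global_mbf_territory_mean=float(np.mean(list(vals.values()))))


class TestRelativeDeviation:
    def test_identity_is_zero(self):
        assert relative_deviation(2.5, 2.5) == 0.0

    def test_twenty_percent_example(self):
        assert relative_deviation(2.76, 2.30) == pytest.approx(20.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_deviation(2.0, 0.0)

    def test_large_artifact_flag_requires_territorial_exceedance(self):
        ref = _result(2.5, 2.5, 2.5)
        just_under = DeviationReport.from_results(_result(2.9, 2.5, 2.5), ref)
        assert not just_under.large_artifact            # +16%
        over = DeviationReport.from_results(_result(3.1, 2.5, 2.5), ref)
        assert over.large_artifact                      # +24% in LAD

    def test_artifact_reduced_compares_worst_territory(self):
        ref = _result(2.5, 2.5, 2.5)
        rep = DeviationReport.from_results(
            _result(3.2, 2.5, 2.5), ref, corrected=_result(2.6, 2.5, 2.5)
        )
        assert rep.artifact_reduced is True
        worse = DeviationReport.from_results(
            _result(2.6, 2.5, 2.5), ref, corrected=_result(3.2, 2.5, 2.5)
        )
        assert worse.artifact_reduced is False


class TestInterpretation:
    def test_all_normal(self):
        rec = interpret(_result(3.0, 3.0, 3.0))
        assert not rec.any_positive
        assert not any(rec.calls.values())

    def test_exactly_at_threshold_is_negative(self):
        rec = interpret(_result(MBF_THRESHOLD, 3.0, 3.0))
        assert rec["LAD"] is False                      # >= 2.3 is normal

    def test_single_territory_positive_sets_any(self):
        rec = interpret(_result(2.5, 2.1, 2.5))
        assert rec["RCA"] and not rec["LAD"] and not rec["LCx"]
        assert rec.any_positive

    def test_threshold_monotone(self):
        res = _result(2.0, 2.6, 3.1)
        low = interpret(res, threshold=2.1)
        high = interpret(res, threshold=2.8)
        for region, call in low.calls.items():
            assert (not call) or high.calls[region]     # raising never clears

    def test_missing_territory_rejected(self):
        bad = MBFResult(territory_mbf={"LAD": 2.0, "RCA": 2.0},
                        global_mbf=2.0, global_mbf_territory_mean=2.0)
        with pytest.raises(ValueError):
            interpret(bad)


class TestInterpretationChange:
    def test_no_change(self):
        a = interpret(_result(3.0, 3.0, 3.0))
        changes = interpretation_change(a, a, a)
        assert all(c["change"] == "none" for c in changes.values())

    def test_true_positive_to_negative(self):
        pre = interpret(_result(2.5, 2.1, 2.5))
        post = interpret(_result(2.5, 2.5, 2.5))
        truth = interpret(_result(2.5, 2.4, 2.5))
        ch = interpretation_change(pre, post, truth)
        assert ch["RCA"] == {"change": "pos_to_neg", "true": True}
        assert ch["any"]["change"] == "pos_to_neg"

    def test_false_negative_to_positive(self):
        pre = interpret(_result(2.5, 2.5, 2.5))
        post = interpret(_result(2.1, 2.5, 2.5))
        truth = interpret(_result(2.5, 2.5, 2.5))
        ch = interpretation_change(pre, post, truth)
        assert ch["LAD"] == {"change": "neg_to_pos", "true": False}


class TestSignedRank:
    def test_all_zero_differences_nonsignificant(self):
        assert signed_rank_deviation_test(np.zeros(10)) == 1.0

    def test_ten_concordant_pairs_exact_p(self):
        # exact two-sided signed-rank null: all 10 same sign -> 2 * 2^-10
        p = signed_rank_deviation_test(np.arange(1.0, 11.0))
        assert p == pytest.approx(2 * 2.0**-10, rel=1e-9)

    def test_banding(self):
        assert significance_band(0.03) == "<.05"
        assert significance_band(0.001) == "<.005"
        assert significance_band(0.5) == ">.05"

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            signed_rank_deviation_test(np.array([1.0, 2.0]))


class TestBlandAltman:
    def test_identical_arrays(self):
        ba = bland_altman(np.ones(5), np.ones(5))
        assert ba.median_difference == 0.0
        assert ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_hand_computed_limits(self):
        pre = np.array([1.0, 2.0, 3.0])
        post = pre + np.array([-1.0, 0.0, 1.0])
        ba = bland_altman(pre, post)
        assert ba.median_difference == 0.0
        assert ba.loa_high == pytest.approx(1.96 * 1.0)     # SD(ddof=1) = 1
        assert ba.loa_low == pytest.approx(-1.96 * 1.0)

    def test_pair_order_permutation_invariant(self):
        rng = np.random.default_rng(0)
        pre, post = rng.normal(size=20), rng.normal(size=20)
        perm = rng.permutation(20)
        a = bland_altman(pre, post)
        b = bland_altman(pre[perm], post[perm])
        assert a.median_difference == pytest.approx(b.median_difference)
        assert a.loa_low == pytest.approx(b.loa_low)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(np.array([1.0]), np.array([1.0]))


@given(st.lists(st.floats(-50, 50), min_size=2, max_size=30))
@settings(max_examples=50, deadline=None)
def test_bland_altman_limits_bracket_mean(diffs):
    diffs = np.asarray(diffs)
    ba = bland_altman(np.zeros_like(diffs), diffs)
    assert ba.loa_low <= ba.mean_difference <= ba.loa_high


class TestStudyDesign:
    def test_motion_scan_count_is_subjects_times_catalogue(self, catalogue):
        design = wp.StudyDesign()
        assert design.n_subjects * len(catalogue) == 160

    def test_unknown_approach_rejected(self):
        with pytest.raises(ValueError):
            wp.StudyDesign(approaches=("oracle", "psychic"))


@pytest.fixture(scope="module")
def small_design():
    return wp.StudyDesign(
        n_subjects=2,
        seed=5,
        approaches=("oracle",),
        base_spec=wp.PhantomSpec(grid_shape=TEST_SHAPE),
        motion_families=("PeakCough",),
    )


@pytest.fixture(scope="module")
def small_results(small_design):
    return run_study(small_design)


class TestRunStudy:
    def test_row_accounting(self, small_results):
        df = small_results.mbf_long
        assert (df.analysis == "motion-free").sum() == 2
        assert (df.analysis == "uncorrected").sum() == 4    # 2 subjects x 2 coughs
        assert (df.analysis == "oracle").sum() == 4
        assert small_results.failures == []

    def test_oracle_never_increases_median_absolute_deviation(self, small_results):
        unc = small_results.heatmap_median("uncorrected").abs()
        cor = small_results.heatmap_median("oracle").abs()
        assert (cor.to_numpy() <= unc.to_numpy() + 1e-9).all()

    def test_rerun_is_bit_reproducible(self, small_design, small_results):
        again = run_study(small_design)
        pd.testing.assert_frame_equal(small_results.mbf_long, again.mbf_long)
        pd.testing.assert_frame_equal(small_results.residuals, again.residuals)

    def test_outputs_persisted(self, small_results, tmp_path):
        small_results.to_dir(tmp_path)
        for name in ("mbf_long.csv", "residual_motion.csv",
                     "interpretation_changes.csv", "study.json",
                     "heatmap_median_uncorrected.csv", "heatmap_p_oracle.csv"):
            assert (tmp_path / name).exists()
        assert "Simulated-motion study" in small_results.summary()

    def test_bland_altman_summary_per_region(self, small_results):
        summ = small_results.bland_altman_summary("oracle")
        assert set(summ) == {"LAD", "RCA", "LCx", "global"}
        for ba in summ.values():
            assert ba.n == 4                          # 2 subjects x 2 coughs
            assert ba.loa_low <= ba.median_difference <= ba.loa_high

    def test_nulled_catalogue_gives_zero_deviations(self):
        design = wp.StudyDesign(
            n_subjects=1, seed=3, approaches=("oracle",),
            base_spec=wp.PhantomSpec(grid_shape=TEST_SHAPE),
            motion_families=("LateCough",), motion_scale=0.0,
        )
        res = run_study(design)
        unc = res.mbf_long[res.mbf_long.analysis == "uncorrected"]
        devs = unc[[c for c in unc.columns if c.startswith("dev_")]].to_numpy()
        assert np.allclose(devs, 0.0)
        if "large_artifact" in res.mbf_long:
            assert not res.mbf_long["large_artifact"].eq(True).any()
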