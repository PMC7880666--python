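"""The statistical core: transforms, reference, z/p/FDR, classification, age model."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tractdx import (AgeResidualizer, CohortFATable, NormativeDiagnostic,
                     apply_age_model, check_normality, compute_reference,
                     diagnose_cohort, fit_age_model, rank_inverse_normalize)
from tractdx.simulate import SimulationConfig, simulate_cohort_table

from conftest import bh_stepup_oracle


class TestRankInverseNormalize:
    def test_middle_rank_maps_to_zero(self):
        out = rank_inverse_normalize([3.0, 1.0, 5.0, 2.0, 4.0])
        # middle value (rank 3 of 5) sits at the Blom score's center
        assert out[0] == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=40, unique=True))
    def test_strictly_monotone(self, values):
        values = np.asarray(values)
        order_in = np.argsort(values)
        out = rank_inverse_normalize(values)
        assert np.all(np.diff(out[order_in]) > 0)

    def test_ties_get_average_rank_quantile(self):
        vals = np.array([1.0, 2.0, 2.0, 3.0])
        out = rank_inverse_normalize(vals)
        # explicit rank-then-quantile oracle with average ranks
        ranks = np.array([1.0, 2.5, 2.5, 4.0])
        expected = stats.norm.ppf((ranks - 0.375) / (4 + 0.25))
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert out[1] == out[2]

    def test_all_equal_rejected(self):
        with pytest.raises(ValueError):
            rank_inverse_normalize([2.0, 2.0, 2.0])

    def test_output_passes_shapiro_for_continuous_input(self):
        rng = np.random.default_rng(0)
        out = rank_inverse_normalize(rng.lognormal(0.0, 1.0, size=100))
        assert stats.shapiro(out).pvalue > 0.05


class TestCheckNormality:
    def test_normal_flag_rate_matches_level(self):
        """False-alarm rate of the screen stays within the binomial band of alpha."""
        rng = np.random.default_rng(42)
        n_seeds, flags = 200, 0
        for _ in range(n_seeds):
            df = pd.DataFrame({"roi": rng.normal(0.5, 0.02, size=50)})
            flags += int(~check_normality(df, alpha_sw=0.05)["normal"].iloc[0])
        rate = flags / n_seeds
        se = np.sqrt(0.05 * 0.95 / n_seeds)
        assert rate == pytest.approx(0.05, abs=3 * se)

    def test_lognormal_flagged_non_normal(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(50):
            df = pd.DataFrame({"roi": rng.lognormal(0.0, 1.0, size=50)})
            hits += int(~check_normality(df)["normal"].iloc[0])
        assert hits == 50  # power ~1 for heavy skew at n=50

    def test_constant_column_flagged_with_warning(self):
        df = pd.DataFrame({"roi": np.full(10, 0.5)})
        with pytest.warns(UserWarning, match="zero variance"):
            out = check_normality(df)
        assert not out["normal"].iloc[0]

    def test_too_few_controls(self):
        with pytest.raises(ValueError):
            check_normality(pd.DataFrame({"roi": [0.4, 0.5]}))


class TestReference:
    def test_two_point_formula(self):
        df = pd.DataFrame({"A": [0.4, 0.6]})
        ref = compute_reference(df)
        assert ref.mean["A"] == pytest.approx(0.5)
        # sample SD with n-1 denominator: sqrt(((0.1)^2 + (0.1)^2) / 1)
        assert ref.sd["A"] == pytest.approx(np.sqrt(0.02), abs=1e-15)

    def test_identical_controls_rejected(self):
        df = pd.DataFrame({"A": [0.5] * 5})
        with pytest.raises(ValueError, match="variance"):
            compute_reference(df)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"A": rng.uniform(0.3, 0.7, 100)})
        ref = compute_reference(df)
        x = df["A"].to_numpy()
        mean = sum(x) / 100
        sd = np.sqrt(sum((v - mean) ** 2 for v in x) / 99)
        assert ref.mean["A"] == pytest.approx(mean, abs=1e-12)
        assert ref.sd["A"] == pytest.approx(sd, abs=1e-12)


def _controls_frame(rng, n=103, rois=("A", "B", "C"), mean=0.5, sd=0.02):
    return pd.DataFrame({r: rng.normal(mean, sd, n) for r in rois})


class TestDiagnose:
    def test_patient_at_control_mean_is_normal(self, null_cohort):
        ctrl = null_cohort.values_frame
        est = NormativeDiagnostic(transform="never").fit(ctrl)
        patient = est.mean_.to_frame().T
        patient.index = ["pat"]
        res = est.diagnose(patient)[0]
        assert res.classification == "normal"
        np.testing.assert_allclose(res.table["z"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res.table["p_raw"], 1.0, atol=1e-12)

    def test_closed_form_z_and_bh(self):
        """x_bar=0.50, rho=0.02, x=0.40 -> z=-5; BH over 10 tracts keeps it significant."""
        rng = np.random.default_rng(2)
        ctrl = _controls_frame(rng, rois=[f"r{i}" for i in range(10)])
        est = NormativeDiagnostic(transform="never").fit(ctrl)
        patient = est.mean_.to_frame().T
        patient.index = ["pat"]
        patient["r0"] = est.mean_["r0"] - 5.0 * est.sd_["r0"]
        res = est.diagnose(patient)[0]
        assert res.table.loc["r0", "z"] == pytest.approx(-5.0, abs=1e-12)
        expected_p = 2 * stats.norm.sf(5.0)
        assert res.table.loc["r0", "p_raw"] == pytest.approx(expected_p, rel=1e-12)
        assert res.table.loc["r0", "p_fdr"] <= 10 * expected_p + 1e-18
        assert res.table.loc["r0", "abnormal"]
        assert res.classification == "abnormal"

    def test_bh_flat_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(bh_stepup_oracle(p), 0.05, atol=1e-15)
        from statsmodels.stats.multitest import multipletests
        np.testing.assert_allclose(multipletests(p, method="fdr_bh")[1], 0.05, atol=1e-15)

    def test_high_fa_not_abnormal(self):
        """Significantly *higher* FA is reported but never counted as injury."""
        rng = np.random.default_rng(3)
        ctrl = _controls_frame(rng, rois=[f"r{i}" for i in range(10)])
        est = NormativeDiagnostic(transform="never").fit(ctrl)
        patient = est.mean_.to_frame().T
        patient.index = ["pat"]
        patient["r1"] = est.mean_["r1"] + 5.0 * est.sd_["r1"]
        res = est.diagnose(patient)[0]
        row = res.table.loc["r1"]
        assert row["p_fdr"] <= 0.05 and row["z"] > 0
        assert not row["abnormal"] and row["high_fa"]
        assert res.classification == "normal"

    def test_missing_roi_shrinks_fdr_family(self):
        rng = np.random.default_rng(4)
        ctrl = _controls_frame(rng, rois=["A", "B", "C"])
        est = NormativeDiagnostic(transform="never").fit(ctrl)
        patient = est.mean_.to_frame().T
        patient.index = ["pat"]
        patient["A"] = est.mean_["A"] - 4 * est.sd_["A"]
        patient["C"] = np.nan
        res = est.diagnose(patient)[0]
        assert res.table.loc["C", "missing"]
        p_raw = res.table.loc["A", "p_raw"]
        # family of 2, rank 1 -> adjusted = 2*p (B is ~null)
        assert res.table.loc["A", "p_fdr"] == pytest.approx(2 * p_raw, rel=1e-9)

    def test_whole_brain_standalone(self, null_cohort):
        ctrl = null_cohort.values_frame
        est = NormativeDiagnostic(transform="never").fit(ctrl)
        patient = est.mean_.to_frame().T
        patient.index = ["pat"]
        patient["WSKL"] = est.mean_["WSKL"] - 4 * est.sd_["WSKL"]
        res = est.diagnose(patient)[0]
        assert res.whole_brain["abnormal"]
        # whole brain alone never drives the subject classification
        assert res.classification == "normal"

    def test_transform_preserves_patient_sign_ordering(self):
        """Rank-inverse transform never flips the patient's side of the controls."""
        rng = np.random.default_rng(5)
        ctrl = pd.DataFrame({"A": rng.lognormal(-0.7, 0.4, 60)})
        ctrl["A"] = np.clip(ctrl["A"], 0.05, 0.95)
        est = NormativeDiagnostic(transform="always").fit(ctrl)
        for q, sign in [(0.02, -1), (0.98, +1)]:
            patient = pd.DataFrame({"A": [ctrl["A"].quantile(q)]}, index=["p"])
            z = est.z_frame(patient).iloc[0, 0]
            assert np.sign(z) == sign

    def test_extreme_rank_flagged(self):
        rng = np.random.default_rng(6)
        ctrl = pd.DataFrame({"A": rng.normal(0.5, 0.02, 30)})
        est = NormativeDiagnostic(transform="always").fit(ctrl)
        patient = pd.DataFrame({"A": [0.2]}, index=["p"])  # below every control
        frame = est.diagnose_frame(patient)
        assert frame.loc[("p", "A"), "extreme_rank"]

    def test_zero_variance_controls_rejected(self):
        df = pd.DataFrame({"A": [0.5] * 10, "B": np.linspace(0.4, 0.6, 10)})
        with pytest.raises(ValueError, match="zero control variance"):
            NormativeDiagnostic(transform="never").fit(df)

    def test_t_tail_option_close_to_normal_at_large_n(self, null_cohort):
        ctrl = null_cohort.values_frame
        pat = ctrl.iloc[[0]]
        z_n = NormativeDiagnostic(transform="never", tail="normal").fit(ctrl.iloc[1:])
        z_t = NormativeDiagnostic(transform="never", tail="t").fit(ctrl.iloc[1:])
        p_n = z_n.diagnose_frame(pat)["p_raw"]
        p_t = z_t.diagnose_frame(pat)["p_raw"]
        assert np.allclose(p_n, p_t, atol=5e-3)


class TestAgeModel:
    def _aged_table(self, rng, beta1=-1e-3, noise=0.0, n=60):
        ages = rng.uniform(20, 70, n)
        fa = 0.6 + beta1 * (ages - 45) + rng.normal(0, noise, n)
        frame = pd.DataFrame({
            "group": ["control"] * (n - 1) + ["patient"],
            "age": ages, "timepoint": "single",
            "A": fa, "WSKL": fa,
        }, index=[f"s{i}" for i in range(n)])
        return CohortFATable(frame)

    def test_exact_linear_fit_leaves_zero_residuals(self):
        rng = np.random.default_rng(7)
        table = self._aged_table(rng, noise=0.0)
        model = fit_age_model(table, fit_cohort="pooled")
        resid = apply_age_model(table, model)
        np.testing.assert_allclose(resid.frame["A"], 0.0, atol=1e-10)
        # zero residual variance propagates as the zero-rho error
        with pytest.raises(ValueError, match="variance"):
            NormativeDiagnostic(transform="never").fit(resid.controls())

    def test_residual_mean_zero_on_fit_cohort(self):
        rng = np.random.default_rng(8)
        table = self._aged_table(rng, noise=0.01)
        model = fit_age_model(table, fit_cohort="controls_only")
        resid = apply_age_model(table, model)
        assert abs(resid.controls().frame["A"].mean()) < 1e-10

    def test_idempotent(self):
        rng = np.random.default_rng(9)
        table = self._aged_table(rng, noise=0.01)
        model = fit_age_model(table, fit_cohort="controls_only")
        once = apply_age_model(table, model)
        model2 = fit_age_model(once, fit_cohort="controls_only")
        twice = apply_age_model(once, model2)
        pd.testing.assert_frame_equal(
            once.frame[["A", "WSKL"]], twice.frame[["A", "WSKL"]], atol=1e-10, rtol=0,
        )

    def test_degenerate_design_rejected(self):
        frame = pd.DataFrame({
            "group": ["control"] * 5, "age": [40.0] * 5, "timepoint": "single",
            "A": np.linspace(0.4, 0.6, 5),
        }, index=[f"s{i}" for i in range(5)])
        with pytest.raises(ValueError, match="degenerate"):
            fit_age_model(CohortFATable(frame))

    def test_no_age_effect_leaves_classification_unchanged(self):
        """With no real age trend, correction flags the same subjects (paired sim)."""
        mismatches = 0
        for seed in range(30):
            cfg = SimulationConfig(n_controls=60, n_patients=4, beta_age=0.0,
                                   effect_size=3.5, n_injured_rois=3)
            table, _ = simulate_cohort_table(cfg, seed=seed)
            raw = [r.classification for r in diagnose_cohort(table, transform="never")]
            cor = [r.classification
                   for r in diagnose_cohort(table, transform="never", age_correct="controls")]
            mismatches += sum(a != b for a, b in zip(raw, cor))
        # borderline-z patients may flip either way; agreement must dominate
        assert mismatches <= 0.05 * 30 * 4
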