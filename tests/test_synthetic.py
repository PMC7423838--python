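import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from ntcpkit import cohort as syn
from ntcpkit.dvh import dose_at_volume
from ntcpkit.errors import ConfigurationError, ParameterError
from ntcpkit.io import build_feature_table

FRAC = syn.Fractionation(60.0, 30, 40, "conventional")


class TestSampleDVH:
    def test_step_limit(self, rng):
        # infinite steepness + full coverage -> step function at prescription
        shape = syn.StructureShape(
            falloff_steepness=1e6, coverage_fraction=1.0,
            midpoint_jitter_sd=0.0, steepness_jitter_sd=0.0,
        )
        c = syn.sample_dvh_curve(shape, FRAC, rng)
        below = c.dose_gy < 59.0
        above = c.dose_gy > 61.0
        assert np.allclose(c.volume_fraction[below], 1.0, atol=1e-6)
        assert np.allclose(c.volume_fraction[above], 0.0, atol=1e-6)

    def test_starts_at_one(self, rng):
        for _ in range(20):
            shape = syn.StructureShape(
                falloff_steepness=float(rng.uniform(1, 20)),
                coverage_fraction=float(rng.uniform(0.1, 1.0)),
            )
            c = syn.sample_dvh_curve(shape, FRAC, rng)
            assert c.volume_fraction[0] == 1.0

    def test_midpoint_matches_analytic_inversion(self, rng):
        # oracle: invert the generating function analytically with brentq
        shape = syn.StructureShape(
            falloff_steepness=12.0, coverage_fraction=0.5,
            midpoint_jitter_sd=0.0, steepness_jitter_sd=0.0, bin_width_gy=0.1,
        )
        c = syn.sample_dvh_curve(shape, FRAC, rng)
        m, slope, dmax = 30.0, 12.0 / 60.0, 72.0
        analytic = brentq(
            lambda d: syn.normalized_sigmoid(np.array([d]), m, slope, dmax)[0] - 0.5,
            0.0, dmax,
        )
        assert dose_at_volume(c, 50) == pytest.approx(analytic, abs=0.06)
        # with steep falloff the inversion sits at the nominal midpoint
        assert analytic == pytest.approx(m, rel=0.02)

    def test_max_dose_bounded(self, rng):
        for _ in range(50):
            shape = syn.StructureShape(
                falloff_steepness=float(rng.uniform(1, 20)),
                coverage_fraction=float(rng.uniform(0.1, 1.0)),
            )
            c = syn.sample_dvh_curve(shape, FRAC, rng)
            assert c.dose_gy[-1] <= 1.2 * FRAC.total_dose_gy + 1e-9
            assert c.volume_fraction[-1] == 0.0

    def test_invalid_shape_params(self):
        with pytest.raises(ParameterError):
            syn.StructureShape(falloff_steepness=-1.0, coverage_fraction=0.5)
        with pytest.raises(ParameterError):
            syn.StructureShape(falloff_steepness=5.0, coverage_fraction=1.5)

    def test_monotone_over_random_spec_draws(self, rng):
        # 1,000 random shape draws: every curve non-increasing within [0, 1]
        for _ in range(1000):
            shape = syn.StructureShape(
                falloff_steepness=float(rng.uniform(0.5, 30)),
                coverage_fraction=float(rng.uniform(0.05, 1.0)),
                midpoint_jitter_sd=float(rng.uniform(0, 0.4)),
                steepness_jitter_sd=float(rng.uniform(0, 0.5)),
            )
            c = syn.sample_dvh_curve(shape, FRAC, rng)
            v = c.volume_fraction
            assert v.min() >= 0.0 and v.max() <= 1.0
            assert np.all(np.diff(v) <= 1e-12)


class TestSampleClinical:
    def test_zero_smoker_shift_null_case(self):
        rng = np.random.default_rng(0)
        dists = syn.ClinicalDists(a2m_smoker_shift=(0.0, 0.0))
        recs = [syn.sample_clinical(dists, rng) for _ in range(4000)]
        a2m = np.array([r.a2m_mg_dl for r in recs])
        never = np.array([r.smoking_status == "never" for r in recs])
        # identical distributions: means agree within Monte Carlo error
        assert abs(a2m[never].mean() - a2m[~never].mean()) < 5.0

    def test_a2m_median_near_configured(self):
        rng = np.random.default_rng(1)
        dists = syn.ClinicalDists()
        a2m = np.array([syn.sample_clinical(dists, rng).a2m_mg_dl for _ in range(10_000)])
        assert abs(np.median(a2m) - 191.0) / 191.0 < 0.05

    def test_a2m_ordered_by_smoking(self):
        rng = np.random.default_rng(2)
        dists = syn.ClinicalDists()
        recs = [syn.sample_clinical(dists, rng) for _ in range(10_000)]
        means = {
            s: np.mean([r.a2m_mg_dl for r in recs if r.smoking_status == s])
            for s in ("never", "former", "current")
        }
        assert means["never"] < means["former"] < means["current"]

    def test_smoking_frequencies_converge(self):
        rng = np.random.default_rng(3)
        dists = syn.ClinicalDists(smoking_probs=(0.18, 0.70, 0.12))
        recs = [syn.sample_clinical(dists, rng) for _ in range(10_000)]
        freq = pd.Series([r.smoking_status for r in recs]).value_counts(normalize=True)
        assert freq["never"] == pytest.approx(0.18, abs=0.02)
        assert freq["former"] == pytest.approx(0.70, abs=0.02)
        assert freq["current"] == pytest.approx(0.12, abs=0.02)

    def test_invalid_probs_rejected(self):
        with pytest.raises(ParameterError):
            syn.ClinicalDists(smoking_probs=(0.5, 0.5, 0.5))


class TestAssignOutcomes:
    def test_null_model_hits_intercept_rate(self):
        rng = np.random.default_rng(4)
        feats = pd.DataFrame({"f": rng.normal(size=20_000)})
        p = 0.2
        model = syn.OutcomeModel(
            endpoint="e", coefficients={"f": 0.0}, intercept=float(np.log(p / (1 - p)))
        )
        grades = syn.assign_outcomes(feats, model, rng)
        assert (grades >= 2).mean() == pytest.approx(0.2, abs=0.015)

    def test_degenerate_intercept_no_events(self):
        rng = np.random.default_rng(5)
        feats = pd.DataFrame({"f": rng.normal(size=500)})
        model = syn.OutcomeModel(endpoint="e", coefficients={"f": 0.0}, intercept=-50.0)
        grades = syn.assign_outcomes(feats, model, rng)
        assert (grades < 2).all()

    def test_huge_beta_concentrates_events_at_top(self):
        rng = np.random.default_rng(6)
        feats = pd.DataFrame({"f": rng.normal(size=2000)})
        model = syn.OutcomeModel(endpoint="e", coefficients={"f": 25.0}, intercept=0.0)
        grades = syn.assign_outcomes(feats, model, rng)
        events = grades >= 2
        from scipy.stats import rankdata

        r = rankdata(feats["f"])
        # events occupy the top of the feature distribution
        assert r[events].mean() > np.quantile(r, 0.7)

    def test_missing_feature_is_config_error(self, rng):
        feats = pd.DataFrame({"f": [1.0, 2.0]})
        model = syn.OutcomeModel(endpoint="e", coefficients={"g": 1.0}, intercept=0.0)
        with pytest.raises(ConfigurationError, match="g"):
            syn.assign_outcomes(feats, model, rng)

    def test_grade_split_probs_validated(self):
        with pytest.raises(ParameterError):
            syn.OutcomeModel(
                endpoint="e", coefficients={}, intercept=0.0, event_grade_probs={2: 0.5}
            )


class TestGenerateCohort:
    def test_determinism(self):
        spec = syn.default_spec(n_patients=40, seed=9)
        a = syn.generate_cohort(spec)
        b = syn.generate_cohort(spec)
        assert a.clinical == b.clinical
        assert a.grades.equals(b.grades)
        for ca, cb in zip(a.dvhs, b.dvhs):
            assert np.array_equal(ca.dose_gy, cb.dose_gy)
            assert np.array_equal(ca.volume_fraction, cb.volume_fraction)

    def test_counts_match_study_size(self, default_cohort):
        assert len(default_cohort.clinical) == 258
        assert len(default_cohort.dvhs) == 258 * 3
        assert set(default_cohort.grades.columns) == {"esophagitis", "pneumonitis"}

    def test_different_seeds_differ(self):
        a = syn.generate_cohort(syn.default_spec(n_patients=30, seed=1))
        b = syn.generate_cohort(syn.default_spec(n_patients=30, seed=2))
        assert [r.a2m_mg_dl for r in a.clinical] != [r.a2m_mg_dl for r in b.clinical]

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ParameterError):
            syn.CohortSpec(n_patients=5)

    def test_adjacent_dx_collinearity(self, default_features):
        # the decorrelation stage's premise: adjacent Dx are highly correlated
        f = default_features.data
        for a, b in [("esophagus_D25", "esophagus_D30"), ("lung_D25", "lung_D30")]:
            assert np.corrcoef(f[a], f[b])[0, 1] > 0.75

    def test_event_prevalence_at_large_n(self):
        # esophagus-only spec keeps the n=10,000 check affordable
        esoph = syn.default_outcome_models()[0]
        spec = syn.CohortSpec(
            n_patients=10_000, seed=12, structure_names=("esophagus",),
            outcome_models=(esoph,),
        )
        cohort = syn.generate_cohort(spec)
        rate = (cohort.grades["esophagitis"] >= 2).mean()
        assert abs(rate - 0.236) < 0.03

    def test_truth_roundtrip(self, tmp_path):
        import json

        models = syn.default_outcome_models()
        path = tmp_path / "truth.json"
        syn.write_truth_json(models, path)
        payload = json.loads(path.read_text())
        assert payload[0]["endpoint"] == "esophagitis"
        assert payload[0]["coefficients"] == dict(models[0].coefficients)
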