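"""Virtual population sampling, CKD scenarios and diagnostics."""

import dataclasses

import numpy as np
import pytest

import renalpbpk as rp
from renalpbpk import virtual_population as vpop


def medians(subjects, attr):
    return float(np.median([getattr(s, attr) for s in subjects]))


@pytest.fixture(scope="module")
def healthy_1000():
    return rp.sample_population(vpop.healthy_spec(), 1000, 123)


@pytest.fixture(scope="module")
def severe_1000():
    return rp.sample_population(vpop.ckd_spec("severe"), 1000, 123)


class TestDeterminism:
    def test_same_seed_same_population(self):
        a = rp.sample_population(vpop.healthy_spec(), 20, 5)
        b = rp.sample_population(vpop.healthy_spec(), 20, 5)
        assert a == b
        c = rp.sample_population(vpop.healthy_spec(), 20, 6)
        assert a != c

    def test_prefix_stability(self):
        """Growing n extends the subject list without reshuffling it."""
        small = rp.sample_population(vpop.healthy_spec(), 10, 5)
        big = rp.sample_population(vpop.healthy_spec(), 40, 5)
        assert big[:10] == small


class TestDistributionCalibration:
    def test_healthy_gfr_median_and_range(self, healthy_1000):
        gfr = np.array([s.gfr for s in healthy_1000])
        assert np.median(gfr) == pytest.approx(114.0, rel=0.10)
        lo, hi = np.quantile(gfr, [0.05, 0.95])
        assert lo == pytest.approx(87.3, rel=0.15)
        assert hi == pytest.approx(166.0, rel=0.15)

    def test_severe_gfr_median(self, severe_1000):
        assert medians(severe_1000, "gfr") == pytest.approx(21.0, rel=0.10)

    def test_severe_albumin_median(self, severe_1000):
        assert medians(severe_1000, "hsa") == pytest.approx(36.7, rel=0.10)

    def test_severity_partition(self, severe_1000):
        for s in severe_1000:
            assert 15.0 <= s.gfr_bsa < 30.0
        moderate = rp.sample_population(vpop.ckd_spec("moderate"), 300, 9)
        for s in moderate:
            assert 30.0 <= s.gfr_bsa <= 60.0

    def test_lognormal_medians_and_cv_converge(self):
        subjects = rp.sample_population(vpop.healthy_spec(), 4000, 77)
        ptc = np.array([s.ptcpgk for s in subjects])
        oat = np.array([s.oat1_rel for s in subjects])
        assert np.median(ptc) == pytest.approx(60.0, rel=0.03)
        assert np.std(ptc) / np.mean(ptc) == pytest.approx(0.30, rel=0.12)
        assert np.median(oat) == pytest.approx(1.0, rel=0.05)
        assert np.std(oat) / np.mean(oat) == pytest.approx(0.60, rel=0.12)

    def test_zero_variance_spec_degenerates_to_fixed_subject(self):
        spec = dataclasses.replace(
            vpop.healthy_spec(), age_range=(40.0, 40.0), sex_ratio=1.0,
            gfr_bsa_cv=0.0, weight_cv=0.0, ptcpgk_cv=0.0, oat1_cv=0.0,
            mate_cv=0.0, kidney_weight_cv=0.0, co_cv=0.0, hsa_sd=0.0,
            hct_sd=0.0, height_mean={"M": 176.0, "F": 163.0},
            height_sd={"M": 0.0, "F": 0.0})
        subjects = rp.sample_population(spec, 5, 3)
        assert all(s == subjects[0] for s in subjects)


class TestScenarios:
    def test_table_factors(self):
        base = rp.sample_subject(vpop.ckd_spec("severe"), 11)
        inh = rp.apply_ckd_scenario(base, rp.CkdScenario("inh_ptcpgk",
                                                         "severe"))
        assert inh.ptcpgk == pytest.approx(base.ptcpgk * 10.2 / 60.0)
        oat = rp.apply_ckd_scenario(base, rp.CkdScenario("inh_oat1",
                                                         "moderate"))
        assert oat.oat1_rel == pytest.approx(base.oat1_rel * 0.35)
        ure = rp.apply_ckd_scenario(base, rp.CkdScenario("inh_ptcpgk_uremic",
                                                         "severe"))
        assert ure.oat1_activity_scale == pytest.approx(0.41)
        assert ure.ptcpgk == pytest.approx(base.ptcpgk * 10.2 / 60.0)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(vpop.PopulationError):
            rp.CkdScenario("inh_everything", "severe")
        with pytest.raises(vpop.PopulationError):
            rp.CkdScenario("default", "mild")

    def test_cellularity_and_abundance_parameterizations_equivalent(self,
                                                                    drug):
        """Equal PTCPGK x OAT1 products (cellularity-loss vs abundance-loss
        hypotheses) give identical whole-kidney secretion and identical CL_R
        on the same sampled subject."""
        for seed in (1, 2, 3):
            base = rp.sample_subject(vpop.ckd_spec("severe"), seed)
            a = rp.apply_ckd_scenario(base, rp.CkdScenario("inh_ptcpgk",
                                                           "severe"))
            b = rp.apply_ckd_scenario(base, rp.CkdScenario("inh_oat1",
                                                           "severe"))
            assert a.ptcpgk * a.oat1_rel == pytest.approx(
                b.ptcpgk * b.oat1_rel, rel=1e-15)
            flows = rp.build_flow_profile(base.gfr, 1.0)
            ma = rp.disposition_moments(a, drug, flows)
            mb = rp.disposition_moments(b, drug, flows)
            assert ma["cl_r"] == pytest.approx(mb["cl_r"], rel=1e-12)


class TestGeriatrics:
    def test_geriatric_population_medians(self, healthy_1000):
        ger = rp.sample_population(vpop.geriatric_spec(), 1000, 123)
        gfr_ratio = medians(ger, "gfr") / medians(healthy_1000, "gfr")
        co_ratio = medians(ger, "cardiac_output") \
            / medians(healthy_1000, "cardiac_output")
        assert 1.0 - gfr_ratio == pytest.approx(0.45, abs=0.05)
        assert 1.0 - co_ratio == pytest.approx(0.19, abs=0.05)
        # kidney weight and urine flow unaffected by age
        kw_ratio = medians(ger, "kidney_weight") \
            / medians(healthy_1000, "kidney_weight")
        assert kw_ratio == pytest.approx(1.0, abs=0.10)
        assert medians(ger, "urine_flow") == medians(healthy_1000,
                                                     "urine_flow")

    def test_covariate_continuity_at_65(self):
        base = rp.sample_subject(vpop.geriatric_spec(), 4)
        base65 = dataclasses.replace(base, age=65.0)
        again = vpop.geriatric_covariates(65.0, base65)
        assert again == base65

    def test_age_out_of_range(self):
        base = rp.sample_subject(vpop.geriatric_spec(), 4)
        with pytest.raises(vpop.PopulationError):
            vpop.geriatric_covariates(50.0, base)


class TestDiagnostics:
    def test_pooled_populations_flag_gfr_gap(self, healthy_1000, severe_1000):
        diag = rp.population_diagnostics(list(healthy_1000)
                                         + list(severe_1000))
        assert diag["gaps"], "expected an empty band between severity classes"
        lo, hi = diag["gaps"][0]
        assert 30.0 <= lo <= 70.0 and hi <= 95.0

    def test_single_smooth_population_no_gap(self, healthy_1000):
        diag = rp.population_diagnostics(list(healthy_1000))
        assert diag["gaps"] == []

    def test_identical_subjects_marked_degenerate(self):
        s = rp.sample_subject(vpop.healthy_spec(), 1)
        diag = rp.population_diagnostics([s, s, s])
        assert "gfr" in diag["zero_variance"]
        assert np.isnan(diag["correlations"].loc["gfr", "age"])

    def test_requires_two_subjects(self):
        with pytest.raises(vpop.PopulationError):
            rp.population_diagnostics([rp.sample_subject(vpop.healthy_spec(),
                                                         1)])
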