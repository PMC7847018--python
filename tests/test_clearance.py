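import numpy as np
import pytest

from crrtpk.clearance import (
    adsorption_percent,
    cl_tm_by_auc,
    cl_tm_by_scsa,
    protein_binding,
    saturation_coefficient,
    sc_sa_for_record,
    sc_variants,
    sieving_coefficient,
)
from crrtpk.core import Analyte, CircuitConfig, ConcentrationSeries, Filter, Mode, Site
from crrtpk.nca import nca_complete
from crrtpk.simulate import SimulationSpec, simulate_open_circuit

from conftest import bolus_record


class TestCoefficients:
    @pytest.mark.parametrize(
        "c_uf,c_pre,expected", [(100.0, 100.0, 1.0), (61.4, 100.0, 0.614), (0.0, 50.0, 0.0)]
    )
    def test_sieving_coefficient(self, c_uf, c_pre, expected):
        assert sieving_coefficient(c_uf, c_pre) == pytest.approx(expected)

    def test_sieving_undefined_for_nonpositive_pre(self):
        with pytest.raises(ValueError):
            sieving_coefficient(10.0, 0.0)

    @pytest.mark.parametrize(
        "c_d,c_pre,c_post,expected",
        [(90.0, 100.0, 80.0, 1.0), (54.0, 100.0, 80.0, 0.6), (0.0, 100.0, 80.0, 0.0)],
    )
    def test_saturation_coefficient(self, c_d, c_pre, c_post, expected):
        assert saturation_coefficient(c_d, c_pre, c_post) == pytest.approx(expected)

    def test_saturation_degenerate_denominator(self):
        with pytest.raises(ValueError):
            saturation_coefficient(10.0, 0.0, 0.0)

    def test_per_record_value_averages_the_paired_times(self, cvvh_config):
        spec = SimulationSpec(
            config=cvvh_config, CL_true=1.9, sc_true=0.6, noise_cv=0.0
        )
        rec = simulate_open_circuit(spec)
        assert sc_sa_for_record(rec) == pytest.approx(0.6, rel=1e-12)


class TestClTmByScSa:
    def test_cvvh_postdilution_matches_reported_value(self):
        cfg = CircuitConfig(Mode.CVVH, Filter.HF1400, 2.0, dilution_split=0.0)
        est = cl_tm_by_scsa(0.614, cfg)
        assert est.CL_TM == pytest.approx(1.228, abs=1e-12)  # prints 1.23

    def test_cvvhd_is_sa_times_dialysate_flow(self):
        cfg = CircuitConfig(Mode.CVVHD, Filter.HF1400, 4.0)
        est = cl_tm_by_scsa(0.601, cfg)
        assert est.CL_TM == pytest.approx(2.404)  # prints 2.40
        assert not est.dilution_corrected

    def test_predilution_correction_factor(self):
        cfg = CircuitConfig(Mode.CVVH, Filter.HF1400, 2.0, dilution_split=1.0)
        corrected = cl_tm_by_scsa(0.531, cfg, dilution_corrected=True)
        assert corrected.CL_TM == pytest.approx(0.531 * 2 * 12 / 14, rel=1e-12)
        uncorrected = cl_tm_by_scsa(0.531, cfg)
        assert uncorrected.CL_TM == pytest.approx(1.062)

    def test_correction_only_matters_with_prefilter_fluid(self):
        post = CircuitConfig(Mode.CVVH, Filter.M150, 2.0, dilution_split=0.0)
        a = cl_tm_by_scsa(0.6, post, dilution_corrected=True).CL_TM
        b = cl_tm_by_scsa(0.6, post, dilution_corrected=False).CL_TM
        assert a == b

    def test_cvvhd_linear_in_flow(self):
        cls = [
            cl_tm_by_scsa(0.6, CircuitConfig(Mode.CVVHD, Filter.M150, q)).CL_TM
            for q in (1.0, 2.0, 4.0)
        ]
        assert cls[1] == pytest.approx(2 * cls[0])
        assert cls[2] == pytest.approx(4 * cls[0])


class TestClTmByAuc:
    def test_recovers_true_clearance_noiseless(self, cvvh_config):
        spec = SimulationSpec(config=cvvh_config, CL_true=1.9, sc_true=0.6, noise_cv=0.0)
        rec = simulate_open_circuit(spec)
        est = cl_tm_by_auc(nca_complete(rec), rec.dose_mg)
        assert est.CL_TM == pytest.approx(1.9, abs=1e-6)

    def test_dose_proportionality_cancels(self, cvvh_config):
        rec1 = bolus_record(cvvh_config, dose_mg=0.124, c0=104.0, k_per_h=0.9)
        rec2 = bolus_record(cvvh_config, dose_mg=0.248, c0=208.0, k_per_h=0.9)
        cl1 = cl_tm_by_auc(nca_complete(rec1), rec1.dose_mg).CL_TM
        cl2 = cl_tm_by_auc(nca_complete(rec2), rec2.dose_mg).CL_TM
        assert cl1 == pytest.approx(cl2, rel=1e-12)

    def test_agrees_with_nca_clearance(self, cvvh_config):
        rec = bolus_record(cvvh_config, dose_mg=0.124, c0=104.0, k_per_h=0.9)
        res = nca_complete(rec)
        assert cl_tm_by_auc(res, rec.dose_mg).CL_TM == pytest.approx(res.CL, rel=1e-15)

    def test_both_estimators_agree_on_consistent_circuit(self):
        """When the simulated SC is chosen consistent with CL = SC·Q_uf, the
        AUC and SC routes measure the same elimination."""
        cfg = CircuitConfig(Mode.CVVH, Filter.HF1400, 2.0, dilution_split=0.0)
        cl_true = 1.2
        spec = SimulationSpec(
            config=cfg, CL_true=cl_true, sc_true=cl_true / 2.0, noise_cv=0.0
        )
        rec = simulate_open_circuit(spec)
        by_auc = cl_tm_by_auc(nca_complete(rec), rec.dose_mg).CL_TM
        by_sc = cl_tm_by_scsa(sc_sa_for_record(rec), cfg).CL_TM
        assert by_auc == pytest.approx(by_sc, rel=0.02)


class TestScVariants:
    def make_cfg(self, split):
        return CircuitConfig(Mode.CVVH, Filter.HF1400, 2.0, dilution_split=split)

    def test_all_sites_equal_gives_unity_everywhere(self):
        out = sc_variants(
            50.0, self.make_cfg(0.5),
            C_pre_undiluted=50.0, C_pre_diluted=50.0,
            C_post_undiluted=50.0, C_post_diluted=50.0,
        )
        assert set(out) == {
            "pre_undiluted", "pre_diluted", "pre_diluted_corrected",
            "mean_pre_post_undiluted", "mean_pre_post_diluted",
        }
        # correction factor rescales the otherwise-unity diluted variant
        cfg = self.make_cfg(0.5)
        cf = (cfg.blood_flow_Qb + cfg.Q_rep_pre) / cfg.blood_flow_Qb
        assert out["pre_diluted_corrected"] == pytest.approx(1 / cf)
        for key in ("pre_undiluted", "pre_diluted", "mean_pre_post_undiluted"):
            assert out[key] == pytest.approx(1.0)

    def test_postdilution_variants_coincide(self):
        out = sc_variants(
            60.0, self.make_cfg(0.0), C_pre_undiluted=100.0, C_pre_diluted=100.0
        )
        assert out["pre_undiluted"] == out["pre_diluted"]
        assert out["pre_diluted_corrected"] == out["pre_diluted"]  # CF = 1

    def test_correction_cancels_true_predilution(self):
        cfg = self.make_cfg(1.0)  # 100/0%
        qb, qrep = cfg.blood_flow_Qb, cfg.Q_rep_pre
        c_pre_undil = 100.0
        c_pre_dil = c_pre_undil * qb / (qb + qrep)
        out = sc_variants(
            60.0, cfg, C_pre_undiluted=c_pre_undil, C_pre_diluted=c_pre_dil
        )
        assert out["pre_diluted_corrected"] == pytest.approx(
            out["pre_undiluted"], rel=1e-12
        )

    def test_missing_everything_raises(self):
        with pytest.raises(ValueError):
            sc_variants(60.0, self.make_cfg(0.5))


class TestAdsorption:
    def series(self, pct_missing, dose=0.124, volume=1.19):
        times = np.array([0.0, 10.0, 30.0, 180.0])
        conc = 1000.0 * dose * (1 - np.asarray(pct_missing)) / volume
        return ConcentrationSeries(Site.reservoir, Analyte.apixaban, times, conc)

    def test_full_recovery_is_zero_adsorption(self):
        res = adsorption_percent(self.series([0, 0, 0, 0]), 0.124, 1.19)
        assert res.percent_adsorbed_peak == 0.0
        assert res.percent_adsorbed_final == 0.0

    def test_38_percent_missing_at_peak(self):
        res = adsorption_percent(self.series([0, 0.38, 0.3, 0.2]), 0.124, 1.19)
        assert res.percent_adsorbed_peak == pytest.approx(38.0, abs=1e-9)
        assert res.percent_adsorbed_final == pytest.approx(20.0, abs=1e-9)

    def test_negative_adsorption_warned_and_preserved_in_profile(self):
        with pytest.warns(UserWarning, match="negative adsorption"):
            res = adsorption_percent(self.series([0, -0.02, 0.1, 0.05]), 0.124, 1.19)
        assert res.profile_percent[1] == pytest.approx(-2.0, abs=1e-9)
        assert res.percent_adsorbed_peak == pytest.approx(10.0, abs=1e-9)  # clipped summary

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError):
            adsorption_percent(self.series([0, 0, 0, 0]), 0.0, 1.19)


class TestProteinBinding:
    def test_fully_bound(self):
        assert protein_binding(100.0, 0.0).fraction_bound == 100.0

    def test_reported_direction_check(self):
        assert protein_binding(100.0, 29.19).fraction_bound == pytest.approx(70.81)

    def test_fully_unbound(self):
        assert protein_binding(100.0, 100.0).fraction_bound == 0.0

    def test_unbound_above_total_beyond_tolerance_rejected(self):
        with pytest.raises(ValueError):
            protein_binding(100.0, 110.0)

    def test_vector_input_reports_intra_assay_cv(self):
        res = protein_binding([100.0, 100.0], [29.0, 31.0])
        assert res.fraction_bound == pytest.approx(70.0)
        assert res.intra_assay_cv > 0
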