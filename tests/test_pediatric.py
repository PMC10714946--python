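"""Pediatric extrapolation, renal scaling and dose-band logic."""

import numpy as np
import pandas as pd
import pytest

from tirzepbpk.calibration import _single_dose_metrics
from tirzepbpk.errors import DomainError
from tirzepbpk.pediatric import (
    CANDIDATE_DOSES_MG, ClearanceScalingInputs, ReferenceRange, extrapolate,
    find_dose_band, scale_renal_clearance,
)
from tirzepbpk.physiology import build_individual


class TestRenalScaling:
    def test_direct_product(self):
        inp = ClearanceScalingInputs(gfr_pediatric=96.0, gfr_adult=120.0,
                                     fu_pediatric=0.01, fu_adult=0.01,
                                     cl_renal_adult=0.0236)
        assert scale_renal_clearance(inp) == pytest.approx(0.8 * 0.0236)

    def test_identity_ratios(self):
        inp = ClearanceScalingInputs(100, 100, 0.01, 0.01, 0.05)
        assert scale_renal_clearance(inp) == 0.05

    def test_hand_arithmetic(self):
        inp = ClearanceScalingInputs(100, 120, 0.01, 0.01, 0.03)
        assert scale_renal_clearance(inp) == pytest.approx(0.025)

    def test_linear_in_each_ratio(self):
        base = ClearanceScalingInputs(100, 120, 0.01, 0.01, 0.03)
        doubled = ClearanceScalingInputs(200, 120, 0.01, 0.01, 0.03)
        assert scale_renal_clearance(doubled) == pytest.approx(
            2 * scale_renal_clearance(base))

    def test_non_positive_rejected(self):
        with pytest.raises(DomainError):
            ClearanceScalingInputs(0.0, 120, 0.01, 0.01, 0.03)


class TestExtrapolate:
    def test_adult_passthrough_is_identity(self, calibrated_model):
        same = extrapolate(calibrated_model, calibrated_model.individual)
        assert same.cl_renal == pytest.approx(calibrated_model.cl_renal)
        assert same.cl_pept_factor == calibrated_model.cl_pept_factor
        a = _single_dose_metrics(calibrated_model, 5.0, 1500.0, 0.5)
        b = _single_dose_metrics(same, 5.0, 1500.0, 0.5)
        assert a["auc_0_inf"] == pytest.approx(b["auc_0_inf"], rel=1e-9)

    def test_drug_parameters_carried_bit_exactly(self, calibrated_model):
        child = build_individual(11, "male", "normal", seed=4)
        model = extrapolate(calibrated_model, child)
        assert model.drug is calibrated_model.drug
        assert model.ka == calibrated_model.ka

    def test_child_exposure_exceeds_adult_reference_upper_bound(
            self, calibrated_model):
        child = build_individual(10, "male", "normal", seed=None)
        model = extrapolate(calibrated_model, child)
        m = _single_dose_metrics(model, 5.0, 1500.0, 0.5)
        assert m["auc_0_168"] > 63467

    def test_obese_teen_has_lower_exposure_than_normal(self, calibrated_model):
        normal = build_individual(13, "male", "normal", seed=6)
        obese = build_individual(13, "male", "obese", seed=6)
        auc_n = _single_dose_metrics(extrapolate(calibrated_model, normal),
                                     5.0, 1500.0, 0.5)["auc_0_168"]
        auc_o = _single_dose_metrics(extrapolate(calibrated_model, obese),
                                     5.0, 1500.0, 0.5)["auc_0_168"]
        assert auc_o < auc_n

    def test_renal_clearance_follows_gfr_ratio(self, calibrated_model):
        child = build_individual(11, "female", "normal", seed=4)
        model = extrapolate(calibrated_model, child)
        ratio = child.gfr / calibrated_model.individual.gfr
        assert model.cl_renal == pytest.approx(
            calibrated_model.cl_renal * ratio)


def _linear_exposure(auc5: float, cmax5: float) -> pd.DataFrame:
    """Synthetic population whose mean exposure is exactly dose-proportional."""
    rows = [{"id": 0, "dose_mg": d, "auc_0_168": auc5 * d / 5.0,
             "cmax": cmax5 * d / 5.0} for d in CANDIDATE_DOSES_MG]
    return pd.DataFrame(rows)


class TestDoseBandLogic:
    ref = ReferenceRange(auc_0_168=(43459, 63467), cmax=(305.7, 488.3),
                         tmax=(24, 72))

    def _band(self, auc5, cmax5):
        return find_dose_band(None, None, ref=self.ref,
                              exposure=_linear_exposure(auc5, cmax5))

    def test_linear_oracle_band(self):
        # 5 mg mean 90000: doses d qualify iff 43459 <= 90000*d/5 <= 63467,
        # i.e. d in [2.415, 3.526] -> {2.5, 3.125}
        rec = self._band(90000.0, 740.0)
        assert rec.qualifying_doses == (2.5, 3.125)
        assert rec.dose_band_mg == (2.5, 3.125)

    def test_only_top_dose_qualifying_means_no_adjustment(self):
        # 5 mg mean 46000: 4.375 -> 40250 < 43459, so only 5 mg qualifies
        rec = self._band(46000.0, 370.0)
        assert rec.no_adjustment and rec.dose_band_mg is None
        assert rec.label == "no_adjustment"

    def test_nothing_qualifying_returns_diagnostics(self):
        rec = self._band(300000.0, 2500.0)
        assert rec.dose_band_mg is None and not rec.no_adjustment
        assert rec.diagnostics is not None and not rec.diagnostics["qualifies"].any()

    def test_band_requires_both_metrics_in_range(self):
        # AUC in range at 5 mg but Cmax far too high -> 5 mg must not qualify
        rec = self._band(50000.0, 2000.0)
        assert 5.0 not in rec.qualifying_doses

    def test_band_monotone_under_linearity(self):
        # under linear PK the qualifying set is always contiguous
        for auc5 in (50000.0, 70000.0, 90000.0, 110000.0):
            rec = self._band(auc5, auc5 / 123.0)
            doses = sorted(rec.qualifying_doses)
            if len(doses) > 1:
                grid = sorted(CANDIDATE_DOSES_MG)
                i0, i1 = grid.index(doses[0]), grid.index(doses[-1])
                assert doses == grid[i0:i1 + 1]

    def test_bundled_reference_range(self):
        ref = ReferenceRange.bundled()
        assert ref.auc_0_168 == (43459, 63467)
        assert ref.cmax == (305.7, 488.3)
        assert ref.tmax == (24, 72)
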