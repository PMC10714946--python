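"""PBPK engine: solver agreement, mass balance, elimination structure."""

import numpy as np
import pytest

from tirzepbpk.engine import (
    DoseRegimen, build_model, simulate, simulate_regimen_table,
)
from tirzepbpk.errors import DomainError, ValidationError
from tirzepbpk.nca import compute_nca


class TestDoseRegimen:
    def test_weekly_expansion(self):
        reg = DoseRegimen.parse("5:8")
        assert reg.events == [(i * 168.0, 5.0) for i in range(8)]

    def test_stage_expansion(self):
        reg = DoseRegimen.parse("2.5:2+5:2+10:4")
        assert len(reg.events) == 8
        assert reg.events[0] == (0.0, 2.5)
        assert reg.events[-1] == (7 * 168.0, 10.0)

    def test_four_week_regimen(self):
        assert len(DoseRegimen.parse("4.5:4").events) == 4

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValidationError):
            DoseRegimen(events=[(0.0, 5.0), (0.0, 5.0)])

    def test_non_positive_dose_rejected(self):
        with pytest.raises(ValidationError):
            DoseRegimen(events=[(0.0, 0.0)])


class TestSimulate:
    def test_solver_routes_agree(self, default_model):
        reg = DoseRegimen.single(5.0)
        a = simulate(default_model, reg, 1500.0, method="analytic")
        b = simulate(default_model, reg, 1500.0, method="lsoda")
        scale = a.conc.max()
        assert np.max(np.abs(a.conc - b.conc)) / scale < 1e-6

    def test_solver_routes_agree_multidose(self, default_model):
        reg = DoseRegimen.weekly(5.0, 4)
        a = simulate(default_model, reg, 4 * 168.0, method="analytic")
        b = simulate(default_model, reg, 4 * 168.0, method="bdf")
        assert np.max(np.abs(a.conc - b.conc)) / a.conc.max() < 1e-6

    def test_mass_balance_exact_on_integrals(self, default_model):
        """F x dose equals total renal + peptidase elimination at t -> inf."""
        y = default_model.integral_states(5.0)
        r, p = default_model._elimination_vectors
        administered = default_model.drug.bioavailability * 5.0e6
        assert (r @ y + p @ y) == pytest.approx(administered, rel=1e-9)

    def test_eliminated_amounts_accumulate(self, default_model):
        prof = simulate(default_model, DoseRegimen.single(5.0), 1500.0,
                        method="analytic")
        renal = prof.amounts_eliminated["renal"]
        pept = prof.amounts_eliminated["peptidase"]
        assert np.all(np.diff(renal) >= -1e-6)
        total = renal[-1] + pept[-1]
        administered = default_model.drug.bioavailability * 5.0e6
        assert total < administered
        assert total > 0.99 * administered * (1 - np.exp(
            -default_model.terminal_slope() * 1500.0))

    def test_zero_dose_gives_zero_concentration(self, default_model):
        prof = simulate(default_model, DoseRegimen(events=[]), 500.0)
        assert np.all(prof.conc == 0.0)

    def test_t_end_before_last_dose_rejected(self, default_model):
        with pytest.raises(DomainError):
            simulate(default_model, DoseRegimen.weekly(5.0, 4), 100.0)

    def test_exposure_increases_with_dose(self, default_model):
        aucs, cmaxes = [], []
        for dose in (2.5, 5.0, 8.0):
            prof = simulate(default_model, DoseRegimen.single(dose), 1500.0,
                            method="analytic")
            pk = compute_nca(prof, dose)
            aucs.append(pk.auc_0_inf)
            cmaxes.append(pk.cmax)
        assert aucs == sorted(aucs) and cmaxes == sorted(cmaxes)


class TestEliminationStructure:
    def test_urine_fraction_constraint_honoured(self, default_model):
        assert default_model.urine_fraction() == pytest.approx(0.66, abs=1e-6)

    def test_renal_only_elimination(self, adult, drug, adult_distribution):
        model = build_model(adult, drug, distribution=adult_distribution,
                            cl_pept_factor=0.0, cl_renal=0.03)
        assert model.urine_fraction() == 1.0

    def test_default_adult_clearance_in_two_fold_window(self, default_model):
        pk = compute_nca(simulate(default_model, DoseRegimen.single(5.0),
                                  1500.0, method="analytic"), 5.0)
        assert 0.5 * 0.0442 <= pk.cl_over_f <= 2 * 0.0442

    def test_doubling_peptidase_doubles_nonrenal_clearance(
            self, adult, drug, adult_distribution, default_model):
        from dataclasses import replace
        drug2 = replace(drug, peptidase_conc=2.0)
        m2 = build_model(adult, drug2, distribution=adult_distribution,
                         ka=default_model.ka,
                         cl_pept_factor=default_model.cl_pept_factor,
                         cl_renal=default_model.cl_renal)

        def nonrenal_cl(model):
            y = model.integral_states(5.0)
            _, p = model._elimination_vectors
            return (p @ y) / (model.auc_inf_exact(5.0) * 1000.0)

        ratio = nonrenal_cl(m2) / nonrenal_cl(default_model)
        assert ratio == pytest.approx(2.0, rel=1e-2)


class TestRegimenTable:
    def test_last_interval_window(self, default_model):
        profs = simulate_regimen_table(default_model, ["5:8"])
        assert len(profs) == 1
        assert profs[0].times[0] == pytest.approx(7 * 168.0)
        assert profs[0].times[-1] == pytest.approx(8 * 168.0)

    def test_empty_list_gives_empty_output(self, default_model):
        assert simulate_regimen_table(default_model, []) == []
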