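"""Whole-body PBPK engine: SC depot → venous blood → organ network.

Model structure
---------------
A subcutaneous depot feeds venous plasma by first-order absorption
(dA_sc/dt = −ka·A_sc, with each dose event adding F·Dose to the depot).
Venous plasma perfuses the lung (in series, full cardiac output), arterial
plasma distributes to the systemic tissues in parallel; gut and spleen
drain through the liver (portal circulation). Tissue uptake is
flow-limited against tissue:plasma partition coefficients Kp (which, for a
large peptide, already encode the permeability restriction to accessible
extracellular water).

Elimination is linear everywhere:

* a hypothetical ubiquitous peptidase in every tissue with intrinsic
  clearance ``cl_spec · 60 · conc · V_organ · calibration_factor`` (L/h)
  acting on unbound emergent tissue concentration (× fu),
* renal elimination in the kidney with operative plasma clearance
  ``cl_renal`` (L/h), chosen so that the urine fraction of total
  elimination equals the target ``f_urine`` (0.66 by default).

Because every process is first order the full system is linear
time-invariant; ``simulate`` therefore offers two routes: the spec'd
implicit stiff solver (LSODA/BDF, rtol 1e-8, atol 1e-10) and an exact
eigendecomposition path used for calibration and population sweeps. Both
are cross-checked in the test suite.

Units: time h, amounts ng, volumes L, concentrations reported in ng/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .drug import DistributionInputs, DrugParameters, compute_distribution
from .errors import DomainError, IntegrationError, ValidationError
from .physiology import IndividualPhysiology, SYSTEMIC_ORGANS

MG_TO_NG = 1.0e6

#: Compartment order of the state vector.
STATE_LABELS = ("sc_depot", "venous", "arterial", "lung") + SYSTEMIC_ORGANS

_DIRECT_TO_VENOUS = (
    "adipose", "bone", "brain", "heart", "kidney", "muscle", "skin", "rest"
)
_PORTAL = ("gut", "spleen")


@dataclass
class DoseRegimen:
    """Subcutaneous dose events: (time_h, dose_mg), strictly increasing."""

    events: list[tuple[float, float]]
    route: str = "SC"

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(t < 0 for t in times):
            raise ValidationError("dose event times must be non-negative")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("dose event times must be strictly increasing")
        if any(d <= 0 for _, d in self.events):
            raise ValidationError("doses must be positive")

    @classmethod
    def single(cls, dose_mg: float, time_h: float = 0.0) -> "DoseRegimen":
        return cls(events=[(time_h, dose_mg)])

    @classmethod
    def weekly(cls, dose_mg: float, n_weeks: int,
               interval_h: float = 168.0) -> "DoseRegimen":
        return cls(events=[(i * interval_h, dose_mg) for i in range(n_weeks)])

    @classmethod
    def from_stages(cls, stages: list[tuple[float, int]],
                    interval_h: float = 168.0) -> "DoseRegimen":
        """Escalation stages [(dose_mg, n_weeks), ...] at weekly spacing."""
        events, t = [], 0.0
        for dose, weeks in stages:
            for _ in range(int(weeks)):
                events.append((t, dose))
                t += interval_h
        return cls(events=events)

    @classmethod
    def parse(cls, text: str, interval_h: float = 168.0) -> "DoseRegimen":
        """Parse ``"2.5:2+5:2+10:4"`` style stage strings."""
        stages = []
        for part in text.split("+"):
            dose, weeks = part.split(":")
            stages.append((float(dose), int(weeks)))
        return cls.from_stages(stages, interval_h)

    @property
    def total_dose_ng(self) -> float:
        return sum(d for _, d in self.events) * MG_TO_NG

    @property
    def last_dose_time(self) -> float:
        return self.events[-1][0] if self.events else 0.0


@dataclass
class ConcentrationProfile:
    """Simulated plasma curve with cumulative eliminated amounts."""

    times: np.ndarray                       # h, strictly increasing grid
    conc: np.ndarray                        # ng/mL venous plasma
    amounts_eliminated: dict[str, np.ndarray]  # {renal, peptidase} -> ng
    dose_ng: float = 0.0                    # total administered (not x F)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("time grid must be strictly increasing")
        if np.any(self.conc < -1e-9):
            raise ValidationError("negative concentrations in profile")
        self.conc = np.maximum(self.conc, 0.0)

    def window(self, t_start: float, t_end: float) -> "ConcentrationProfile":
        mask = (self.times >= t_start - 1e-9) & (self.times <= t_end + 1e-9)
        return ConcentrationProfile(
            times=self.times[mask],
            conc=self.conc[mask],
            amounts_eliminated={
                k: v[mask] for k, v in self.amounts_eliminated.items()
            },
            dose_ng=self.dose_ng,
        )


class PBPKModel:
    """Assembled whole-body model for one individual and one drug.

    Holds the physiology, drug record, partition coefficients and the
    three calibratable kinetic constants (``ka`` 1/h, ``cl_pept_factor``
    dimensionless scaling of the raw peptidase intrinsic clearance,
    ``cl_renal`` L/h operative renal plasma clearance).
    """

    def __init__(self, individual: IndividualPhysiology, drug: DrugParameters,
                 distribution: DistributionInputs, ka: float,
                 cl_pept_factor: float, cl_renal: float):
        if ka <= 0 or cl_pept_factor < 0 or cl_renal < 0:
            raise ValidationError("kinetic constants must be non-negative (ka > 0)")
        if cl_pept_factor == 0 and cl_renal == 0:
            raise ValidationError("model has no elimination pathway")
        self.individual = individual
        self.drug = drug
        self.distribution = distribution
        self.ka = float(ka)
        self.cl_pept_factor = float(cl_pept_factor)
        self.cl_renal = float(cl_renal)
        self._check_flows()

    def _check_flows(self) -> None:
        ind = self.individual
        total = sum(ind.organ_blood_flows.values())
        if total > ind.cardiac_output * (1 + 1e-9):
            raise ValidationError("organ blood flows exceed cardiac output")

    # -- structural pieces -------------------------------------------------

    @cached_property
    def plasma_flows(self) -> dict[str, float]:
        """Plasma flows (L/h): blood flows x (1 - hematocrit)."""
        hct = self.individual.hematocrit
        q = {o: f * (1 - hct) for o, f in self.individual.organ_blood_flows.items()}
        q["__co__"] = self.individual.cardiac_output * (1 - hct)
        return q

    @cached_property
    def volumes(self) -> dict[str, float]:
        v = dict(self.individual.organ_volumes)
        v["venous"] = v["plasma"] * (2.0 / 3.0)
        v["arterial"] = v["plasma"] / 3.0
        return v

    def clint_peptidase(self, organ: str) -> float:
        """Intrinsic peptidase clearance of one organ, L/h."""
        d = self.drug
        return (d.cl_spec_peptidase * 60.0 * d.peptidase_conc
                * self.individual.organ_volumes[organ] * self.cl_pept_factor)

    @cached_property
    def system_matrix(self) -> np.ndarray:
        """State matrix A of dx/dt = A x over :data:`STATE_LABELS`."""
        n = len(STATE_LABELS)
        idx = {name: i for i, name in enumerate(STATE_LABELS)}
        A = np.zeros((n, n))
        q = self.plasma_flows
        v = self.volumes
        kp = self.distribution.kp
        fu = self.drug.fu
        co = q["__co__"]

        def kout(organ: str) -> float:
            return 1.0 / (v[organ] * kp[organ])

        A[idx["sc_depot"], idx["sc_depot"]] = -self.ka
        A[idx["venous"], idx["sc_depot"]] = self.ka
        # venous inflows
        for organ in _DIRECT_TO_VENOUS:
            A[idx["venous"], idx[organ]] += q[organ] * kout(organ)
        q_liver_out = q["liver"] + q["gut"] + q["spleen"]
        A[idx["venous"], idx["liver"]] += q_liver_out * kout("liver")
        A[idx["venous"], idx["venous"]] -= co / v["venous"]
        # lung (in series) with peptidase
        A[idx["lung"], idx["venous"]] = co / v["venous"]
        A[idx["lung"], idx["lung"]] = -(co + fu * self.clint_peptidase("lung")) * kout("lung")
        A[idx["arterial"], idx["lung"]] = co * kout("lung")
        A[idx["arterial"], idx["arterial"]] = -co / v["arterial"]
        # systemic tissues
        for organ in SYSTEMIC_ORGANS:
            outflow = q_liver_out if organ == "liver" else q[organ]
            loss = outflow + fu * self.clint_peptidase(organ)
            if organ == "kidney":
                loss += self.cl_renal
            A[idx[organ], idx[organ]] = -loss * kout(organ)
            if organ == "liver":
                A[idx[organ], idx["arterial"]] = q["liver"] / v["arterial"]
                A[idx[organ], idx["gut"]] = q["gut"] * kout("gut")
                A[idx[organ], idx["spleen"]] = q["spleen"] * kout("spleen")
            else:
                A[idx[organ], idx["arterial"]] = q[organ] / v["arterial"]
        return A

    @cached_property
    def _elimination_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """Row vectors r, p with renal / peptidase rates = r·x, p·x (ng/h)."""
        n = len(STATE_LABELS)
        idx = {name: i for i, name in enumerate(STATE_LABELS)}
        v, kp, fu = self.volumes, self.distribution.kp, self.drug.fu
        r = np.zeros(n)
        r[idx["kidney"]] = self.cl_renal / (v["kidney"] * kp["kidney"])
        p = np.zeros(n)
        for organ in SYSTEMIC_ORGANS + ("lung",):
            p[idx[organ]] = fu * self.clint_peptidase(organ) / (v[organ] * kp[organ])
        return r, p

    @cached_property
    def _eig(self):
        A = self.system_matrix
        w, P = np.linalg.eig(A)
        Pinv = np.linalg.inv(P)
        if np.linalg.cond(P) > 1e12:
            raise IntegrationError("near-defective system matrix")
        return w, P, Pinv

    # -- derived quantities ------------------------------------------------

    def vss(self) -> float:
        """Steady-state distribution volume referenced to plasma, L."""
        v, kp = self.volumes, self.distribution.kp
        return (v["venous"] + v["arterial"]
                + sum(v[o] * kp[o] for o in SYSTEMIC_ORGANS + ("lung",)))

    def _bolus(self, dose_ng: float) -> np.ndarray:
        x = np.zeros(len(STATE_LABELS))
        x[0] = self.drug.bioavailability * dose_ng
        return x

    def integral_states(self, dose_mg: float = 5.0) -> np.ndarray:
        """∫0^∞ x(t) dt after a single SC dose (exact, via −A⁻¹ x0)."""
        x0 = self._bolus(dose_mg * MG_TO_NG)
        return np.linalg.solve(self.system_matrix, -x0)

    def auc_inf_exact(self, dose_mg: float) -> float:
        """Exact AUC_0-inf of venous plasma, ng·h/mL."""
        y = self.integral_states(dose_mg)
        return y[STATE_LABELS.index("venous")] / self.volumes["venous"] / 1000.0

    def urine_fraction(self) -> float:
        """Fraction of a dose eliminated renally (dose-independent)."""
        if self.cl_renal == 0:
            return 0.0
        if self.cl_pept_factor == 0:
            return 1.0
        y = self.integral_states(1.0)
        r, p = self._elimination_vectors
        renal, pept = float(r @ y), float(p @ y)
        return renal / (renal + pept)

    def terminal_slope(self) -> float:
        """Slowest system eigenvalue magnitude (1/h)."""
        w, _, _ = self._eig
        return float(np.min(np.abs(np.real(w[np.real(w) < -1e-15]))))


def build_model(individual: IndividualPhysiology, drug: DrugParameters,
                distribution: DistributionInputs | None = None,
                ka: float | None = None,
                cl_pept_factor: float | None = None,
                cl_renal: float | None = None,
                f_urine_target: float | None = None) -> PBPKModel:
    """Assemble a :class:`PBPKModel`.

    ``ka`` defaults to the drug record's absorption constant and
    ``cl_pept_factor`` to the package default calibration. If ``cl_renal``
    is not given it is solved (Brent's method on the linear system's
    eliminated-fraction) so that the urine fraction equals
    ``f_urine_target`` (default: the drug record's ``f_urine``).
    """
    from .calibration import DEFAULT_CALIBRATION  # circular-safe at call time

    if distribution is None:
        distribution = compute_distribution(drug, individual)
    if ka is None:
        ka = drug.ka
    if cl_pept_factor is None:
        cl_pept_factor = DEFAULT_CALIBRATION["cl_pept_factor"]
    if cl_renal is None:
        target = drug.f_urine if f_urine_target is None else f_urine_target
        cl_renal = solve_renal_clearance(
            individual, drug, distribution, ka, cl_pept_factor, target
        )
    return PBPKModel(individual, drug, distribution, ka, cl_pept_factor, cl_renal)


def solve_renal_clearance(individual: IndividualPhysiology,
                          drug: DrugParameters,
                          distribution: DistributionInputs,
                          ka: float, cl_pept_factor: float,
                          f_urine: float,
                          bracket: tuple[float, float] = (1e-6, 50.0)) -> float:
    """Renal plasma clearance (L/h) yielding the requested urine fraction."""
    if not 0 < f_urine < 1:
        raise DomainError("f_urine target must be in (0, 1) to solve cl_renal")

    def gap(clr: float) -> float:
        m = PBPKModel(individual, drug, distribution, ka, cl_pept_factor, clr)
        return m.urine_fraction() - f_urine

    lo, hi = bracket
    return float(brentq(gap, lo, hi, xtol=1e-10, rtol=1e-12))


# ---------------------------------------------------------------------------
# Simulation


def _output_grid(t_end: float, dt_out: float) -> np.ndarray:
    n = int(round(t_end / dt_out))
    return np.linspace(0.0, n * dt_out, n + 1)


def simulate(model: PBPKModel, regimen: DoseRegimen, t_end: float,
             dt_out: float = 0.5, method: str = "lsoda",
             mass_balance_rtol: float = 1e-6) -> ConcentrationProfile:
    """Simulate a dosing regimen and return the plasma profile.

    ``method`` is ``"lsoda"`` / ``"bdf"`` (implicit stiff integration,
    rtol 1e-8, atol 1e-10 ng) or ``"analytic"`` (exact eigendecomposition
    of the linear system). Mass balance — administered × F equals amount
    remaining in the body plus cumulative eliminated — is enforced at the
    final time to ``mass_balance_rtol``.
    """
    if regimen.events and t_end < regimen.last_dose_time:
        raise DomainError("t_end must extend beyond the last dose event")
    grid = _output_grid(t_end, dt_out)
    if not regimen.events:
        zeros = np.zeros_like(grid)
        return ConcentrationProfile(grid, zeros.copy(),
                                    {"renal": zeros.copy(),
                                     "peptidase": zeros.copy()}, 0.0)
    if method == "analytic":
        profile, remaining = _simulate_analytic(model, regimen, grid)
    elif method in ("lsoda", "bdf"):
        profile, remaining = _simulate_ivp(model, regimen, grid, method)
    else:
        raise ValueError(f"unknown method {method!r}")
    administered = model.drug.bioavailability * regimen.total_dose_ng
    eliminated = (profile.amounts_eliminated["renal"][-1]
                  + profile.amounts_eliminated["peptidase"][-1])
    gap = abs(administered - remaining - eliminated)
    if gap > mass_balance_rtol * administered:
        raise IntegrationError(
            f"mass balance violated: |in - body - out| = {gap:.3g} ng "
            f"({gap / administered:.2e} of administered)"
        )
    return profile


def _segments(regimen: DoseRegimen, t_end: float):
    times = [t for t, _ in regimen.events]
    doses = [d for _, d in regimen.events]
    bounds = times + [t_end]
    for i, (t0, dose) in enumerate(zip(times, doses)):
        yield t0, bounds[i + 1], dose


def _simulate_analytic(model: PBPKModel, regimen: DoseRegimen,
                       grid: np.ndarray) -> ConcentrationProfile:
    w, P, Pinv = model._eig
    r, p = model._elimination_vectors
    n = len(STATE_LABELS)
    x = np.zeros(n, dtype=complex)
    elim = np.zeros(2)
    conc = np.zeros_like(grid)
    renal = np.zeros_like(grid)
    pept = np.zeros_like(grid)
    iv = STATE_LABELS.index("venous")
    v_ven = model.volumes["venous"]
    t_end = grid[-1]
    # points before the first dose stay zero
    for t0, t1, dose in _segments(regimen, t_end):
        x = x + model._bolus(dose * MG_TO_NG)
        c = Pinv @ x
        last = t1 >= t_end - 1e-12
        mask = (grid >= t0 - 1e-12) & ((grid <= t1 + 1e-12) if last
                                       else (grid < t1 - 1e-12))
        s = grid[mask] - t0
        E = np.exp(np.outer(s, w))                  # (n_s, n)
        states = (E * c) @ P.T                      # (n_s, n)
        with np.errstate(invalid="ignore"):
            Eint = (E - 1.0) / w                    # ∫0^s e^{wt} dt
        int_states = (Eint * c) @ P.T
        conc[mask] = np.real(states[:, iv]) / v_ven / 1000.0
        renal[mask] = elim[0] + np.real(int_states @ r)
        pept[mask] = elim[1] + np.real(int_states @ p)
        # advance the state to the end of the segment
        tau = t1 - t0
        e_tau = np.exp(w * tau)
        int_tau = (e_tau - 1.0) / w
        elim = elim + np.array([
            np.real((int_tau * c) @ (P.T @ r)),
            np.real((int_tau * c) @ (P.T @ p)),
        ])
        x = P @ (c * e_tau)
    profile = ConcentrationProfile(grid, conc,
                                   {"renal": renal, "peptidase": pept},
                                   regimen.total_dose_ng)
    return profile, float(np.real(x).sum())


def _simulate_ivp(model: PBPKModel, regimen: DoseRegimen, grid: np.ndarray,
                  method: str) -> ConcentrationProfile:
    A = model.system_matrix
    r, p = model._elimination_vectors
    n = len(STATE_LABELS)

    def rhs(t, y):
        x = y[:n]
        dx = A @ x
        return np.concatenate([dx, [r @ x, p @ x]])

    solver = "LSODA" if method == "lsoda" else "BDF"
    y = np.zeros(n + 2)
    conc = np.zeros_like(grid)
    renal = np.zeros_like(grid)
    pept = np.zeros_like(grid)
    iv = STATE_LABELS.index("venous")
    v_ven = model.volumes["venous"]
    t_end = grid[-1]
    jac = np.zeros((n + 2, n + 2))
    jac[:n, :n] = A
    jac[n, :n] = r
    jac[n + 1, :n] = p
    for t0, t1, dose in _segments(regimen, t_end):
        y[:n] += model._bolus(dose * MG_TO_NG)
        last = t1 >= t_end - 1e-12
        mask = (grid >= t0 - 1e-12) & ((grid <= t1 + 1e-12) if last
                                       else (grid < t1 - 1e-12))
        t_eval = grid[mask]
        eval_times = np.unique(np.concatenate([t_eval, [t0, t1]]))
        sol = solve_ivp(rhs, (t0, t1), y, method=solver, t_eval=eval_times,
                        rtol=1e-8, atol=1e-10, jac=lambda t, y: jac)
        if not sol.success:
            raise IntegrationError(f"{solver} failed: {sol.message}")
        take = np.isin(eval_times, t_eval)
        conc[mask] = sol.y[iv, take] / v_ven / 1000.0
        renal[mask] = sol.y[n, take]
        pept[mask] = sol.y[n + 1, take]
        y = sol.y[:, -1].copy()
    profile = ConcentrationProfile(grid, conc,
                                   {"renal": renal, "peptidase": pept},
                                   regimen.total_dose_ng)
    return profile, float(y[:n].sum())


def simulate_regimen_table(model: PBPKModel,
                           regimens: list[DoseRegimen | str],
                           dt_out: float = 0.5,
                           interval_h: float = 168.0
                           ) -> list[ConcentrationProfile]:
    """Simulate weekly multiple-dose regimens, keeping the last interval.

    Each entry may be a :class:`DoseRegimen` or a stage string such as
    ``"2.5:2+5:2+10:4"``. The returned profiles are windowed to
    [t_last_dose, t_last_dose + 168 h] for interval NCA.
    """
    out = []
    for item in regimens:
        regimen = DoseRegimen.parse(item, interval_h) if isinstance(item, str) else item
        if not regimen.events:
            continue
        t_end = regimen.last_dose_time + interval_h
        profile = simulate(model, regimen, t_end, dt_out=dt_out, method="analytic")
        out.append(profile.window(regimen.last_dose_time, t_end))
    return out
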