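"""Trial-like synthetic datasets: individual profiles and PK tables.

Generates observed-style datasets from the model itself so that the
calibration and validation machinery is testable without any external
download: per-subject kinetic parameters are drawn log-normally around
the generating model's values (inter-individual variability on ka, total
clearance and distribution volume), observations are the subject model's
predictions multiplied by log-normal residual error, and a per-subject
NCA table summarises the result the way clinical PK tables do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drug import DistributionInputs
from .engine import DoseRegimen, PBPKModel, simulate
from .errors import ValidationError
from .nca import compute_nca

#: Default sampling grid (h): dense first week plus three weekly tails so
#: the terminal phase is identifiable by NCA.
DEFAULT_SAMPLING_TIMES = (
    0.0, 4.0, 8.0, 12.0, 24.0, 48.0, 72.0, 96.0, 120.0, 168.0,
    336.0, 504.0, 672.0,
)


@dataclass
class TrialSpec:
    """Specification of one synthetic trial."""

    n_subjects: int = 56
    regimen: DoseRegimen = field(default_factory=lambda: DoseRegimen.single(5.0))
    iiv_cv: dict[str, float] = field(default_factory=lambda: {
        "ka": 0.30, "cl_total": 0.25, "v": 0.20})
    residual_cv: float = 0.15
    sampling_times: tuple[float, ...] = DEFAULT_SAMPLING_TIMES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        for k, cv in self.iiv_cv.items():
            if not 0 <= cv < 1:
                raise ValidationError(f"iiv CV for {k} must be in [0, 1)")
        if not 0 <= self.residual_cv < 1:
            raise ValidationError("residual_cv must be in [0, 1)")


def _subject_model(base: PBPKModel, eta_ka: float, eta_cl: float,
                   eta_v: float) -> PBPKModel:
    """Perturb one subject's kinetics around the generating model.

    ka scales directly; total clearance via both elimination routes
    (preserving the urine fraction); distribution volume via the partition
    coefficients (plasma volume untouched, so Cmax variability is mostly
    distributional).
    """
    kp = {organ: v * eta_v for organ, v in base.distribution.kp.items()}
    dist = DistributionInputs(kp=kp, cellular_permeability=base.distribution.cellular_permeability)
    return PBPKModel(base.individual, base.drug, dist,
                     ka=base.ka * eta_ka,
                     cl_pept_factor=base.cl_pept_factor * eta_cl,
                     cl_renal=base.cl_renal * eta_cl)


def _lognormal(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    sigma = float(np.sqrt(np.log(1.0 + cv * cv)))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size))


def generate_trial(spec: TrialSpec, base_model: PBPKModel
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (profiles, pk_table) for one synthetic trial.

    ``profiles`` is long-format (subject_id, time_h, conc_ng_per_mL);
    ``pk_table`` is long-format (subject_id, parameter, value) from a
    per-subject NCA of the noisy sampled profile. Both are bit-reproducible
    under ``spec.seed``. The log-normal multipliers are median-1
    (mean-log 0) for ka/CL/V and mean-1 for the residual.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    eta_ka = np.exp(rng.normal(0.0, _sigma(spec.iiv_cv.get("ka", 0.0)), n))
    eta_cl = np.exp(rng.normal(0.0, _sigma(spec.iiv_cv.get("cl_total", 0.0)), n))
    eta_v = np.exp(rng.normal(0.0, _sigma(spec.iiv_cv.get("v", 0.0)), n))
    times = np.asarray(spec.sampling_times, dtype=float)
    t_end = float(times[-1])
    dose_mg = spec.regimen.events[0][1] if spec.regimen.events else 0.0

    profile_rows, pk_rows = [], []
    for i in range(n):
        model = _subject_model(base_model, eta_ka[i], eta_cl[i], eta_v[i])
        dense = simulate(model, spec.regimen, t_end, dt_out=0.5,
                         method="analytic")
        pred = np.interp(times, dense.times, dense.conc)
        eps = _lognormal(rng, spec.residual_cv, times.size)
        obs = pred * eps
        for t, c in zip(times, obs):
            profile_rows.append({"subject_id": i, "time_h": t,
                                 "conc_ng_per_mL": c})
        sampled = _as_profile(times, obs)
        pk = compute_nca(sampled, dose_mg)
        for name, value in (("auc_0_inf", pk.auc_0_inf),
                            ("auc_0_168", pk.auc_0_168),
                            ("cmax", pk.cmax), ("tmax", pk.tmax),
                            ("t_half", pk.t_half),
                            ("cl_over_f", pk.cl_over_f)):
            pk_rows.append({"subject_id": i, "parameter": name, "value": value})
    return pd.DataFrame(profile_rows), pd.DataFrame(pk_rows)


def _sigma(cv: float) -> float:
    return float(np.sqrt(np.log(1.0 + cv * cv))) if cv > 0 else 0.0


def _as_profile(times: np.ndarray, conc: np.ndarray):
    from .engine import ConcentrationProfile
    zeros = np.zeros_like(times)
    return ConcentrationProfile(times=times, conc=conc,
                                amounts_eliminated={"renal": zeros,
                                                    "peptidase": zeros.copy()})


def summarize_pk_table(pk_table: pd.DataFrame) -> dict[str, float]:
    """Arithmetic means per parameter (clinical-table style summary)."""
    means = pk_table.groupby("parameter")["value"].mean()
    return {k: float(v) for k, v in means.items()}
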