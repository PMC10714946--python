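"""Pediatric extrapolation and dose-band search.

The calibrated adult model is extrapolated to 10–18-year-olds by swapping
in pediatric physiology while keeping every drug-specific input fixed:
peptidase clearance rescales implicitly with organ volumes, and renal
clearance follows the GFR ratio

    CL_renal,ped = (GFR_ped / GFR_adult) · (fu_ped / fu_adult) · CL_renal,adult

with the fu ratio fixed at 1 for ages >= 10 (adult-like albumin). Virtual
populations per age band (children 10–12, early adolescents 12–15,
adolescents 15–18; normal-weight and obese) are then simulated at the
candidate dose grid {5, 4.375, 3.75, 3.125, 2.5} mg, and the band of
doses whose population-mean AUC_0–168h AND Cmax both fall inside the
adult reference range is reported. If only the full 5 mg reference dose
qualifies, no dose adjustment is recommended.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .calibration import _single_dose_metrics
from .engine import PBPKModel, build_model
from .drug import compute_distribution
from .errors import DomainError, ValidationError
from .physiology import IndividualPhysiology, PopulationSpec, sample_population

CANDIDATE_DOSES_MG = (5.0, 4.375, 3.75, 3.125, 2.5)

AGE_BANDS = {
    "children_10_12": (10.0, 12.0),
    "early_adol_12_15": (12.0, 15.0),
    "adol_15_18": (15.0, 18.0),
}


@dataclass
class ClearanceScalingInputs:
    """Inputs of the renal-clearance scaling rule."""

    gfr_pediatric: float   # mL/min
    gfr_adult: float       # mL/min
    fu_pediatric: float
    fu_adult: float
    cl_renal_adult: float  # L/h

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if not v > 0:
                raise DomainError(f"{name} must be positive")


@dataclass
class ReferenceRange:
    """Adult reference exposure ranges for a single 5 mg dose."""

    auc_0_168: tuple[float, float]
    cmax: tuple[float, float]
    tmax: tuple[float, float]

    def __post_init__(self) -> None:
        for name in ("auc_0_168", "cmax", "tmax"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"reference range {name} must be ordered")

    @classmethod
    def bundled(cls) -> "ReferenceRange":
        with resources.files("tirzepbpk.data").joinpath(
            "reference_ranges.json"
        ).open() as fh:
            data = json.load(fh)
        return cls(auc_0_168=tuple(data["auc_0_168_ng_h_per_ml"]),
                   cmax=tuple(data["cmax_ng_per_ml"]),
                   tmax=tuple(data["tmax_h"]))


@dataclass
class DoseRecommendation:
    """Outcome of the dose-band search for one population."""

    age_band: str
    weight_class: str
    dose_band_mg: tuple[float, float] | None   # None together with flags below
    no_adjustment: bool = False
    qualifying_doses: tuple[float, ...] = ()
    diagnostics: pd.DataFrame | None = None

    @property
    def label(self) -> str:
        if self.no_adjustment:
            return "no_adjustment"
        if self.dose_band_mg is None:
            return "none_qualify"
        lo, hi = self.dose_band_mg
        return f"{lo:g}-{hi:g}"


def scale_renal_clearance(inp: ClearanceScalingInputs) -> float:
    """Pediatric renal clearance (L/h) from the GFR and fu ratios."""
    return (inp.gfr_pediatric / inp.gfr_adult
            * inp.fu_pediatric / inp.fu_adult
            * inp.cl_renal_adult)


def extrapolate(adult_model: PBPKModel,
                individual: IndividualPhysiology) -> PBPKModel:
    """Swap pediatric physiology into the calibrated adult model.

    Drug parameters (and hence fu, ka, the peptidase calibration factor)
    are carried over bit-exactly; renal clearance is rescaled by the GFR
    ratio with the fu ratio equal to 1.
    """
    cl_renal = scale_renal_clearance(ClearanceScalingInputs(
        gfr_pediatric=individual.gfr,
        gfr_adult=adult_model.individual.gfr,
        fu_pediatric=adult_model.drug.fu,
        fu_adult=adult_model.drug.fu,
        cl_renal_adult=adult_model.cl_renal,
    ))
    distribution = compute_distribution(adult_model.drug, individual)
    return build_model(individual, adult_model.drug,
                       distribution=distribution, ka=adult_model.ka,
                       cl_pept_factor=adult_model.cl_pept_factor,
                       cl_renal=cl_renal)


def population_exposure(adult_model: PBPKModel,
                        population: list[IndividualPhysiology],
                        doses_mg: tuple[float, ...] = CANDIDATE_DOSES_MG,
                        t_end: float = 1500.0,
                        dt_out: float = 0.5) -> pd.DataFrame:
    """Single-dose exposure metrics per individual and candidate dose."""
    rows = []
    for i, ind in enumerate(population):
        model = extrapolate(adult_model, ind)
        for dose in doses_mg:
            m = _single_dose_metrics(model, dose, t_end, dt_out)
            rows.append({"id": i, "age_years": ind.age_years, "sex": ind.sex,
                         "dose_mg": dose, **m})
    return pd.DataFrame(rows)


def find_dose_band(adult_model: PBPKModel,
                   population: list[IndividualPhysiology],
                   candidate_doses: tuple[float, ...] = CANDIDATE_DOSES_MG,
                   ref: ReferenceRange | None = None,
                   age_band: str = "", weight_class: str = "",
                   exposure: pd.DataFrame | None = None) -> DoseRecommendation:
    """Find the contiguous candidate-dose band matching adult exposure.

    A dose qualifies when the population arithmetic-mean AUC_0–168h AND
    Cmax both lie inside the adult reference range. If the 5 mg reference
    dose qualifies alone at the top of the grid the recommendation is
    "no adjustment"; if nothing qualifies, the recommendation carries the
    per-dose diagnostics and an empty band.
    """
    if ref is None:
        ref = ReferenceRange.bundled()
    if exposure is None:
        exposure = population_exposure(adult_model, population,
                                       tuple(candidate_doses))
    means = (exposure.groupby("dose_mg")[["auc_0_168", "cmax"]]
             .mean().reset_index())
    lo_a, hi_a = ref.auc_0_168
    lo_c, hi_c = ref.cmax
    means["auc_in_range"] = means["auc_0_168"].between(lo_a, hi_a)
    means["cmax_in_range"] = means["cmax"].between(lo_c, hi_c)
    means["qualifies"] = means["auc_in_range"] & means["cmax_in_range"]
    qualifying = tuple(sorted(means.loc[means["qualifies"], "dose_mg"]))
    top = max(candidate_doses)
    if not qualifying:
        return DoseRecommendation(age_band, weight_class, None,
                                  qualifying_doses=(), diagnostics=means)
    if qualifying == (top,):
        return DoseRecommendation(age_band, weight_class, None,
                                  no_adjustment=True,
                                  qualifying_doses=qualifying,
                                  diagnostics=means)
    return DoseRecommendation(age_band, weight_class,
                              (min(qualifying), max(qualifying)),
                              qualifying_doses=qualifying, diagnostics=means)


def recommend_doses(adult_model: PBPKModel, seed: int = 0,
                    n_per_sex: int = 50,
                    candidate_doses: tuple[float, ...] = CANDIDATE_DOSES_MG,
                    ref: ReferenceRange | None = None) -> pd.DataFrame:
    """Dose-band table over all age bands and weight classes."""
    rows = []
    sub_seeds = np.random.SeedSequence(seed).generate_state(
        2 * len(AGE_BANDS)) % (2**31 - 1)
    k = 0
    for band, age_range in AGE_BANDS.items():
        for weight_class in ("normal", "obese"):
            spec = PopulationSpec(n_female=n_per_sex, n_male=n_per_sex,
                                  age_range=age_range,
                                  weight_class=weight_class,
                                  seed=int(sub_seeds[k]))
            k += 1
            pop = sample_population(spec)
            rec = find_dose_band(adult_model, pop, candidate_doses, ref,
                                 age_band=band, weight_class=weight_class)
            rows.append({"age_band": band, "weight_class": weight_class,
                         "dose_band_mg": rec.label,
                         "qualifying_doses": ",".join(
                             f"{d:g}" for d in rec.qualifying_doses)})
    return pd.DataFrame(rows)
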