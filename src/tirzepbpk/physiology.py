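"""Virtual physiology: anthropometry, organ volumes, blood flows and GFR.

Builds age- and sex-resolved virtual individuals — reference adults and
pediatric subjects between 10 and 18 years, in normal-weight or obese
variants — to serve as the anatomical scaffold of the whole-body PK model.

Design
------
* Median height/weight by age and sex come from a bundled synthetic
  growth-reference table (CDC-style curves, shipped with the package); BMI
  95th-percentile curves are stored in LMS form on the same table.
* Organ masses are scaled allometrically from same-sex adult reference
  organ weights (ICRP-style): mass ∝ body weight for all organs except
  brain (exponent 0.15, nearly weight-invariant), with adipose tissue
  absorbing the residual so that organ masses sum exactly to body weight
  (density 1 kg/L throughout).
* Cardiac output scales with body weight to the 3/4 power; organ blood
  flows are fixed fractions of cardiac output; absolute GFR is a
  body-surface-area-normalised reference (120 mL/min/1.73 m², adult-like
  maturation for ages >= 10) via the Du Bois formula.
* Obesity is imposed on a normal-weight individual: kidney and liver grow
  by x1.15, other lean organs by x1.05 (brain unchanged), adipose absorbs
  the remaining excess weight, organ blood flows rescale in proportion to
  the new organ volumes, and GFR rescales with kidney volume.
* Individual variability: multiplicative truncated-normal factors around
  the medians (weight CV 10 %, height CV 3.5 %, truncated at ±2.5 SD),
  driven by a single integer seed per individual or population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError

#: Organs carried by every individual (volumes in L). ``plasma`` is the
#: vascular plasma pool; all other entries are tissue compartments.
ORGANS = (
    "adipose", "bone", "brain", "gut", "heart", "kidney", "liver",
    "lung", "muscle", "skin", "spleen", "rest", "plasma",
)

#: Systemically perfused tissues (receive a share of cardiac output in
#: parallel). The lung sits in series and receives the full cardiac output.
SYSTEMIC_ORGANS = (
    "adipose", "bone", "brain", "gut", "heart", "kidney", "liver",
    "muscle", "skin", "spleen", "rest",
)

# Adult reference organ masses (kg ~ L), ICRP-style reference persons.
# ``adipose`` is the residual so the column sums exactly to body weight.
_ADULT_ORGANS = {
    "male": {
        "bone": 10.5, "brain": 1.45, "gut": 1.20, "heart": 0.33,
        "kidney": 0.31, "liver": 1.80, "lung": 0.50, "muscle": 28.0,
        "skin": 3.30, "spleen": 0.15, "rest": 6.00, "plasma": 3.00,
    },
    "female": {
        "bone": 7.80, "brain": 1.30, "gut": 1.10, "heart": 0.25,
        "kidney": 0.275, "liver": 1.40, "lung": 0.42, "muscle": 20.0,
        "skin": 2.30, "spleen": 0.13, "rest": 5.00, "plasma": 2.40,
    },
}

# Reference adults: height (cm), weight (kg), cardiac output (L/h).
_ADULT_REFERENCE = {
    "male": {"height_cm": 171.0, "weight_kg": 72.0, "co_l_per_h": 370.0},
    "female": {"height_cm": 158.0, "weight_kg": 58.0, "co_l_per_h": 330.0},
}

# Fractions of cardiac output perfusing each systemic tissue (arterial
# side; the liver fraction is hepatic-arterial only — portal inflow from
# gut and spleen is added on top inside the PK engine). Sums to 1.
_FLOW_FRACTIONS = {
    "male": {
        "adipose": 0.050, "bone": 0.050, "brain": 0.120, "gut": 0.150,
        "heart": 0.040, "kidney": 0.190, "liver": 0.065, "muscle": 0.170,
        "skin": 0.050, "spleen": 0.030, "rest": 0.085,
    },
    "female": {
        "adipose": 0.085, "bone": 0.040, "brain": 0.120, "gut": 0.160,
        "heart": 0.040, "kidney": 0.170, "liver": 0.065, "muscle": 0.120,
        "skin": 0.050, "spleen": 0.030, "rest": 0.120,
    },
}

_BRAIN_EXPONENT = 0.15
_WEIGHT_CV = 0.10
_HEIGHT_CV = 0.035
_TRUNCATION_SD = 2.5
_GFR_REFERENCE = 120.0  # mL/min per 1.73 m^2, adult-like for ages >= 10
_Z95 = 1.6448536269514722


def _growth_table() -> pd.DataFrame:
    with resources.files("tirzepbpk.data").joinpath(
        "growth_reference_synthetic.csv"
    ).open() as fh:
        return pd.read_csv(fh, comment="#")


_GROWTH = None


def growth_reference() -> pd.DataFrame:
    """Bundled synthetic growth-reference table (cached)."""
    global _GROWTH
    if _GROWTH is None:
        _GROWTH = _growth_table()
    return _GROWTH


def _interp_growth(age: float, sex: str, column: str) -> float:
    tab = growth_reference()
    sub = tab[tab["sex"] == sex]
    return float(np.interp(age, sub["age_years"], sub[column]))


def bmi_percentile_95(age: float, sex: str) -> float:
    """BMI-for-age 95th percentile (kg/m^2) from the bundled LMS curves.

    For adults (age >= 18) the age-18 curve is used (the conventional
    adult obesity threshold of 30 kg/m^2 is not applied here; pediatric
    classification is the purpose of this curve).
    """
    _check_sex(sex)
    a = min(float(age), 18.0)
    L = _interp_growth(a, sex, "bmi_l")
    M = _interp_growth(a, sex, "bmi_m")
    S = _interp_growth(a, sex, "bmi_s")
    return M * (1.0 + L * S * _Z95) ** (1.0 / L)


def body_surface_area(height_cm: float, weight_kg: float) -> float:
    """Du Bois body surface area in m^2."""
    return 0.007184 * height_cm ** 0.725 * weight_kg ** 0.425


@dataclass
class IndividualPhysiology:
    """Anthropometry, organ volumes, blood flows and GFR of one individual.

    Volumes are in litres (tissue density taken as 1 kg/L, so organ masses
    in kg are numerically equal); flows in L/h of blood; GFR in mL/min.
    ``organ_blood_flows`` covers the systemically perfused tissues; lung
    perfusion equals ``cardiac_output`` (in-series pulmonary circulation).
    """

    age_years: float
    sex: str
    body_weight: float
    height: float
    bmi: float
    organ_volumes: dict[str, float]
    organ_blood_flows: dict[str, float]
    cardiac_output: float
    gfr: float
    hematocrit: float
    weight_class: str = "normal"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check_sex(self.sex)
        if not (10.0 <= self.age_years <= 18.0 or self.age_years >= 18.0):
            raise DomainError(f"unsupported age {self.age_years}")
        expected_bmi = self.body_weight / (self.height / 100.0) ** 2
        if abs(self.bmi - expected_bmi) > 1e-9:
            raise ValidationError("bmi inconsistent with weight and height")
        if set(self.organ_volumes) != set(ORGANS):
            raise ValidationError("organ_volumes must cover all organs")
        for organ, v in self.organ_volumes.items():
            if v <= 0:
                raise ValidationError(f"non-positive volume for {organ}")
        for organ, q in self.organ_blood_flows.items():
            if q <= 0:
                raise ValidationError(f"non-positive flow for {organ}")
        if self.cardiac_output <= 0 or self.gfr <= 0:
            raise ValidationError("cardiac output and GFR must be positive")
        if not 0 < self.hematocrit < 1:
            raise ValidationError("hematocrit must be a fraction")
        total_flow = sum(self.organ_blood_flows.values())
        if total_flow > self.cardiac_output * (1 + 1e-9):
            raise ValidationError("organ blood flows exceed cardiac output")
        mass = sum(self.organ_volumes.values())
        if abs(mass - self.body_weight) > 0.01 * self.body_weight:
            raise ValidationError("organ masses do not sum to body weight")

    @property
    def is_pediatric(self) -> bool:
        return self.age_years < 18.0


@dataclass
class ObesityScaling:
    """Organ rescaling rule that converts a normal-weight individual to obese.

    ``organ_volume_factors`` multiply lean-organ volumes (kidney and liver
    x1.15 by default, remaining lean organs x1.05, brain unchanged);
    adipose tissue is not listed — it absorbs the residual excess weight.
    GFR is rescaled with kidney volume (``per_organ_volume``).
    """

    organ_volume_factors: dict[str, float] = field(default_factory=lambda: {
        "kidney": 1.15, "liver": 1.15, "bone": 1.05, "brain": 1.00,
        "gut": 1.05, "heart": 1.05, "lung": 1.05, "muscle": 1.05,
        "skin": 1.05, "spleen": 1.05, "rest": 1.05, "plasma": 1.05,
    })
    bmi_percentile_threshold: float = 95.0
    gfr_scaling: str = "per_organ_volume"

    def __post_init__(self) -> None:
        for organ, f in self.organ_volume_factors.items():
            if f < 1.0:
                raise ValidationError(
                    f"obesity factor for {organ} must be >= 1.0, got {f}"
                )


@dataclass
class PopulationSpec:
    """Specification of a virtual population."""

    n_female: int
    n_male: int
    age_range: tuple[float, float]
    weight_class: str = "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_female + self.n_male < 1:
            raise ValidationError("population must contain at least one subject")
        lo, hi = self.age_range
        if lo > hi:
            raise ValidationError("age_range must be ordered")
        if hi < 18.0 and not (10.0 <= lo and hi <= 18.0):
            raise ValidationError("pediatric age_range must lie within [10, 18]")
        if self.weight_class not in ("normal", "obese"):
            raise ValidationError(f"unknown weight class {self.weight_class!r}")


def _check_sex(sex: str) -> None:
    if sex not in ("female", "male"):
        raise ValidationError(f"unknown sex {sex!r}")


def _median_anthropometry(age: float, sex: str) -> tuple[float, float]:
    # ages up to and including 18 follow the pediatric growth curves; older
    # individuals use the (trial-cohort-like) reference adult anthropometry
    if age > 18.0:
        ref = _ADULT_REFERENCE[sex]
        return ref["height_cm"], ref["weight_kg"]
    return (
        _interp_growth(age, sex, "height_cm"),
        _interp_growth(age, sex, "weight_kg"),
    )


def _truncated_normal(rng: np.random.Generator) -> float:
    while True:
        z = rng.standard_normal()
        if abs(z) <= _TRUNCATION_SD:
            return float(z)


def _hematocrit(age: float, sex: str) -> float:
    frac = min(max((age - 10.0) / 8.0, 0.0), 1.0)
    top = 0.43 if sex == "male" else 0.40
    return 0.39 + (top - 0.39) * frac


def _organ_masses(sex: str, body_weight: float) -> dict[str, float]:
    """Allometric organ masses summing exactly to body weight."""
    ref = _ADULT_ORGANS[sex]
    bw_ref = _ADULT_REFERENCE[sex]["weight_kg"]
    ratio = body_weight / bw_ref
    organs = {}
    for organ, mass in ref.items():
        exponent = _BRAIN_EXPONENT if organ == "brain" else 1.0
        organs[organ] = mass * ratio ** exponent
    lean = sum(organs.values())
    adipose = body_weight - lean
    if adipose <= 0:
        raise DomainError(
            f"body weight {body_weight:.1f} kg too low for {sex} lean mass"
        )
    organs["adipose"] = adipose
    return organs


def _assemble(age: float, sex: str, height: float, weight: float,
              weight_class: str) -> IndividualPhysiology:
    organs = _organ_masses(sex, weight)
    co = _ADULT_REFERENCE[sex]["co_l_per_h"] * (
        weight / _ADULT_REFERENCE[sex]["weight_kg"]
    ) ** 0.75
    fractions = _FLOW_FRACTIONS[sex]
    flows = {organ: co * fractions[organ] for organ in SYSTEMIC_ORGANS}
    gfr = _GFR_REFERENCE * body_surface_area(height, weight) / 1.73
    return IndividualPhysiology(
        age_years=age,
        sex=sex,
        body_weight=weight,
        height=height,
        bmi=weight / (height / 100.0) ** 2,
        organ_volumes=organs,
        organ_blood_flows=flows,
        cardiac_output=co,
        gfr=gfr,
        hematocrit=_hematocrit(age, sex),
        weight_class=weight_class,
    )


def build_individual(age: float, sex: str, weight_class: str = "normal",
                     seed: int | None = None) -> IndividualPhysiology:
    """Construct one virtual individual.

    Parameters
    ----------
    age : float
        Decimal age in years; 10–18 (pediatric) or >= 18 (adult).
    sex : {"female", "male"}
    weight_class : {"normal", "obese"}
        Obese individuals are built from the normal-weight base and pushed
        above the 95th BMI percentile via :func:`apply_obesity`.
    seed : int or None
        ``None`` returns the deterministic median individual; an integer
        seeds the multiplicative anthropometric variability.
    """
    _check_sex(sex)
    if not (10.0 <= age):
        raise DomainError(f"unsupported age {age}; must be >= 10 years")
    if weight_class not in ("normal", "obese"):
        raise ValidationError(f"unknown weight class {weight_class!r}")

    h_med, w_med = _median_anthropometry(age, sex)
    if seed is None:
        height, weight = h_med, w_med
        bmi_excess = 1.175  # midpoint of the sampled obese range
    else:
        rng = np.random.default_rng(seed)
        weight = w_med * math.exp(_WEIGHT_CV * _truncated_normal(rng))
        height = h_med * math.exp(_HEIGHT_CV * _truncated_normal(rng))
        bmi_excess = 1.05 + 0.25 * rng.uniform()

    ind = _assemble(age, sex, height, weight, "normal")
    if weight_class == "normal":
        return ind

    p95 = bmi_percentile_95(age, sex)
    target_bmi = p95 * bmi_excess
    target_weight = target_bmi * (height / 100.0) ** 2
    # Guard: the obese target must exceed the base plus the lean-organ growth.
    target_weight = max(target_weight, ind.body_weight * 1.08)
    return apply_obesity(ind, ObesityScaling(), target_weight)


def reference_adult(sex: str = "male", age: float = 30.0) -> IndividualPhysiology:
    """Deterministic reference adult (median anthropometry)."""
    return build_individual(age, sex, "normal", seed=None)


def apply_obesity(ind: IndividualPhysiology, scaling: ObesityScaling,
                  target_body_weight: float | None = None) -> IndividualPhysiology:
    """Convert a normal-weight individual to its obese counterpart.

    Lean organs are multiplied by their scaling factors, adipose tissue
    absorbs the remaining excess up to ``target_body_weight``, organ blood
    flows rescale proportionally to the new organ volumes (raising cardiac
    output), and GFR rescales with kidney volume.

    With identity factors and no target weight the individual is returned
    unchanged.
    """
    if ind.weight_class != "normal":
        raise ValidationError("apply_obesity expects a normal-weight individual")
    factors = scaling.organ_volume_factors
    if target_body_weight is None:
        target_body_weight = ind.body_weight

    new_volumes = {}
    for organ, v in ind.organ_volumes.items():
        if organ == "adipose":
            continue
        new_volumes[organ] = v * factors.get(organ, 1.0)
    lean = sum(new_volumes.values())
    adipose = target_body_weight - lean
    if adipose <= 0:
        raise DomainError(
            "target body weight too low to accommodate scaled lean organs"
        )
    if adipose < ind.organ_volumes["adipose"] * (1 - 1e-9):
        raise DomainError("obesity scaling would shrink adipose tissue")
    new_volumes["adipose"] = adipose

    flow_scale = {
        organ: new_volumes[organ] / ind.organ_volumes[organ]
        for organ in SYSTEMIC_ORGANS
    }
    new_flows = {
        organ: q * flow_scale[organ]
        for organ, q in ind.organ_blood_flows.items()
    }
    new_co = ind.cardiac_output * sum(new_flows.values()) / sum(
        ind.organ_blood_flows.values()
    )
    kidney_factor = factors.get("kidney", 1.0)
    identity = (
        abs(target_body_weight - ind.body_weight) < 1e-12
        and all(abs(f - 1.0) < 1e-12 for f in factors.values())
    )
    return IndividualPhysiology(
        age_years=ind.age_years,
        sex=ind.sex,
        body_weight=target_body_weight,
        height=ind.height,
        bmi=target_body_weight / (ind.height / 100.0) ** 2,
        organ_volumes=new_volumes,
        organ_blood_flows=new_flows,
        cardiac_output=new_co,
        gfr=ind.gfr * kidney_factor,
        hematocrit=ind.hematocrit,
        weight_class="normal" if identity else "obese",
    )


def sample_population(spec: PopulationSpec) -> list[IndividualPhysiology]:
    """Sample a reproducible virtual population.

    Ages are uniform over ``spec.age_range``; individual anthropometry is
    sampled through per-individual seeds drawn from the population seed,
    so identical specs yield bit-identical populations.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range
    individuals = []
    for sex, n in (("female", spec.n_female), ("male", spec.n_male)):
        for _ in range(n):
            age = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            individuals.append(
                build_individual(age, sex, spec.weight_class, seed=sub_seed)
            )
    return individuals


def population_to_frame(population: Iterable[IndividualPhysiology]) -> pd.DataFrame:
    """Flatten a population to one row per individual (CSV-exportable)."""
    rows = []
    for i, ind in enumerate(population):
        row = {
            "id": i,
            "age_years": ind.age_years,
            "sex": ind.sex,
            "weight_class": ind.weight_class,
            "body_weight_kg": ind.body_weight,
            "height_cm": ind.height,
            "bmi": ind.bmi,
            "cardiac_output_l_per_h": ind.cardiac_output,
            "gfr_ml_per_min": ind.gfr,
            "hematocrit": ind.hematocrit,
        }
        for organ in ORGANS:
            row[f"v_{organ}_l"] = ind.organ_volumes[organ]
        for organ in SYSTEMIC_ORGANS:
            row[f"q_{organ}_l_per_h"] = ind.organ_blood_flows[organ]
        rows.append(row)
    return pd.DataFrame(rows)
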