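"""Model qualification: fold errors, average fold error, two-fold window.

A prediction set is qualified by the fold error of each PK parameter per
study and by the average fold error (AFE) per parameter,

    AFE = 10 ** (Σ log10(fold error) / N),

with the acceptance window 0.5–2 applied to both. The default fold-error
convention is predicted/observed, matching the published comparison
tables this package ships as fixtures (their equation text states the
inverse; the printed values use predicted/observed). Studies with missing
(NA) values for a parameter are excluded from that parameter's N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError


def fold_error(predicted: float, observed: float,
               convention: str = "pred_over_obs") -> float:
    """Ratio of predicted and observed per the chosen convention."""
    if not (predicted > 0 and observed > 0):
        raise DomainError("fold error requires positive predicted and observed")
    if convention == "pred_over_obs":
        return predicted / observed
    if convention == "obs_over_pred":
        return observed / predicted
    raise ValueError(f"unknown convention {convention!r}")


def afe(fold_errors: Sequence[float]) -> float:
    """Average (geometric mean) fold error, 10^(Σ log10 fe / N)."""
    fe = np.asarray(list(fold_errors), dtype=float)
    if fe.size == 0:
        raise DomainError("AFE of an empty list is undefined")
    if np.any(fe <= 0) or np.any(~np.isfinite(fe)):
        raise DomainError("fold errors must be positive and finite")
    return float(10.0 ** (np.log10(fe).mean()))


def in_two_fold(value: float, lo: float = 0.5, hi: float = 2.0) -> bool:
    """Closed-interval acceptance check."""
    return lo <= value <= hi


@dataclass
class ValidationReport:
    """Fold errors per study/parameter plus per-parameter AFE and flags."""

    per_study: pd.DataFrame       # study_id, parameter, predicted, observed, fold_error, pass_2fold
    afe: dict[str, float] = field(default_factory=dict)
    n_used: dict[str, int] = field(default_factory=dict)
    afe_pass_2fold: dict[str, bool] = field(default_factory=dict)
    convention: str = "pred_over_obs"

    def all_pass(self, include_per_study: bool = True) -> bool:
        ok = all(self.afe_pass_2fold.values())
        if include_per_study:
            ok = ok and bool(self.per_study["pass_2fold"].all())
        return ok

    def to_dict(self) -> dict:
        return {
            "convention": self.convention,
            "afe": self.afe,
            "n_used": self.n_used,
            "afe_pass_2fold": self.afe_pass_2fold,
            "per_study": self.per_study.to_dict(orient="records"),
        }


def validate_table(table: pd.DataFrame,
                   convention: str = "pred_over_obs") -> ValidationReport:
    """Qualify a tidy predicted/observed table.

    ``table`` needs columns ``study_id``, ``parameter``, ``predicted``,
    ``observed``; rows with NA predicted or observed are dropped from the
    fold-error list (and hence from the AFE of their parameter).
    """
    df = table.copy()
    df["predicted"] = pd.to_numeric(df["predicted"], errors="coerce")
    df["observed"] = pd.to_numeric(df["observed"], errors="coerce")
    df = df.dropna(subset=["predicted", "observed"]).reset_index(drop=True)
    df["fold_error"] = [
        fold_error(p, o, convention)
        for p, o in zip(df["predicted"], df["observed"])
    ]
    df["pass_2fold"] = [in_two_fold(fe) for fe in df["fold_error"]]
    afes, n_used, flags = {}, {}, {}
    for parameter, grp in df.groupby("parameter", sort=False):
        afes[parameter] = afe(grp["fold_error"])
        n_used[parameter] = int(len(grp))
        flags[parameter] = in_two_fold(afes[parameter])
    return ValidationReport(per_study=df, afe=afes, n_used=n_used,
                            afe_pass_2fold=flags, convention=convention)


def _load_fixture(name: str) -> pd.DataFrame:
    with resources.files("tirzepbpk.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


def load_single_dose_table() -> pd.DataFrame:
    """Bundled adult single-dose predicted/observed comparison table."""
    return _load_fixture("observed_single_dose.csv")


def load_multiple_dose_table() -> pd.DataFrame:
    """Bundled adult multiple-dose predicted/observed comparison table."""
    return _load_fixture("observed_multiple_dose.csv")
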