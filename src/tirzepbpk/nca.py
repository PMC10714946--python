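"""Non-compartmental analysis of concentration–time profiles.

Computes the standard exposure metrics from a plasma curve: AUC_0-inf and
AUC_0–168h (linear trapezoid on rising segments, log trapezoid on
declining segments), Cmax and Tmax (grid maximum, earliest tie), terminal
half-life (log-linear regression over the terminal tail chosen to
maximise adjusted r², at least three points after Tmax), and apparent
clearance CL/F = dose / AUC_0-inf.

Conventions: time in h, concentration in ng/mL, dose in mg (converted to
ng internally), CL/F reported in L/h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import ConcentrationProfile, MG_TO_NG
from .errors import NCAError

_LN2 = float(np.log(2.0))


@dataclass
class PKParameters:
    """NCA outputs. Fields not defined for the requested window are None."""

    auc_0_inf: float | None
    auc_0_168: float | None
    cmax: float
    tmax: float
    t_half: float | None
    cl_over_f: float | None
    lambda_z: float | None = None
    n_lambda_z: int | None = None
    r2_adj: float | None = None


def _auc_cumulative(t: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Cumulative AUC by linear-up/log-down trapezoid (ng·h/mL)."""
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    lin = 0.5 * (c1 + c2) * dt
    declining = (c2 < c1) & (c2 > 0) & (c1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_seg = (c1 - c2) / np.log(c1 / c2) * dt
    seg = np.where(declining, log_seg, lin)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _terminal_fit(t: np.ndarray, c: np.ndarray, i_tmax: int,
                  min_points: int) -> tuple[float, int, float]:
    """Best adjusted-r² log-linear terminal fit; returns (λz, n, r²_adj).

    Candidate tails start after Tmax and run to the last positive
    concentration; all suffix regressions are evaluated via reversed
    cumulative sums (O(n)).
    """
    pos = c > 0
    # last contiguous positive block
    end = len(c)
    while end > 0 and not pos[end - 1]:
        end -= 1
    if end == 0:
        raise NCAError("no positive concentrations for terminal fit")
    start_min = i_tmax + 1
    block_start = end - 1
    while block_start > start_min and pos[block_start - 1]:
        block_start -= 1
    tt = t[block_start:end]
    yy = np.log(c[block_start:end])
    m = len(tt)
    if m < min_points:
        raise NCAError("not enough points after Tmax for terminal fit")
    # suffix sums: for each start j, regression over tt[j:], yy[j:]
    n_tail = m - np.arange(m)
    s_t = np.cumsum(tt[::-1])[::-1]
    s_y = np.cumsum(yy[::-1])[::-1]
    s_tt = np.cumsum((tt * tt)[::-1])[::-1]
    s_ty = np.cumsum((tt * yy)[::-1])[::-1]
    s_yy = np.cumsum((yy * yy)[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sxx = s_tt - s_t ** 2 / n_tail
        sxy = s_ty - s_t * s_y / n_tail
        syy = s_yy - s_y ** 2 / n_tail
        slope = sxy / sxx
        r2 = np.where(syy > 0, sxy ** 2 / (sxx * syy), 1.0)
        r2_adj = 1.0 - (1.0 - r2) * (n_tail - 1) / (n_tail - 2)
    valid = (n_tail >= min_points) & (slope < 0) & np.isfinite(r2_adj)
    if not np.any(valid):
        raise NCAError("no declining terminal phase identified")
    j = int(np.nanargmax(np.where(valid, r2_adj, -np.inf)))
    return float(-slope[j]), int(n_tail[j]), float(r2_adj[j])


def compute_nca(profile: ConcentrationProfile, dose_mg: float,
                window: str = "0_inf", min_tail_points: int = 3,
                interval_h: float = 168.0) -> PKParameters:
    """NCA of one profile.

    ``window="0_inf"``: full single-dose analysis with extrapolated tail
    (C_last/λz) and CL/F. ``window="last_interval_168h"``: the profile is
    interpreted as one dosing interval (the last 168 h of the input);
    AUC_0-168 covers the interval, Tmax is relative to the interval start,
    and AUC_0-inf / CL/F are not reported.
    """
    t = np.asarray(profile.times, dtype=float)
    c = np.asarray(profile.conc, dtype=float)
    if t.size < 3:
        raise NCAError("profile too short for NCA")
    if not np.any(c > 0):
        raise NCAError("profile is identically zero")
    if window == "last_interval_168h":
        t0 = t[-1] - interval_h
        mask = t >= t0 - 1e-9
        t, c = t[mask] - max(t0, t[0]), c[mask]
    elif window != "0_inf":
        raise ValueError(f"unknown NCA window {window!r}")

    cum = _auc_cumulative(t, c)
    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])
    lam, n_lam, r2 = None, None, None
    t_half = None
    try:
        lam, n_lam, r2 = _terminal_fit(t, c, i_max, min_tail_points)
        t_half = _LN2 / lam
    except NCAError:
        if window == "0_inf":
            raise
    auc_0_168 = None
    if t[-1] >= interval_h - 1e-9:
        auc_0_168 = float(np.interp(interval_h, t, cum))
    elif window == "last_interval_168h":
        auc_0_168 = float(cum[-1])
    if window == "0_inf":
        c_last = c[c > 0][-1] if np.any(c > 0) else 0.0
        if c_last <= 0:
            raise NCAError("non-positive last concentration; cannot extrapolate")
        auc_inf = float(cum[-1] + c_last / lam)
        cl_over_f = dose_mg * MG_TO_NG / auc_inf / 1000.0  # L/h
        return PKParameters(auc_0_inf=auc_inf, auc_0_168=auc_0_168,
                            cmax=cmax, tmax=tmax, t_half=t_half,
                            cl_over_f=cl_over_f, lambda_z=lam,
                            n_lambda_z=n_lam, r2_adj=r2)
    return PKParameters(auc_0_inf=None, auc_0_168=auc_0_168, cmax=cmax,
                        tmax=tmax, t_half=t_half, cl_over_f=None,
                        lambda_z=lam, n_lambda_z=n_lam, r2_adj=r2)
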