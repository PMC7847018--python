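"""Noncompartmental analysis of a pre-filter concentration-time profile.

The bench experiments are one-hour bolus decays sampled at
0, 10, 20, 30, 45 and 60 min, so the profile is mono-exponential by design:
the terminal slope λz is fit on the log scale, AUC is integrated with the
linear-up/log-down trapezoid, and clearance and volume follow from the dose.

Because the sampling window is one hour, ``AUC_0_24`` is reported as
``24 × AUC_0_last`` (exposure scales proportionally in a linear system).

Units: concentrations ng/mL, times enter in minutes and are converted to
hours here, AUC ng·h/mL, CL L/h, Vz L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import Analyte, ConcentrationSeries, ExperimentRecord, Site

__all__ = ["NCAResult", "fit_lambda_z", "auc_lin_up_log_down", "nca_complete"]


class NCAError(ValueError):
    """Raised when a profile cannot support the requested estimate."""


@dataclass
class NCAResult:
    """Per-experiment noncompartmental parameter bundle."""

    C_max: float
    C_last: float
    lambda_z: float  # hr^-1
    t_half: float  # h
    AUC_0_last: float  # ng·h/mL
    AUC_0_inf: float  # ng·h/mL
    AUC_0_24: float  # ng·h/mL
    CL: float = math.nan  # L/h (needs dose)
    Vz: float = math.nan  # L (needs dose)
    lambda_z_points_used: int = 0
    lambda_z_r2: float = math.nan

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _positive_terminal_points(
    times_h: np.ndarray, conc: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Points strictly after Cmax with C > 0 (zero/BLQ excluded from log fit)."""
    pos = conc > 0
    if not pos.any():
        raise NCAError("no positive concentrations")
    i_max = int(np.argmax(conc))
    sel = pos & (np.arange(len(conc)) > i_max)
    if sel.sum() < 3:
        # tiny profiles: fall back to every positive point from Cmax onward
        sel = pos & (np.arange(len(conc)) >= i_max)
    return times_h[sel], conc[sel]


def _loglinear(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(t, np.log(c), 1)
    pred = slope * t + intercept
    y = np.log(c)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), r2


def fit_lambda_z(
    series: ConcentrationSeries, n_points: Optional[int] = None, auto: bool = False
) -> tuple[float, float, int]:
    """Terminal elimination rate constant from a log-linear fit.

    Parameters
    ----------
    series
        Pre-filter profile (times min, conc ng/mL).
    n_points
        Use exactly the last ``n_points`` positive post-peak points.
        Default: all positive points after Cmax.
    auto
        Pick the terminal window (≥3 points, excluding Cmax) maximizing
        adjusted r² of the log-linear fit.

    Returns
    -------
    (lambda_z, r2, points_used)
        ``lambda_z`` in hr⁻¹.  A non-positive slope yields ``lambda_z ≤ 0``
        flagged to the caller via the returned value; downstream operations
        refuse extrapolation for such fits.
    """
    t_all, c_all = _positive_terminal_points(series.times_h, series.concentrations)
    if len(t_all) < 3:
        raise NCAError("need at least 3 positive concentrations for lambda_z")

    if auto:
        best = None
        for n in range(3, len(t_all) + 1):
            t, c = t_all[-n:], c_all[-n:]
            slope, r2 = _loglinear(t, c)
            adj = 1 - (1 - r2) * (n - 1) / (n - 2)
            if best is None or adj > best[0] + 1e-12:
                best = (adj, slope, r2, n)
        _, slope, r2, n = best
        return -slope, r2, n

    if n_points is not None:
        if n_points < 3:
            raise NCAError("lambda_z needs at least 3 points")
        if n_points > len(t_all):
            raise NCAError(f"only {len(t_all)} terminal points available")
        t_all, c_all = t_all[-n_points:], c_all[-n_points:]
    slope, r2 = _loglinear(t_all, c_all)
    return -slope, r2, len(t_all)


def auc_lin_up_log_down(series: ConcentrationSeries) -> float:
    """AUC(0→last) by the linear-up/log-down trapezoidal rule, ng·h/mL.

    Rising or flat intervals (or any interval touching a zero) use the linear
    trapezoid; strictly decreasing intervals with both endpoints positive use
    the logarithmic trapezoid, which is exact on exponential decay.
    """
    t = series.times_h
    c = series.concentrations
    if len(t) < 2:
        raise NCAError("AUC needs at least 2 points")
    auc = 0.0
    for i in range(len(t) - 1):
        c1, c2, dt = c[i], c[i + 1], t[i + 1] - t[i]
        if c2 < c1 and c1 > 0 and c2 > 0:
            auc += (c1 - c2) * dt / math.log(c1 / c2)
        else:
            auc += 0.5 * (c1 + c2) * dt
    return float(auc)


def nca_complete(
    rec: ExperimentRecord,
    lambda_z_points: Optional[int] = None,
    lambda_z_auto: bool = False,
) -> NCAResult:
    """Full noncompartmental workup of the pre-filter apixaban profile.

    ``AUC_0_inf = AUC_0_last + C_last/λz``; ``CL = dose/AUC_0_inf`` and
    ``Vz = CL/λz`` when a dose is recorded, NaN otherwise.
    """
    series = rec.get_series(Site.pre_filter, Analyte.apixaban)
    if series is None:
        raise NCAError("record has no pre-filter apixaban series")
    conc = series.concentrations
    lam, r2, n_used = fit_lambda_z(series, n_points=lambda_z_points, auto=lambda_z_auto)

    c_max = float(conc.max())
    pos = conc > 0
    c_last = float(conc[pos][-1])
    auc_last = auc_lin_up_log_down(series)
    if lam <= 0:
        raise NCAError("non-positive terminal slope; refusing extrapolation")
    auc_inf = auc_last + c_last / lam

    res = NCAResult(
        C_max=c_max,
        C_last=c_last,
        lambda_z=lam,
        t_half=math.log(2) / lam,
        AUC_0_last=auc_last,
        AUC_0_inf=auc_inf,
        AUC_0_24=24.0 * auc_last,
        lambda_z_points_used=n_used,
        lambda_z_r2=r2,
    )
    if rec.dose_mg is not None:
        # AUC ng·h/mL ≡ µg·h/L; /1000 → mg·h/L so that mg / (mg·h/L) = L/h
        res.CL = rec.dose_mg / (auc_inf / 1000.0)
        res.Vz = res.CL / lam
    return res
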