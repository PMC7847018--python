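"""Exposure-matched apixaban dose optimization for CRRT.

Transmembrane clearance is predicted from the fitted linear model
(``CL_TM = b0 + b_filter·code + b_flow·Q``, filter coded HF1400=1, M150=2),
non-renal clearance is added (``CL_T = CL_TM + CL_NR``, CL_NR = 2.52 L/h,
residual renal function assumed negligible), and the total daily dose
matching the healthy-subject steady-state exposure target
(AUC_0-24 = 2103.8 ng·h/mL for 5 mg BID) follows from ``AUC = Dose/CL_T``:

    TDD (mg) = target_AUC (mg·h/L) × CL_T (L/h)

All intermediate values are carried unrounded; only the final single dose is
rounded to the tablet increment (2.5 mg), with exact midpoints rounded DOWN
as the conservative choice for an anticoagulant, and single doses capped at
10 mg to stay within apixaban's linear-absorption range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from . import reference
from .core import FILTER_FROM_CODE, Filter
from .inference import RegressionFit

__all__ = ["DosingPolicy", "DoseRecommendation", "predict_cl_tm", "optimal_tdd",
           "round_regimen", "dose_table"]


@dataclass(frozen=True)
class DosingPolicy:
    """Constants of the exposure-matching calculation."""

    CL_NR: float = reference.CL_NR_L_H  # non-renal clearance, L/h
    target_AUC_24: float = reference.TARGET_AUC_24  # ng·h/mL
    tablet_increment: float = 2.5  # mg
    doses_per_day: int = 2  # BID
    max_single_dose: float = 10.0  # mg
    residual_renal_cl: float = 0.0  # L/h, exposed for sensitivity use

    def __post_init__(self) -> None:
        if min(self.CL_NR, self.target_AUC_24, self.tablet_increment,
               self.max_single_dose) <= 0 or self.doses_per_day <= 0:
            raise ValueError("policy fields must be strictly positive")
        if (self.max_single_dose / self.tablet_increment) % 1 != 0:
            raise ValueError("tablet_increment must divide max_single_dose")


@dataclass
class DoseRecommendation:
    flow_rate: float
    cl_tm: dict[str, float]  # per filter, L/h
    cl_t: dict[str, float]  # per filter, L/h
    tdd_exact: dict[str, float]  # per filter, mg/day
    single_dose: dict[str, float]  # per filter, mg (rounded)
    regimen: str


_DEFAULT_COEFS = (
    reference.REGRESSION_INTERCEPT,
    reference.REGRESSION_FILTER_COEF,
    reference.REGRESSION_FLOW_COEF,
)


def _coefs(fit: Optional[RegressionFit]) -> tuple[float, float, float]:
    if fit is None:
        return _DEFAULT_COEFS
    return (
        float(fit.params.get("const", 0.0)),
        float(fit.params.get("filter", 0.0)),
        float(fit.params.get("flow", 0.0)),
    )


def predict_cl_tm(
    filter_code: int, flow_rate: float, fit: Optional[RegressionFit] = None
) -> float:
    """Predicted transmembrane clearance (L/h), carried unrounded."""
    if filter_code not in FILTER_FROM_CODE:
        raise ValueError(f"invalid filter code {filter_code!r} (expected 1 or 2)")
    if not 0.5 <= flow_rate <= 5.0:
        warnings.warn(
            f"flow rate {flow_rate} L/h outside the studied 0.5-5 L/h range; "
            "prediction is an extrapolation",
            stacklevel=2,
        )
    b0, b_filter, b_flow = _coefs(fit)
    return b0 + b_filter * filter_code + b_flow * flow_rate


def optimal_tdd(cl_tm: float, policy: DosingPolicy = DosingPolicy()) -> float:
    """Total daily dose (mg) matching the target 24-h exposure."""
    if cl_tm < 0:
        raise ValueError("cl_tm must be non-negative")
    cl_t = cl_tm + policy.CL_NR + policy.residual_renal_cl
    return (policy.target_AUC_24 / 1000.0) * cl_t


def round_regimen(
    tdd_exact: float, policy: DosingPolicy = DosingPolicy()
) -> tuple[float, str]:
    """Round the per-administration dose to the tablet increment.

    Nearest multiple of the increment; exact midpoints round down (safety);
    floored at one tablet.  Raises if the rounded single dose would exceed
    the linear-PK cap.
    """
    if tdd_exact <= 0:
        raise ValueError("tdd_exact must be positive")
    single = tdd_exact / policy.doses_per_day
    ratio = single / policy.tablet_increment
    n = max(1, math.ceil(ratio - 0.5))  # round half down
    dose = n * policy.tablet_increment
    if dose > policy.max_single_dose:
        raise ValueError(
            f"rounded single dose {dose} mg exceeds the {policy.max_single_dose} mg "
            "cap that preserves linear absorption"
        )
    label = f"{dose:g} mg {'BID' if policy.doses_per_day == 2 else f'x{policy.doses_per_day}/day'}"
    return dose, label


def _range_label(doses: Sequence[float], policy: DosingPolicy) -> str:
    unit = "BID" if policy.doses_per_day == 2 else f"x{policy.doses_per_day}/day"
    lo, hi = min(doses), max(doses)
    if lo == hi:
        return f"{lo:g} mg {unit}"
    return f"{lo:g}–{hi:g} mg {unit}"


def dose_table(
    flow_rates: Sequence[float],
    policy: DosingPolicy = DosingPolicy(),
    fit: Optional[RegressionFit] = None,
    filters: Sequence[Filter] = (Filter.HF1400, Filter.M150),
) -> list[DoseRecommendation]:
    """One recommendation per flow rate; regimen label spans the filters."""
    if not len(flow_rates):
        raise ValueError("flow_rates must be non-empty")
    out = []
    for q in flow_rates:
        cl_tm = {f.value: predict_cl_tm(f.code, q, fit) for f in filters}
        cl_t = {k: v + policy.CL_NR + policy.residual_renal_cl for k, v in cl_tm.items()}
        tdd = {k: optimal_tdd(v, policy) for k, v in cl_tm.items()}
        rounded = {k: round_regimen(v, policy)[0] for k, v in tdd.items()}
        out.append(
            DoseRecommendation(
                flow_rate=q,
                cl_tm=cl_tm,
                cl_t=cl_t,
                tdd_exact=tdd,
                single_dose=rounded,
                regimen=_range_label(list(rounded.values()), policy),
            )
        )
    return out


def dose_table_frame(recs: Sequence[DoseRecommendation]) -> pd.DataFrame:
    """Flatten recommendations to the published table layout."""
    rows = []
    for r in recs:
        row = {"flow_rate_L_h": r.flow_rate}
        for filt, v in r.cl_tm.items():
            row[f"cl_tm_{filt}"] = v
        for filt, v in r.cl_t.items():
            row[f"cl_t_{filt}"] = v
        for filt, v in r.tdd_exact.items():
            row[f"tdd_{filt}"] = v
        row["regimen"] = r.regimen
        rows.append(row)
    return pd.DataFrame(rows)
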