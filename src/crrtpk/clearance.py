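"""Transmembrane clearance, filter adsorption and protein binding.

Two estimators of transmembrane clearance (CL_TM) are provided:

* **by AUC** (primary): ``CL_TM = dose / AUC_0_inf`` from the
  noncompartmental workup — in a closed in vitro circuit the only
  elimination route is the filter, so total CL ≡ CL_TM.
* **by SC/SA** (secondary): the sieving coefficient ``SC = C_uf/C_pre``
  (convection) or saturation coefficient ``SA = 2·C_d/(C_pre+C_post)``
  (diffusion) times the effluent flow.  For CVVH with pre-filter replacement
  fluid an optional dilution correction ``Q_b/(Q_b+Q_rep)`` can be applied;
  it is OFF by default because the study's reported clearances equal
  SC × flow for every condition, including 100% pre-dilution.

Adsorption in the closed (no-elimination) circuit is quantified as the
unrecovered mass fraction ``1 − C(t)·V/dose``, and protein binding from
paired total/ultrafiltrate concentrations as ``(total − unbound)/total``.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import Analyte, CircuitConfig, ConcentrationSeries, ExperimentRecord, Mode, Site
from .nca import NCAResult

__all__ = [
    "ClearanceEstimate",
    "AdsorptionResult",
    "ProteinBindingResult",
    "sieving_coefficient",
    "saturation_coefficient",
    "sc_sa_for_record",
    "cl_tm_by_scsa",
    "cl_tm_by_auc",
    "sc_variants",
    "adsorption_percent",
    "protein_binding",
]


class ClearanceMethod(str, enum.Enum):
    by_AUC = "by_AUC"
    by_SC_SA = "by_SC_SA"


@dataclass
class ClearanceEstimate:
    method: ClearanceMethod
    CL_TM: float  # L/h
    config: Optional[CircuitConfig] = None
    sc_or_sa: Optional[float] = None  # absent for by_AUC
    dilution_corrected: bool = False

    def __post_init__(self) -> None:
        if self.CL_TM < 0:
            raise ValueError("CL_TM must be non-negative")


@dataclass
class AdsorptionResult:
    percent_adsorbed_peak: float
    percent_adsorbed_final: float
    times_min: np.ndarray
    profile_percent: np.ndarray  # raw per-time values, negatives preserved


@dataclass
class ProteinBindingResult:
    fraction_bound: float  # percent
    per_sample: np.ndarray
    intra_assay_cv: float  # percent


def sieving_coefficient(C_uf: float, C_pre: float) -> float:
    """SC = C_uf / C_pre (convective transfer; 1 = free passage)."""
    if C_pre <= 0:
        raise ValueError("sieving coefficient undefined for C_pre <= 0")
    return C_uf / C_pre


def saturation_coefficient(C_d: float, C_pre: float, C_post: float) -> float:
    """SA = 2·C_dialysate / (C_pre + C_post) (dialysate saturation)."""
    if C_pre + C_post <= 0:
        raise ValueError("saturation coefficient undefined: degenerate denominator")
    return 2.0 * C_d / (C_pre + C_post)


def sc_sa_for_record(rec: ExperimentRecord, analyte: Analyte | str = Analyte.apixaban) -> float:
    """Per-experiment SC (CVVH) or SA (CVVHD): mean over the paired
    effluent/post-filter sampling times (10 and 30 min on the bench)."""
    analyte = Analyte(analyte)
    pre = rec.get_series(Site.pre_filter, analyte)
    eff = rec.get_series(Site.effluent, analyte)
    if pre is None or eff is None:
        raise ValueError("record needs pre_filter and effluent series")
    pre_at = dict(zip(pre.times, pre.concentrations))
    vals = []
    if rec.config.mode is Mode.CVVH:
        for t, c_uf in zip(eff.times, eff.concentrations):
            vals.append(sieving_coefficient(c_uf, pre_at[t]))
    else:
        post = rec.get_series(Site.post_filter, analyte)
        if post is None:
            raise ValueError("CVVHD record needs a post_filter series")
        post_at = dict(zip(post.times, post.concentrations))
        for t, c_d in zip(eff.times, eff.concentrations):
            vals.append(saturation_coefficient(c_d, pre_at[t], post_at[t]))
    return float(np.mean(vals))


def cl_tm_by_scsa(
    sc_or_sa: float,
    config: CircuitConfig,
    dilution_corrected: bool = False,
) -> ClearanceEstimate:
    """Transmembrane clearance from the sieving/saturation coefficient.

    CVVHD: ``SA · Q_d``.  CVVH: ``SC · Q_uf``, or with
    ``dilution_corrected=True`` the pre-dilution form
    ``SC · Q_uf · Q_b / (Q_b + Q_rep_pre)``.
    """
    if config.mode is Mode.CVVHD:
        cl = sc_or_sa * config.effluent_flow
        dilution_corrected = False  # never applicable under CVVHD
    elif dilution_corrected:
        cl = (
            sc_or_sa
            * config.effluent_flow
            * config.blood_flow_Qb
            / (config.blood_flow_Qb + config.Q_rep_pre)
        )
    else:
        cl = sc_or_sa * config.effluent_flow
    return ClearanceEstimate(
        method=ClearanceMethod.by_SC_SA,
        CL_TM=cl,
        config=config,
        sc_or_sa=sc_or_sa,
        dilution_corrected=dilution_corrected,
    )


def cl_tm_by_auc(nca: NCAResult, dose_mg: float, config: Optional[CircuitConfig] = None) -> ClearanceEstimate:
    """Primary estimator: CL_TM = dose / AUC_0_inf (units harmonized)."""
    if dose_mg is None:
        raise ValueError("dose required for CL_TM by AUC")
    if not nca.AUC_0_inf > 0:
        raise ValueError("AUC_0_inf must be positive")
    cl = dose_mg / (nca.AUC_0_inf / 1000.0)
    return ClearanceEstimate(method=ClearanceMethod.by_AUC, CL_TM=cl, config=config)


def sc_variants(
    C_uf: float,
    config: CircuitConfig,
    C_pre_undiluted: Optional[float] = None,
    C_pre_diluted: Optional[float] = None,
    C_post_undiluted: Optional[float] = None,
    C_post_diluted: Optional[float] = None,
) -> dict[str, float]:
    """Sieving coefficient under the conventions in circulation.

    The literature computes SC against different reference concentrations:
    the pre-filter sample before or after the replacement fluid joins
    (undiluted vs diluted), optionally undoing the dilution with the factor
    ``(Q_b + Q_rep)/Q_b``, or against the pre/post-filter mean.  Variants
    whose required concentration is missing are omitted from the result.
    """
    qb, qrep = config.blood_flow_Qb, config.Q_rep_pre
    cf = (qb + qrep) / qb
    out: dict[str, float] = {}
    if C_pre_undiluted is not None and C_pre_undiluted > 0:
        out["pre_undiluted"] = C_uf / C_pre_undiluted
    if C_pre_diluted is not None and C_pre_diluted > 0:
        out["pre_diluted"] = C_uf / C_pre_diluted
        out["pre_diluted_corrected"] = C_uf / (C_pre_diluted * cf)
    if (
        C_pre_undiluted is not None
        and C_post_undiluted is not None
        and C_pre_undiluted + C_post_undiluted > 0
    ):
        out["mean_pre_post_undiluted"] = (
            2.0 * C_uf / (C_pre_undiluted + C_post_undiluted)
        )
    if (
        C_pre_diluted is not None
        and C_post_diluted is not None
        and C_pre_diluted + C_post_diluted > 0
    ):
        out["mean_pre_post_diluted"] = 2.0 * C_uf / (C_pre_diluted + C_post_diluted)
    if not out:
        raise ValueError("no pre-filter concentration available for any variant")
    return out


def adsorption_percent(
    reservoir_series: ConcentrationSeries, dose_mg: float, volume_L: float
) -> AdsorptionResult:
    """Percent of dose adsorbed to the circuit in a closed-loop run.

    With no elimination route, any dose not in solution is on the filter or
    tubing: ``percent(t) = 100·(1 − C(t)·V/dose)``.  Negative values (noise
    pushing recovery above the dose) are preserved in the profile with a
    warning and clipped to 0 only in the peak/final summaries.
    """
    if dose_mg <= 0:
        raise ValueError("dose must be positive")
    if volume_L <= 0:
        raise ValueError("reservoir volume must be positive")
    c = reservoir_series.concentrations
    recovered_mg = c * volume_L / 1000.0  # ng/mL ≡ µg/L → mg
    pct = 100.0 * (1.0 - recovered_mg / dose_mg)
    if np.any(pct < 0):
        warnings.warn(
            "recovered mass exceeds dose at some times (negative adsorption; "
            "measurement noise)",
            stacklevel=2,
        )
    summary = np.clip(pct, 0.0, None)
    return AdsorptionResult(
        percent_adsorbed_peak=float(summary.max()),
        percent_adsorbed_final=float(summary[-1]),
        times_min=reservoir_series.times.copy(),
        profile_percent=pct,
    )


def protein_binding(
    total: float | np.ndarray,
    unbound: float | np.ndarray,
    tolerance: float = 0.05,
) -> ProteinBindingResult:
    """Fraction bound (%) from paired total and ultrafiltrate concentrations."""
    total = np.atleast_1d(np.asarray(total, dtype=float))
    unbound = np.atleast_1d(np.asarray(unbound, dtype=float))
    if np.any(total <= 0):
        raise ValueError("total concentration must be positive")
    if np.any(unbound < 0) or np.any(unbound > total * (1.0 + tolerance)):
        raise ValueError("unbound concentration outside [0, total] beyond tolerance")
    per_sample = 100.0 * (total - np.minimum(unbound, total)) / total
    mean = float(per_sample.mean())
    cv = float(100.0 * per_sample.std(ddof=1) / mean) if len(per_sample) > 1 and mean else 0.0
    return ProteinBindingResult(
        fraction_bound=mean, per_sample=per_sample, intra_assay_cv=cv
    )
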