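"""Synthetic bench-circuit experiments with known ground truth.

The study's raw per-experiment concentrations are unpublished, so recovery
tests and end-to-end checks run on simulated data with the same structure:

* **Open circuit** (clearance runs): a stirred reservoir of volume V losing
  drug through the filter at clearance CL gives mono-exponential decay
  ``C(t) = C0·e^(−(CL/V)t)``; effluent and post-filter concentrations follow
  from the sieving coefficient and single-pass plasma mass balance
  ``C_post = C_pre·(1 − CL/Q_plasma)``.  Sampled at 0, 10, 20, 30, 45,
  60 min like the bench runs.
* **Closed circuit** (adsorption runs): effluent rerouted to the reservoir,
  so the only sink is reversible single-site (Langmuir-type) binding to the
  filter, integrated over 180 min with mass conservation ``C·V + A = dose``.
* **Protein binding**: paired total/ultrafiltrate samples at a true bound
  fraction.

Noise is multiplicative lognormal per sample (median 1), default CV 5%,
within the assay's acceptance range.  Condition-level truth for the 24-run
study layout defaults to the reported noncompartmental clearance means, with
lognormal between-replicate variability (CV 30%) bracketing the reported
per-condition SDs.  All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import reference
from .core import (
    Analyte,
    CircuitConfig,
    ConcentrationSeries,
    ExperimentRecord,
    Filter,
    Mode,
    Site,
)

__all__ = [
    "AdsorptionKinetics",
    "SimulationSpec",
    "simulate_open_circuit",
    "simulate_closed_circuit",
    "simulate_protein_binding",
    "generate_study",
    "adsorption_kinetics_for_fraction",
]

#: Bench sampling schedules (minutes).
OPEN_SCHEDULE = (0.0, 10.0, 20.0, 30.0, 45.0, 60.0)
PAIRED_SCHEDULE = (10.0, 30.0)
CLOSED_SCHEDULE = (0.0, 10.0, 20.0, 30.0, 45.0, 60.0, 90.0, 105.0, 120.0, 150.0, 180.0)

#: 1 L blood + ~0.19 L circuit prime.
DEFAULT_RESERVOIR_VOLUME_L = 1.19
#: Reservoir spiked to the healthy-subject single-dose peak, 0.104 mg/L.
DEFAULT_C0_NG_ML = 104.0


@dataclass(frozen=True)
class AdsorptionKinetics:
    """Reversible single-site filter binding.

    ``A_max`` is the binding capacity (mg), ``k_on`` the association rate
    (per h per ng/mL of free drug), ``k_off`` the dissociation rate (per h).
    """

    A_max: float  # mg
    k_on: float  # 1/(h·ng/mL)
    k_off: float  # 1/h

    def __post_init__(self) -> None:
        if min(self.A_max, self.k_on, self.k_off) < 0:
            raise ValueError("adsorption rates/capacity must be non-negative")
        if self.A_max == 0 and self.k_on > 0:
            raise ValueError("k_on > 0 requires a positive binding capacity")


def adsorption_kinetics_for_fraction(
    fraction_bound: float,
    dose_mg: float,
    volume_L: float = DEFAULT_RESERVOIR_VOLUME_L,
    A_max: Optional[float] = None,
    k_off: float = 6.0,
) -> AdsorptionKinetics:
    """Kinetics whose closed-circuit equilibrium binds ``fraction_bound`` of
    the dose (solving the Langmuir balance exactly for k_on)."""
    if not 0 < fraction_bound < 1:
        raise ValueError("fraction_bound must lie in (0, 1)")
    if A_max is None:
        A_max = 4.0 * dose_mg  # far from saturation, as observed
    A_eq = fraction_bound * dose_mg
    if A_eq >= A_max:
        raise ValueError("capacity A_max too small for requested bound fraction")
    C_eq = 1000.0 * (1.0 - fraction_bound) * dose_mg / volume_L  # ng/mL
    k_on = k_off * A_eq / (C_eq * (A_max - A_eq))
    return AdsorptionKinetics(A_max=A_max, k_on=k_on, k_off=k_off)


@dataclass
class SimulationSpec:
    """Everything one simulated experiment needs."""

    config: CircuitConfig
    CL_true: float  # L/h
    sc_true: float  # SC (CVVH) or SA (CVVHD)
    dose_mg: float = DEFAULT_C0_NG_ML * DEFAULT_RESERVOIR_VOLUME_L / 1000.0
    reservoir_volume_L: float = DEFAULT_RESERVOIR_VOLUME_L
    adsorption: Optional[AdsorptionKinetics] = None
    noise_cv: float = 0.05
    seed: int = 0
    schedule: Sequence[float] = OPEN_SCHEDULE
    paired_schedule: Sequence[float] = PAIRED_SCHEDULE

    def __post_init__(self) -> None:
        if self.CL_true < 0 or self.reservoir_volume_L <= 0 or self.dose_mg <= 0:
            raise ValueError("rates, volume and dose must be positive")
        if not 0 <= self.noise_cv < 1:
            raise ValueError("noise_cv must lie in [0, 1)")


def _noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(0.0, sigma, size))  # median-1 multiplicative


def simulate_open_circuit(spec: SimulationSpec) -> ExperimentRecord:
    """One clearance run: pre-filter decay plus paired post-filter/effluent
    samples, with per-sample multiplicative noise."""
    if spec.CL_true <= 0:
        raise ValueError("open-circuit simulation needs CL_true > 0")
    cfg = spec.config
    if spec.CL_true > cfg.plasma_flow:
        raise ValueError(
            f"CL_true {spec.CL_true} exceeds plasma flow {cfg.plasma_flow:.3f} L/h "
            "(single-pass extraction > 1)"
        )
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.schedule, float)
    t_h = t / 60.0
    k = spec.CL_true / spec.reservoir_volume_L
    C0 = 1000.0 * spec.dose_mg / spec.reservoir_volume_L  # ng/mL, fully mixed at t=0
    c_pre = C0 * np.exp(-k * t_h)

    extraction = spec.CL_true / cfg.plasma_flow
    tp = np.asarray(spec.paired_schedule, float)
    c_pre_paired = C0 * np.exp(-k * tp / 60.0)
    c_post = c_pre_paired * (1.0 - extraction)
    if cfg.mode is Mode.CVVH:
        c_eff = spec.sc_true * c_pre_paired
    else:
        c_eff = spec.sc_true * (c_pre_paired + c_post) / 2.0

    c_pre_obs = c_pre * _noise(rng, spec.noise_cv, len(t))
    c_post_obs = c_post * _noise(rng, spec.noise_cv, len(tp))
    c_eff_obs = c_eff * _noise(rng, spec.noise_cv, len(tp))
    series = [
        ConcentrationSeries(Site.pre_filter, Analyte.apixaban, t, c_pre_obs),
        ConcentrationSeries(Site.post_filter, Analyte.apixaban, tp, c_post_obs),
        ConcentrationSeries(Site.effluent, Analyte.apixaban, tp, c_eff_obs),
    ]
    return ExperimentRecord(config=cfg, series=series, dose_mg=spec.dose_mg)


def simulate_closed_circuit(spec: SimulationSpec) -> ExperimentRecord:
    """One adsorption run: no elimination, reversible filter binding.

    Integrates (mass units mg; C in ng/mL = 1000·M_free/V):

        dA/dt = k_on·C·(A_max − A) − k_off·A,   M_free = dose − A

    over the 180-min closed-circuit schedule.  Mass is conserved exactly by
    construction; the integrator tolerance only enters through A(t).
    """
    ads = spec.adsorption
    if ads is None:
        raise ValueError("closed-circuit simulation needs adsorption kinetics")
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.schedule if spec.schedule is not OPEN_SCHEDULE else CLOSED_SCHEDULE, float)
    t_h = t / 60.0
    V = spec.reservoir_volume_L

    def rhs(_t, y):
        (A,) = y
        C = 1000.0 * (spec.dose_mg - A) / V
        return [ads.k_on * C * (ads.A_max - A) - ads.k_off * A]

    if ads.k_on == 0:
        A = np.zeros_like(t_h)
    else:
        sol = solve_ivp(
            rhs, (0.0, float(t_h[-1])), [0.0], t_eval=t_h, method="LSODA",
            rtol=1e-10, atol=1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"adsorption ODE failed: {sol.message}")
        A = sol.y[0]
    c = 1000.0 * (spec.dose_mg - A) / V
    c_obs = c * _noise(rng, spec.noise_cv, len(t))
    series = [ConcentrationSeries(Site.reservoir, Analyte.apixaban, t, c_obs)]
    return ExperimentRecord(config=spec.config, series=series, dose_mg=spec.dose_mg)


def simulate_protein_binding(
    fraction_bound_true: float,
    totals: Sequence[float] = (104.0, 104.0, 52.0, 52.0),
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (total, unbound) ultrafiltration samples; percent input."""
    if not 0 <= fraction_bound_true <= 100:
        raise ValueError("fraction_bound_true is a percent in [0, 100]")
    rng = np.random.default_rng(seed)
    totals = np.asarray(totals, float)
    unbound = totals * (1.0 - fraction_bound_true / 100.0)
    unbound = unbound * _noise(rng, noise_cv, len(totals))
    return totals, unbound


# ---------------------------------------------------------------------------
# full-study generator

def _default_design() -> pd.DataFrame:
    """The 12 study conditions with reported clearance/SC truth attached."""
    d = reference.NCA_CL_TM_SUMMARY.merge(
        reference.CONDITION_SUMMARY[["mode", "filter", "flow", "dilution", "sc_sa"]],
        on=["mode", "filter", "flow", "dilution"],
        how="left",
    )
    return d.rename(columns={"cl_tm": "cl_true", "sc_sa": "sc_true"})


def generate_study(
    design: Optional[pd.DataFrame] = None,
    n_replicates: int = 2,
    noise_cv: float = 0.05,
    between_replicate_cv: float = 0.30,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full open-circuit study (12 conditions × replicates).

    Parameters
    ----------
    design
        Condition table with columns mode, filter, flow, dilution, cl_true,
        sc_true (default: the reported condition-level truth).
    between_replicate_cv
        Lognormal CV of each replicate's realized clearance around its
        condition mean; 0 makes replicates share the exact condition truth.

    Returns
    -------
    (tidy, truth)
        ``tidy`` is the long-format sample table consumed by the pipeline;
        ``truth`` carries each run's realized CL and SC for recovery tests.
    """
    design = _default_design() if design is None else design.copy()
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for i, cond in design.iterrows():
        dilution = cond["dilution"]
        cfg = CircuitConfig(
            mode=Mode(cond["mode"]),
            filter=Filter(cond["filter"]),
            effluent_flow=float(cond["flow"]),
            dilution_split=None if pd.isna(dilution) else float(dilution),
        )
        for rep in range(n_replicates):
            cl_rep = float(cond["cl_true"]) * float(
                _noise(rng, between_replicate_cv, ())
            )
            cl_rep = min(cl_rep, 0.99 * cfg.plasma_flow)
            exp_id = f"{cond['mode']}_{cond['filter']}_{cond['flow']:g}"
            if not pd.isna(dilution):
                exp_id += f"_d{dilution:g}"
            spec = SimulationSpec(
                config=cfg,
                CL_true=cl_rep,
                sc_true=float(cond["sc_true"]),
                noise_cv=noise_cv,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rec = simulate_open_circuit(spec)
            rep_id = f"r{rep + 1}"
            for s in rec.series:
                for t, c in zip(s.times, s.concentrations):
                    rows.append(
                        {
                            "experiment_id": exp_id,
                            "replicate_id": rep_id,
                            "mode": cfg.mode.value,
                            "filter": cfg.filter.value,
                            "effluent_flow_L_h": cfg.effluent_flow,
                            "dilution_split": (
                                "" if cfg.dilution_split is None else cfg.dilution_split
                            ),
                            "analyte": s.analyte.value,
                            "site": s.site.value,
                            "time_min": t,
                            "conc_ng_mL": c,
                            "dose_mg": spec.dose_mg,
                        }
                    )
            truth_rows.append(
                {
                    "experiment_id": exp_id,
                    "replicate_id": rep_id,
                    "cl_true": cl_rep,
                    "cl_condition_mean": float(cond["cl_true"]),
                    "sc_true": float(cond["sc_true"]),
                }
            )
    tidy = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    dup = truth.duplicated(["experiment_id", "replicate_id"])
    if dup.any():
        raise ValueError("duplicate replicate ids in design")
    return tidy, truth
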