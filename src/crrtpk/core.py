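"""Shared domain types for in vitro CRRT pharmacokinetic experiments.

A bench CRRT run is described by a :class:`CircuitConfig` (mode, hemofilter,
flows, replacement-fluid dilution split), the concentration-time data sampled
at the circuit's ports as :class:`ConcentrationSeries`, and the whole
experiment as an :class:`ExperimentRecord`.

Conventions
-----------
* Concentrations are ng/mL (identically µg/L); doses are mg; flows and
  clearances are L/h.
* Time is stored in **minutes** at the data layer.  All PK math works in
  hours; the minute→hour conversion happens exactly once, on entry to the
  NCA/clearance layer (:data:`MIN_PER_H`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np

MIN_PER_H = 60.0
#: ng/mL (= µg/L) per mg/L
NG_ML_PER_MG_L = 1000.0

#: Blood flow used in every experiment: 200 mL/min.
DEFAULT_BLOOD_FLOW_L_H = 12.0
#: Measured bovine hematocrit.
DEFAULT_HEMATOCRIT = 0.369


class Mode(str, enum.Enum):
    """CRRT modality: convective (CVVH) or diffusive (CVVHD)."""

    CVVH = "CVVH"
    CVVHD = "CVVHD"


class Filter(str, enum.Enum):
    """Hemofilter set: PAES (HF1400) or AN69 (M150)."""

    HF1400 = "HF1400"
    M150 = "M150"

    @property
    def code(self) -> int:
        """Numeric regression coding: HF1400 → 1, M150 → 2."""
        return FILTER_CODES[self]


FILTER_CODES = {Filter.HF1400: 1, Filter.M150: 2}
FILTER_FROM_CODE = {v: k for k, v in FILTER_CODES.items()}


class Site(str, enum.Enum):
    pre_filter = "pre_filter"
    post_filter = "post_filter"
    effluent = "effluent"
    reservoir = "reservoir"
    ultrafiltrate_protein = "ultrafiltrate_protein"


class Analyte(str, enum.Enum):
    apixaban = "apixaban"
    urea = "urea"


def to_mg_per_L(conc_ng_mL: float) -> float:
    return conc_ng_mL / NG_ML_PER_MG_L


def to_ng_per_mL(conc_mg_L: float) -> float:
    return conc_mg_L * NG_ML_PER_MG_L


@dataclass(frozen=True)
class CircuitConfig:
    """One CRRT run's settings.

    Parameters
    ----------
    mode
        CVVH (hemofiltration) or CVVHD (hemodialysis).
    filter
        Hemofilter set.
    effluent_flow
        Ultrafiltration rate Q_uf (CVVH) or dialysate rate Q_d (CVVHD), L/h.
    dilution_split
        Fraction of CVVH replacement fluid given pre-filter, in [0, 1]
        (1.0 = 100/0%, 0.5 = 50/50%, 0.0 = 0/100%).  Must be ``None`` for
        CVVHD, which uses no replacement fluid.
    blood_flow_Qb
        Blood flow rate, L/h (fixed at 12 L/h = 200 mL/min on the bench).
    hematocrit
        Carried as metadata; plasma flow is ``Qb * (1 - hematocrit)``.
    """

    mode: Mode
    filter: Filter
    effluent_flow: float
    dilution_split: Optional[float] = None
    blood_flow_Qb: float = DEFAULT_BLOOD_FLOW_L_H
    hematocrit: float = DEFAULT_HEMATOCRIT

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", Mode(self.mode))
        object.__setattr__(self, "filter", Filter(self.filter))
        if self.effluent_flow <= 0:
            raise ValueError("effluent_flow must be > 0")
        if self.mode is Mode.CVVHD:
            # dilution_split is meaningless under CVVHD; it is ignored by all
            # flow math and flagged by validate_experiment if present.
            pass
        else:
            if self.dilution_split is None:
                raise ValueError("CVVH requires a dilution_split in [0, 1]")
            if not 0.0 <= self.dilution_split <= 1.0:
                raise ValueError("dilution_split must lie in [0, 1]")

    @property
    def Q_rep_pre(self) -> float:
        """Pre-filter replacement-fluid flow, L/h (0 for CVVHD)."""
        if self.mode is Mode.CVVHD or self.dilution_split is None:
            return 0.0
        return self.dilution_split * self.effluent_flow

    @property
    def plasma_flow(self) -> float:
        """Plasma flow Q_b·(1 − hct), L/h."""
        return self.blood_flow_Qb * (1.0 - self.hematocrit)

    @property
    def filter_code(self) -> int:
        return self.filter.code


@dataclass
class ConcentrationSeries:
    """Timestamped concentrations at one sampling site.

    ``times`` are minutes (strictly increasing), ``concentrations`` ng/mL
    (non-negative).
    """

    site: Site
    analyte: Analyte
    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        self.site = Site(self.site)
        self.analyte = Analyte(self.analyte)
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)

    def findings(self) -> list[str]:
        out = []
        if len(self.times) != len(self.concentrations):
            out.append(
                f"{self.site.value}/{self.analyte.value}: times and "
                "concentrations differ in length"
            )
            return out
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            out.append(
                f"{self.site.value}/{self.analyte.value}: times not strictly increasing"
            )
        if np.any(self.concentrations < 0):
            out.append(
                f"{self.site.value}/{self.analyte.value}: negative concentration"
            )
        return out

    @property
    def times_h(self) -> np.ndarray:
        return self.times / MIN_PER_H


@dataclass
class ExperimentRecord:
    """One circuit experiment: configuration, dose and all sampled series."""

    config: CircuitConfig
    series: list[ConcentrationSeries]
    dose_mg: Optional[float] = None
    replicate_id: str = ""
    experiment_id: str = ""

    def get_series(
        self, site: Site | str, analyte: Analyte | str = Analyte.apixaban
    ) -> Optional[ConcentrationSeries]:
        site, analyte = Site(site), Analyte(analyte)
        for s in self.series:
            if s.site is site and s.analyte is analyte:
                return s
        return None


def validate_experiment(rec: ExperimentRecord) -> list[str]:
    """Check every type invariant; return one finding per violation.

    An empty list means the record is well formed.  Violations are reported
    as findings rather than raised, so a whole dataset can be screened.
    """
    findings: list[str] = []
    for s in rec.series:
        findings.extend(s.findings())

    if rec.config.mode is Mode.CVVHD and rec.config.dilution_split is not None:
        findings.append("CVVHD record carries a dilution_split; not applicable")

    # exactly one pre-filter series per analyte present in the record
    analytes = {s.analyte for s in rec.series}
    for analyte in analytes:
        n_pre = sum(
            1 for s in rec.series if s.site is Site.pre_filter and s.analyte is analyte
        )
        if n_pre != 1:
            findings.append(
                f"expected exactly one pre_filter series for {analyte.value}, "
                f"found {n_pre}"
            )

    # post-filter / effluent times must be a subset of pre-filter times
    for analyte in analytes:
        pre = rec.get_series(Site.pre_filter, analyte)
        if pre is None:
            continue
        for site in (Site.post_filter, Site.effluent):
            s = rec.get_series(site, analyte)
            if s is not None and not set(s.times).issubset(set(pre.times)):
                findings.append(
                    f"{site.value}/{analyte.value}: sampled at times outside "
                    "the pre_filter schedule"
                )

    if rec.dose_mg is not None and rec.dose_mg <= 0:
        findings.append("dose_mg must be positive when present")
    return findings
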