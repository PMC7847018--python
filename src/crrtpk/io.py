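"""Tidy-CSV interchange and report writing.

The interchange format is one row per sample::

    experiment_id, replicate_id, mode, filter, effluent_flow_L_h,
    dilution_split, analyte, site, time_min, conc_ng_mL [, dose_mg]

UTF-8, '.' decimal, comma separator.  ``dose_mg`` is optional; without it
dose-dependent parameters (CL, Vz) are reported as NaN.  All computation is
full precision; display rounding happens only in :func:`write_report`.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import (
    Analyte,
    CircuitConfig,
    ConcentrationSeries,
    ExperimentRecord,
    Filter,
    Mode,
    Site,
)

__all__ = ["read_samples", "records_from_frame", "write_samples", "write_report"]

REQUIRED_COLUMNS = [
    "experiment_id",
    "replicate_id",
    "mode",
    "filter",
    "effluent_flow_L_h",
    "dilution_split",
    "analyte",
    "site",
    "time_min",
    "conc_ng_mL",
]

#: layout name -> (ordered columns, decimals per column kind)
_LAYOUTS = {
    "table1": [
        "experiment_id", "replicate_id", "C_max", "C_last", "lambda_z",
        "t_half", "Vz", "CL", "AUC_0_inf", "AUC_0_last", "AUC_0_24",
    ],
    "table2": [
        "experiment_id", "replicate_id", "mode", "filter", "flow",
        "dilution", "sc_sa", "cl_tm_scsa", "cl_tm_auc",
    ],
    "table3": ["mode", "filter", "flow", "emmean", "se", "ci_lower", "ci_upper"],
    "table4": ["variable", "coefficient", "ci_lower", "ci_upper", "p_value"],
    "table5": [
        "flow_rate_L_h", "cl_tm_HF1400", "cl_tm_M150", "cl_nr",
        "cl_t_HF1400", "cl_t_M150", "target_auc", "tdd_HF1400", "tdd_M150",
        "regimen",
    ],
}
#: 3 decimals for coefficients/ratios, 2 for clearances/doses/PK values
_THREE_DP = {"sc_sa", "lambda_z", "coefficient", "ci_lower", "ci_upper", "se", "p_value"}


def records_from_frame(df: pd.DataFrame) -> list[ExperimentRecord]:
    """Group a tidy sample table into validated experiment records."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    bad = df["conc_ng_mL"].isna() | df["time_min"].isna()
    if bad.any():
        raise ValueError(
            f"unparseable numeric value at row index {int(df.index[bad][0])}"
        )
    records = []
    for (exp_id, rep_id), grp in df.groupby(["experiment_id", "replicate_id"], sort=True):
        first = grp.iloc[0]
        dil = first["dilution_split"]
        if isinstance(dil, str) and dil.strip() == "":
            dil = None
        elif pd.isna(dil):
            dil = None
        else:
            dil = float(dil)
        cfg = CircuitConfig(
            mode=Mode(first["mode"]),
            filter=Filter(first["filter"]),
            effluent_flow=float(first["effluent_flow_L_h"]),
            dilution_split=dil,
        )
        series = []
        for (site, analyte), sgrp in grp.groupby(["site", "analyte"], sort=True):
            sgrp = sgrp.sort_values("time_min")
            series.append(
                ConcentrationSeries(
                    Site(site),
                    Analyte(analyte),
                    sgrp["time_min"].to_numpy(float),
                    sgrp["conc_ng_mL"].to_numpy(float),
                )
            )
        dose = None
        if "dose_mg" in grp.columns and not pd.isna(first.get("dose_mg", np.nan)):
            dose = float(first["dose_mg"])
        records.append(
            ExperimentRecord(
                config=cfg,
                series=series,
                dose_mg=dose,
                replicate_id=str(rep_id),
                experiment_id=str(exp_id),
            )
        )
    return records


def read_samples(path: str | Path) -> list[ExperimentRecord]:
    path = Path(path)
    df = pd.read_csv(path, dtype={"dilution_split": object})
    try:
        df["time_min"] = pd.to_numeric(df["time_min"])
        df["conc_ng_mL"] = pd.to_numeric(df["conc_ng_mL"])
    except (ValueError, KeyError) as exc:
        raise ValueError(f"unparseable numeric column in {path}: {exc}") from exc
    return records_from_frame(df)


def write_samples(records: Iterable[ExperimentRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        cfg = rec.config
        for s in rec.series:
            for t, c in zip(s.times, s.concentrations):
                rows.append(
                    {
                        "experiment_id": rec.experiment_id,
                        "replicate_id": rec.replicate_id,
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
                        "dose_mg": "" if rec.dose_mg is None else rec.dose_mg,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def _fmt(col: str, x) -> str:
    if isinstance(x, str) or x is None or (isinstance(x, float) and math.isnan(x)):
        return "" if x is None or (isinstance(x, float) and math.isnan(x)) else x
    if not isinstance(x, (int, float, np.floating, np.integer)):
        return str(x)
    nd = 3 if col in _THREE_DP else 2
    return f"{x:.{nd}f}"


def write_report(results: pd.DataFrame, layout: str, path: str | Path) -> pd.DataFrame:
    """Write a results table in one of the published layouts.

    Column order follows the layout; numbers are formatted at the published
    precision (3 decimals for coefficients and SC/SA, 2 elsewhere).  Returns
    the formatted frame that was written.
    """
    if layout not in _LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; expected one of {sorted(_LAYOUTS)}")
    if results is None or len(results) == 0:
        raise ValueError("results are empty; nothing written")
    cols = [c for c in _LAYOUTS[layout] if c in results.columns]
    if not cols:
        raise ValueError(f"results share no columns with layout {layout!r}")
    out = results[cols].copy()
    for c in cols:
        out[c] = [_fmt(c, v) for v in out[c]]
    out.to_csv(path, index=False)
    return out
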