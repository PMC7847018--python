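"""Model/Results facade over the whole pipeline.

``CrrtStudy`` wraps a tidy sample table (one row per measured concentration)
the way a statsmodels model wraps its data; ``fit()`` runs the full analysis
— per-experiment noncompartmental workup, transmembrane clearance by both
estimators, and the backward-stepwise regression of clearance on circuit
covariates — and returns a ``CrrtStudyResults`` carrying the per-experiment
tables, the fitted regression, ANOVA access, a dosing-table builder and a
``summary()``.

Example
-------
>>> from crrtpk.simulate import generate_study
>>> from crrtpk.study import CrrtStudy
>>> tidy, truth = generate_study(seed=7)
>>> res = CrrtStudy.from_dataframe(tidy).fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .clearance import cl_tm_by_auc, cl_tm_by_scsa, sc_sa_for_record
from .core import ExperimentRecord, validate_experiment
from .dosing import DosingPolicy, dose_table, dose_table_frame
from .inference import (
    AnovaResult,
    FactorialDesign,
    RegressionFit,
    backward_stepwise,
    factorial_anova,
)
from .nca import nca_complete

__all__ = ["CrrtStudy", "CrrtStudyResults"]


class CrrtStudy:
    """An in vitro CRRT clearance study ready to be analysed."""

    def __init__(self, records: list[ExperimentRecord], strict: bool = True):
        self.records = records
        self.findings = {
            (r.experiment_id, r.replicate_id): validate_experiment(r) for r in records
        }
        bad = {k: v for k, v in self.findings.items() if v}
        if strict and bad:
            raise ValueError(f"invalid experiment records: {bad}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, strict: bool = True) -> "CrrtStudy":
        return cls(_io.records_from_frame(df), strict=strict)

    @classmethod
    def from_csv(cls, path: str | Path, strict: bool = True) -> "CrrtStudy":
        return cls(_io.read_samples(path), strict=strict)

    def fit(
        self,
        lambda_z_auto: bool = False,
        dilution_corrected: bool = False,
        alpha: float = 0.05,
    ) -> "CrrtStudyResults":
        """Run NCA, clearance estimation and the stepwise regression."""
        rows = []
        for rec in self.records:
            cfg = rec.config
            row = {
                "experiment_id": rec.experiment_id,
                "replicate_id": rec.replicate_id,
                "mode": cfg.mode.value,
                "filter": cfg.filter.value,
                "filter_code": cfg.filter_code,
                "flow": cfg.effluent_flow,
                "dilution": (
                    np.nan if cfg.dilution_split is None else cfg.dilution_split
                ),
            }
            nca = nca_complete(rec, lambda_z_auto=lambda_z_auto)
            row.update(nca.as_dict())
            sc = sc_sa_for_record(rec)
            row["sc_sa"] = sc
            row["cl_tm_scsa"] = cl_tm_by_scsa(
                sc, cfg, dilution_corrected=dilution_corrected
            ).CL_TM
            row["cl_tm_auc"] = (
                cl_tm_by_auc(nca, rec.dose_mg, cfg).CL_TM
                if rec.dose_mg is not None
                else np.nan
            )
            rows.append(row)
        table = pd.DataFrame(rows)

        reg_data = table.rename(columns={"filter": "filter_name"}).rename(
            columns={"filter_code": "filter"}
        )
        reg_data["mode_code"] = (reg_data["mode"] == "CVVHD").astype(float)
        # CVVHD uses no replacement fluid: dilution covariate is 0 there
        reg_data["dilution_cov"] = reg_data["dilution"].fillna(0.0)
        design = FactorialDesign(
            data=reg_data.assign(cl_tm=reg_data["cl_tm_auc"]),
            response="cl_tm",
            factors=("mode_code", "filter", "flow", "dilution_cov"),
        )
        regression = backward_stepwise(
            design, candidates=["mode_code", "filter", "flow", "dilution_cov"],
            alpha=alpha,
        )
        return CrrtStudyResults(
            study=self, table=table, regression=regression, alpha=alpha
        )


@dataclass
class CrrtStudyResults:
    """Estimates, uncertainties and downstream tables of a fitted study."""

    study: CrrtStudy
    table: pd.DataFrame  # per-experiment NCA + clearance estimates
    regression: RegressionFit
    alpha: float = 0.05

    @property
    def nca_table(self) -> pd.DataFrame:
        cols = [
            "experiment_id", "replicate_id", "mode", "filter", "flow", "dilution",
            "C_max", "C_last", "lambda_z", "t_half", "Vz", "CL",
            "AUC_0_inf", "AUC_0_last", "AUC_0_24",
        ]
        return self.table[cols]

    @property
    def clearance_table(self) -> pd.DataFrame:
        cols = [
            "experiment_id", "replicate_id", "mode", "filter", "flow", "dilution",
            "sc_sa", "cl_tm_scsa", "cl_tm_auc",
        ]
        return self.table[cols]

    def anova(
        self,
        response: str = "cl_tm_auc",
        factors: Sequence[str] = ("mode", "filter", "flow"),
        interactions: int = 1,
        tukey_factor: Optional[str] = None,
    ) -> AnovaResult:
        """Factorial ANOVA of either clearance estimate on circuit factors."""
        design = FactorialDesign(
            data=self.table.assign(resp=self.table[response]),
            response="resp",
            factors=tuple(factors),
        )
        return factorial_anova(
            design, interactions=interactions, tukey_factor=tukey_factor,
            alpha=self.alpha,
        )

    def dose_table(
        self,
        flow_rates: Sequence[float] = tuple(np.arange(0.5, 5.01, 0.5)),
        policy: DosingPolicy = DosingPolicy(),
        use_fitted: bool = True,
    ) -> pd.DataFrame:
        """Exposure-matched dosing per flow rate and filter.

        ``use_fitted=False`` evaluates the published regression coefficients
        instead of this study's fit.
        """
        fit = self.regression if use_fitted else None
        return dose_table_frame(dose_table(list(flow_rates), policy=policy, fit=fit))

    def summary(self) -> str:
        t = self.table
        reg = self.regression
        lines = [
            "In vitro CRRT pharmacokinetic study",
            "=" * 51,
            f"Experiments: {len(t)}  "
            f"(CVVH {int((t['mode'] == 'CVVH').sum())}, "
            f"CVVHD {int((t['mode'] == 'CVVHD').sum())})",
            f"C_max mean ± SD: {t['C_max'].mean():.1f} ± {t['C_max'].std(ddof=1):.1f} ng/mL",
            "",
            "Transmembrane clearance (L/h), mean ± SD",
            f"  by AUC:   {t['cl_tm_auc'].mean():.2f} ± {t['cl_tm_auc'].std(ddof=1):.2f}",
            f"  by SC/SA: {t['cl_tm_scsa'].mean():.2f} ± {t['cl_tm_scsa'].std(ddof=1):.2f}",
            "",
            "Backward-stepwise regression of CL_TM (by AUC)",
            f"  retained: {reg.retained or ['(intercept only)']}"
            f"   dropped: {reg.dropped}",
        ]
        for name, val in reg.params.items():
            lo, hi = reg.conf_int.loc[name]
            lines.append(
                f"  {name:>12s}: {val:8.3f}  [{lo:.3f}, {hi:.3f}]"
                f"  p={reg.pvalues[name]:.4f}"
            )
        lines.append(f"  adjusted R^2: {reg.adjusted_r2:.3f}   n={reg.nobs}")
        return "\n".join(lines)
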