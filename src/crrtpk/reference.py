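"""Published bench-study reference values used as inputs.

These constants transcribe the condition-level summary statistics reported
for apixaban in the in vitro CRRT study this package models: per-condition
sieving/saturation coefficients and transmembrane clearances, the
noncompartmental clearance means used as simulator truth, the fitted
dose-prediction regression, and the exposure-matching dosing constants.
They are *inputs* to the analysis (e.g. simulator defaults, dosing
coefficients), not expected outputs baked into tests.
"""

from __future__ import annotations

import pandas as pd

#: Per-condition sieving (CVVH) / saturation (CVVHD) coefficients and the
#: clearances reported alongside them (apixaban).  ``flow`` is the effluent
#: flow in L/h; ``dilution`` the pre-filter fraction of replacement fluid
#: (NaN for CVVHD).  ``sc_sa`` is SC for CVVH rows and SA for CVVHD rows.
CONDITION_SUMMARY = pd.DataFrame(
    [
        # mode,   filter,   flow, dilution, sc_sa, sc_sa_sd, cl_tm, cl_tm_sd
        ("CVVH", "HF1400", 2.0, 0.5, 0.608, 0.08, 1.22, 0.16),
        ("CVVH", "HF1400", 2.0, 1.0, 0.531, 0.06, 1.06, 0.11),
        ("CVVH", "HF1400", 2.0, 0.0, 0.614, 0.03, 1.23, 0.06),
        ("CVVH", "HF1400", 4.0, 0.5, 0.622, 0.04, 2.49, 0.17),
        ("CVVHD", "HF1400", 2.0, None, 0.622, 0.12, 1.24, 0.24),
        ("CVVHD", "HF1400", 4.0, None, 0.601, 0.11, 2.40, 0.43),
        ("CVVH", "M150", 2.0, 0.5, 0.612, 0.03, 1.22, 0.06),
        ("CVVH", "M150", 2.0, 1.0, 0.581, 0.07, 1.16, 0.14),
        ("CVVH", "M150", 2.0, 0.0, 0.603, 0.02, 1.21, 0.04),
        ("CVVH", "M150", 4.0, 0.5, 0.540, 0.04, 2.16, 0.17),
        ("CVVHD", "M150", 2.0, None, 0.619, 0.01, 1.24, 0.03),
        ("CVVHD", "M150", 4.0, None, 0.555, 0.05, 2.22, 0.20),
    ],
    columns=[
        "mode",
        "filter",
        "flow",
        "dilution",
        "sc_sa",
        "sc_sa_sd",
        "cl_tm",
        "cl_tm_sd",
    ],
)

#: Per-condition transmembrane clearance by AUC (noncompartmental) means and
#: SDs; the simulator uses these as condition-level truth.
NCA_CL_TM_SUMMARY = pd.DataFrame(
    [
        ("CVVH", "HF1400", 2.0, 0.5, 1.9, 0.1),
        ("CVVH", "HF1400", 2.0, 1.0, 1.7, 0.4),
        ("CVVH", "HF1400", 2.0, 0.0, 1.9, 0.2),
        ("CVVH", "HF1400", 4.0, 0.5, 3.3, 0.3),
        ("CVVHD", "HF1400", 2.0, None, 1.7, 0.2),
        ("CVVHD", "HF1400", 4.0, None, 2.2, 0.1),
        ("CVVH", "M150", 2.0, 0.5, 1.6, 0.7),
        ("CVVH", "M150", 2.0, 1.0, 1.3, 0.6),
        ("CVVH", "M150", 2.0, 0.0, 1.1, 0.6),
        ("CVVH", "M150", 4.0, 0.5, 2.1, 0.7),
        ("CVVHD", "M150", 2.0, None, 0.9, 0.7),
        ("CVVHD", "M150", 4.0, None, 1.6, 0.6),
    ],
    columns=["mode", "filter", "flow", "dilution", "cl_tm", "cl_tm_sd"],
)

#: Published linear model for predicting transmembrane clearance (L/h) from
#: the filter code (HF1400=1, M150=2) and effluent flow rate (L/h):
#: CL_TM = intercept + filter_coef·code + flow_coef·flow.
REGRESSION_INTERCEPT = 1.469
REGRESSION_FILTER_COEF = -0.821
REGRESSION_FLOW_COEF = 0.612

#: Non-renal clearance of apixaban imputed from phase 2/3 studies, L/h.
CL_NR_L_H = 2.52
#: Steady-state 24-h exposure target (5 mg BID in healthy subjects), ng·h/mL.
TARGET_AUC_24 = 2103.8

#: Mean filter adsorption fractions observed in the closed-circuit runs.
ADSORBED_FRACTION = {"HF1400": 0.381, "M150": 0.128}
#: Mean apixaban protein binding in bovine plasma, percent.
PROTEIN_BINDING_PCT = 70.81

#: Published combined dosing regimen per flow rate, 0.5–5 L/h in 0.5 steps.
PUBLISHED_REGIMENS = [
    "2.5 mg BID",
    "2.5–5 mg BID",
    "2.5–5 mg BID",
    "5 mg BID",
    "5 mg BID",
    "5 mg BID",
    "5 mg BID",
    "5 mg BID",
    "5 mg BID",
    "5–7.5 mg BID",
]
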