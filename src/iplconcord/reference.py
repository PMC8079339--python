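"""Published clinical correlation indices used as worked-example inputs.

The table below reproduces the printed per-method results of a 35-patient
biopsy-validation study of PSMA-PET and mpMRI lesion contouring (mean +/- SD
of sector-level DSC, Youden index, sensitivity and specificity per contouring
method).  The underlying patient data are not public; these summary rows are
the study-level inputs on which threshold selection and method ranking are
demonstrated and tested.

Sensitivity/specificity are percentages, as printed.  Note the printed YI
means do not exactly equal sensitivity + specificity - 1 of the printed
means — per-lesion rounding in the source; the rows are stored as printed.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "clinical_reference_table",
    "per_threshold_rows",
    "manual_method_rows",
    "TRACER_GA68_CT",
    "TRACER_F18_CT",
]

TRACER_GA68_CT = "68Ga-PSMA-PET/CT"
TRACER_F18_CT = "18F-PSMA-PET/CT"
TRACER_GA68_MRI = "68Ga-PSMA-PET/MRI"

# (method, threshold_label, threshold, dsc, dsc_sd, yi, yi_sd,
#  sens_pct, sens_sd, spec_pct, spec_sd); threshold None = manual contour,
# an absolute SUV for "abs", a fraction of SUVmax otherwise.
_ROWS = [
    (TRACER_GA68_CT, "SUV3.0", 3.0, "abs", 0.42, 0.17, 0.33, 0.14, 57, 9, 88, 18),
    (TRACER_F18_CT, "SUV3.0", 3.0, "abs", 0.45, 0.10, 0.38, 0.12, 61, 8, 90, 18),
    (TRACER_GA68_CT, "SUV40%", 0.4, "frac", 0.51, 0.15, 0.40, 0.13, 95, 21, 41, 14),
    (TRACER_GA68_CT, "SUV50%", 0.5, "frac", 0.54, 0.11, 0.44, 0.13, 93, 23, 59, 19),
    (TRACER_GA68_CT, "SUV60%", 0.6, "frac", 0.58, 0.15, 0.47, 0.16, 83, 20, 76, 21),
    (TRACER_GA68_CT, "SUV70%", 0.7, "frac", 0.63, 0.24, 0.51, 0.22, 59, 17, 90, 18),
    (TRACER_GA68_CT, "SUV80%", 0.8, "frac", 0.49, 0.13, 0.38, 0.19, 45, 23, 93, 12),
    (TRACER_F18_CT, "SUV40%", 0.4, "frac", 0.55, 0.21, 0.44, 0.18, 97, 25, 42, 18),
    (TRACER_F18_CT, "SUV50%", 0.5, "frac", 0.57, 0.23, 0.45, 0.17, 94, 21, 62, 20),
    (TRACER_F18_CT, "SUV60%", 0.6, "frac", 0.62, 0.20, 0.49, 0.21, 86, 19, 79, 24),
    (TRACER_F18_CT, "SUV70%", 0.7, "frac", 0.67, 0.18, 0.53, 0.20, 64, 23, 89, 15),
    (TRACER_F18_CT, "SUV80%", 0.8, "frac", 0.53, 0.16, 0.41, 0.24, 54, 20, 93, 15),
    (TRACER_GA68_MRI + "_man", "manual", None, "manual",
     0.61, 0.21, 0.50, 0.18, 79, 17, 97, 17),
    (TRACER_GA68_MRI, "SUV70%", 0.7, "frac", 0.62, 0.14, 0.51, 0.37, 61, 13, 96, 11),
    (TRACER_GA68_CT + "+mpMRI_man", "manual", None, "manual",
     0.59, 0.24, 0.50, 0.23, 75, 19, 92, 21),
    (TRACER_F18_CT + "+mpMRI_man", "manual", None, "manual",
     0.63, 0.19, 0.54, 0.23, 77, 23, 93, 16),
    ("mpMRI_man", "manual", None, "manual", 0.47, 0.13, 0.41, 0.16, 45, 9, 96, 9),
]

_COLS = ["method", "threshold_label", "threshold", "kind",
         "dsc_mean", "dsc_sd", "yi_mean", "yi_sd",
         "sensitivity_mean", "sensitivity_sd",
         "specificity_mean", "specificity_sd"]


def clinical_reference_table() -> pd.DataFrame:
    """The full printed per-method summary table (tidy, one row per method)."""
    return pd.DataFrame(_ROWS, columns=_COLS)


def per_threshold_rows(method: str) -> pd.DataFrame:
    """Threshold-family rows (absolute + fractional) of one PET method."""
    df = clinical_reference_table()
    out = df[(df["method"] == method) & (df["kind"].isin(["abs", "frac"]))]
    if out.empty:
        raise KeyError(f"no threshold rows for method {method!r}")
    return out.reset_index(drop=True)


def manual_method_rows() -> pd.DataFrame:
    """The manual-contouring arms (human-reader methods)."""
    df = clinical_reference_table()
    return df[df["kind"] == "manual"].reset_index(drop=True)
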