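"""Plasma lipid derivations: Friedewald LDL-C, non-HDL-C, unit conversion.

All quantities are handled on the mmol/L scale internally; a helper
converts mg/dL readings on input (1 mg/dL = 0.0259 mmol/L for
cholesterol).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: mg/dL -> mmol/L for cholesterol
CHOLESTEROL_MGDL_TO_MMOLL = 0.0259

#: Friedewald triglyceride divisor on the mmol/L scale (TG/5 in mg/dL)
FRIEDEWALD_TG_DIVISOR = 2.2

#: Friedewald validity bound: TG above this (mmol/L, ~400 mg/dL) -> LDL missing
FRIEDEWALD_TG_MAX = 4.52


def friedewald_ldl(tc, hdl, tg):
    """LDL-C (mmol/L) from the Friedewald equation ``TC - HDL - TG/2.2``.

    Returns NaN where TG exceeds the 4.52 mmol/L validity bound or where
    the derived value is negative (warned, a data-quality signal).
    Scalar inputs return a float; array inputs return an ndarray.
    """
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    for name, v in (("tc", tc), ("hdl", hdl), ("tg", tg)):
        if np.any(v[~np.isnan(v)] < 0):
            raise ValueError(f"{name} must be >= 0")
    ldl = tc - hdl - tg / FRIEDEWALD_TG_DIVISOR
    invalid = tg > FRIEDEWALD_TG_MAX
    n_invalid = int(np.sum(invalid))
    if n_invalid:
        logger.warning(
            "Friedewald LDL-C not computed for %d records with TG > %.2f mmol/L",
            n_invalid,
            FRIEDEWALD_TG_MAX,
        )
    negative = ldl < 0
    n_negative = int(np.sum(negative & ~invalid))
    if n_negative:
        logger.warning("negative derived LDL-C set missing for %d records", n_negative)
    ldl = np.where(invalid | negative, np.nan, ldl)
    return float(ldl) if ldl.ndim == 0 else ldl


def non_hdl(tc, hdl):
    """Non-HDL cholesterol: total cholesterol minus HDL-C (mmol/L)."""
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    bad = hdl > tc
    if np.any(bad[~np.isnan(tc) & ~np.isnan(hdl)] if bad.ndim else bad):
        raise ValueError("HDL-C exceeds total cholesterol (data-quality error)")
    out = tc - hdl
    return float(out) if out.ndim == 0 else out


def convert_cholesterol_units(value, direction: str):
    """Convert cholesterol between mg/dL and mmol/L.

    direction: ``"mgdl_to_mmoll"`` multiplies by 0.0259;
    ``"mmoll_to_mgdl"`` divides.
    """
    value = np.asarray(value, dtype=float)
    if np.any(value[~np.isnan(value)] < 0):
        raise ValueError("cholesterol concentration must be >= 0")
    if direction == "mgdl_to_mmoll":
        out = value * CHOLESTEROL_MGDL_TO_MMOLL
    elif direction == "mmoll_to_mgdl":
        out = value / CHOLESTEROL_MGDL_TO_MMOLL
    else:
        raise ValueError(
            f"unknown direction {direction!r}; use 'mgdl_to_mmoll' or 'mmoll_to_mgdl'"
        )
    return float(out) if out.ndim == 0 else out


def derive_lipid_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Add ``ldl_c`` and ``non_hdl_c`` columns to a lipid table.

    Expects columns ``total_cholesterol``, ``hdl_c``, ``triglycerides``
    in mmol/L; rows with missing inputs get missing derived values.
    """
    required = {"total_cholesterol", "hdl_c", "triglycerides"}
    missing = required - set(panel.columns)
    if missing:
        raise KeyError(f"lipid table missing columns: {sorted(missing)}")
    out = panel.copy()
    out["non_hdl_c"] = non_hdl(
        out["total_cholesterol"].to_numpy(), out["hdl_c"].to_numpy()
    )
    out["ldl_c"] = friedewald_ldl(
        out["total_cholesterol"].to_numpy(),
        out["hdl_c"].to_numpy(),
        out["triglycerides"].to_numpy(),
    )
    return out
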