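"""Diet-score computation: APDQS quintile-rank scoring and the Keys Score.

APDQS: each beneficial food group contributes 0-4 points by ascending
intake quintile within the analysis sample, each adverse group 4-0
(reverse), neutral groups 0; the total ranges 0-132.

Keys Score: 1.35*(2*P_sf - P_pufa) + 1.5*sqrt(C), with P_sf and P_pufa
the percent of energy from saturated and polyunsaturated fat and C the
dietary cholesterol density in mg per 1000 kcal.  Higher values predict
higher serum cholesterol.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .catalog import (
    RATING_ADVERSE,
    RATING_BENEFICIAL,
    RATING_NEUTRAL,
    FoodGroupCatalog,
)

logger = logging.getLogger(__name__)

#: empirical quintile cut points (percentiles)
QUINTILE_PERCENTILES = (20.0, 40.0, 60.0, 80.0)

#: kcal per gram, Atwater-style factors
KCAL_PER_GRAM = {"fat": 9.0, "carbohydrate": 4.0, "protein": 4.0, "alcohol": 7.0}


def quintile_cut_points(values: np.ndarray) -> np.ndarray:
    """20/40/60/80th empirical percentiles of the non-missing values."""
    values = np.asarray(values, dtype=float)
    finite = values[~np.isnan(values)]
    if finite.size < 5:
        raise ValueError(
            f"need at least 5 non-missing values to form quintiles, got {finite.size}"
        )
    return np.percentile(finite, QUINTILE_PERCENTILES)


def assign_quintile_points(values, rating: str) -> np.ndarray:
    """Score one food group's intakes into quintile points.

    A value's beneficial-direction category is the number of cut points it
    strictly exceeds, so ties at a cut point fall in the lower category and
    coincident cut points (mass points such as non-consumers) collapse
    categories downward: zero intake of a beneficial group always scores 0,
    of an adverse group always 4.  Adverse ratings return ``4 - category``.

    Missing values yield missing points.
    """
    if rating == RATING_NEUTRAL:
        raise ValueError("neutral groups are scored 0 by convention, not ranked")
    if rating not in (RATING_BENEFICIAL, RATING_ADVERSE):
        raise ValueError(f"unknown rating {rating!r}")
    values = np.asarray(values, dtype=float)
    if np.all(np.isnan(values)):
        raise ValueError("all intake values missing; quintiles undefined")
    cuts = quintile_cut_points(values)
    points = (values[:, None] > cuts[None, :]).sum(axis=1).astype(float)
    points[np.isnan(values)] = np.nan
    if rating == RATING_ADVERSE:
        points = 4.0 - points
    return points


def compute_apdqs(intakes: pd.DataFrame, catalog: FoodGroupCatalog) -> pd.DataFrame:
    """Compute APDQS and per-group points for one exam's intake matrix.

    Parameters
    ----------
    intakes
        One row per participant, one column per ``group_id`` in the catalog
        (servings/day); the index identifies participants.  Missing intake
        must be encoded as NaN, never as 0.
    catalog
        Rating catalog; every catalog group must be present as a column.

    Returns
    -------
    DataFrame indexed like ``intakes`` with one ``points_<group_id>``
    column per rated group and an ``apdqs`` column equal to their sum.
    A participant missing any rated group's intake has missing APDQS
    (no imputation).
    """
    missing_cols = [g for g in catalog.group_ids if g not in intakes.columns]
    if missing_cols:
        raise KeyError(f"intake table missing food-group columns: {missing_cols}")
    if len(intakes) < 5:
        raise ValueError(
            f"need at least 5 participants to form quintiles, got {len(intakes)}"
        )
    neg = intakes[catalog.group_ids].lt(0).any()
    if neg.any():
        bad = list(neg.index[neg])
        raise ValueError(f"negative servings/day in groups: {bad}")

    points = {}
    for gid in catalog.rated_groups:
        points[f"points_{gid}"] = assign_quintile_points(
            intakes[gid].to_numpy(), catalog.rating_of(gid)
        )
    out = pd.DataFrame(points, index=intakes.index)
    out["apdqs"] = out.sum(axis=1, skipna=False)
    n_missing = int(out["apdqs"].isna().sum())
    if n_missing:
        logger.info("APDQS missing for %d participants (incomplete intakes)", n_missing)
    return out


def compute_keys_score(
    pct_energy_sfa, pct_energy_pufa, dietary_cholesterol_mg_per_1000kcal
):
    """Keys dietary lipid score.

    ``1.35 * (2 * P_sf - P_pufa) + 1.5 * sqrt(C)`` with C the numeric value
    of cholesterol density in mg/1000 kcal.  Inputs may be scalars or
    aligned arrays/Series; missing inputs give missing scores.
    """
    p_sf = np.asarray(pct_energy_sfa, dtype=float)
    p_pufa = np.asarray(pct_energy_pufa, dtype=float)
    c = np.asarray(dietary_cholesterol_mg_per_1000kcal, dtype=float)
    if np.any(c[~np.isnan(c)] < 0):
        raise ValueError("dietary cholesterol density must be >= 0")
    score = 1.35 * (2.0 * p_sf - p_pufa) + 1.5 * np.sqrt(c)
    n_missing = int(np.sum(np.isnan(score)))
    if n_missing and score.ndim:
        logger.info("Keys Score missing for %d records (missing inputs)", n_missing)
    if score.ndim == 0:
        return float(score)
    if isinstance(pct_energy_sfa, pd.Series):
        return pd.Series(score, index=pct_energy_sfa.index, name="keys_score")
    return score


def macronutrient_percent_energy(
    fat_g=0.0, carbohydrate_g=0.0, protein_g=0.0, alcohol_g=0.0, energy_kcal_d=None
) -> dict:
    """Convert macronutrient grams/day to percent of total energy.

    Uses 9 kcal/g fat, 4 carbohydrate, 4 protein, 7 alcohol.
    """
    if energy_kcal_d is None:
        raise ValueError("energy_kcal_d is required")
    energy = np.asarray(energy_kcal_d, dtype=float)
    if np.any(energy <= 0):
        raise ValueError("energy_kcal_d must be > 0")
    grams = {
        "fat": np.asarray(fat_g, dtype=float),
        "carbohydrate": np.asarray(carbohydrate_g, dtype=float),
        "protein": np.asarray(protein_g, dtype=float),
        "alcohol": np.asarray(alcohol_g, dtype=float),
    }
    for k, v in grams.items():
        if np.any(v < 0):
            raise ValueError(f"{k} grams must be >= 0")
    out = {}
    for k, v in grams.items():
        pct = 100.0 * KCAL_PER_GRAM[k] * v / energy
        out[f"pct_energy_{k}"] = float(pct) if pct.ndim == 0 else pct
    return out
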