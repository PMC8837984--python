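"""Descriptive and contrast tables.

``quintile_summary`` reproduces the baseline-characteristics layout:
mean +/- SD (one-way ANOVA across quintiles) for continuous variables
and count (%) (chi-square) for categorical ones.  ``difference_of_
differences`` reproduces the food-group contrast table: mean servings/day
in the extreme quintiles of each diet score, the within-score extreme-
quintile differences, and their difference of differences
(APDQS Q5 - Q1) - (Keys Q1 - Q5), with rating subtotals and a grand
total.  Internally nothing is rounded; rounding to 2 decimals is applied
only for display.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import FoodGroupCatalog, reference_extreme_quintile_means
from .exposures import quintile_categorize


def quintile_summary(
    data: pd.DataFrame,
    exposure: str,
    continuous=(),
    categorical=(),
) -> pd.DataFrame:
    """Characteristics by exposure quintile with across-quintile tests.

    Returns one row per characteristic with per-quintile ``mean (sd)`` or
    ``count (%)`` strings, the underlying numbers, and the ANOVA or
    chi-square p-value.
    """
    labels, _ = quintile_categorize(data[exposure])
    labels = pd.Series(labels, index=data.index)
    qlabels = [f"Q{i}" for i in range(1, 6)]
    counts = labels.value_counts()
    empty = [q for q in qlabels if counts.get(q, 0) == 0]
    if empty:
        raise ValueError(f"empty exposure quintiles: {empty}")

    rows = []
    rows.append(
        {
            "characteristic": "n",
            **{q: float(counts[q]) for q in qlabels},
            "p": np.nan,
            "kind": "count",
        }
    )
    for var in continuous:
        groups = [data.loc[labels == q, var].dropna() for q in qlabels]
        f, p = stats.f_oneway(*groups)
        row = {"characteristic": var, "kind": "continuous", "p": float(p)}
        for q, g in zip(qlabels, groups):
            row[q] = float(g.mean())
            row[f"{q}_sd"] = float(g.std())
        rows.append(row)
    for var in categorical:
        tab = pd.crosstab(labels, data[var])
        chi2, p, _, _ = stats.chi2_contingency(tab)
        row = {"characteristic": var, "kind": "categorical", "p": float(p)}
        for q in qlabels:
            sub = data.loc[labels == q, var]
            n_pos = float((sub == 1).sum() if sub.dtype != object else sub.notna().sum())
            row[q] = n_pos
            row[f"{q}_pct"] = 100.0 * n_pos / len(sub)
        rows.append(row)
    return pd.DataFrame(rows)


def extreme_quintile_means(
    intakes: pd.DataFrame,
    score_values: pd.Series,
    catalog: FoodGroupCatalog,
) -> pd.DataFrame:
    """Mean servings/day per food group in the lowest and highest score
    quintile of a cohort (one intake row per participant)."""
    labels, _ = quintile_categorize(score_values.reindex(intakes.index))
    labels = pd.Series(labels, index=intakes.index)
    out = pd.DataFrame(
        {
            "group_id": catalog.group_ids,
            "rating": [catalog.rating_of(g) for g in catalog.group_ids],
            "q1": [intakes.loc[labels == "Q1", g].mean() for g in catalog.group_ids],
            "q5": [intakes.loc[labels == "Q5", g].mean() for g in catalog.group_ids],
        }
    )
    return out


def difference_of_differences(
    table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Food-group contrast table with rating subtotals and grand total.

    ``table`` needs columns ``group_id, rating, apdqs_q1, apdqs_q5,
    keys_q1, keys_q5`` (mean servings/day); by default the bundled
    reference table is used.  Adds:

    * ``apdqs_diff`` = APDQS Q5 - Q1 (high minus low diet quality),
    * ``keys_diff``  = Keys Q1 - Q5 (low minus high score: both
      differences point toward the "healthier" end of each score),
    * ``dod``        = apdqs_diff - keys_diff,

    plus one subtotal row per rating (column sums of its groups) and a
    grand-total row.  A positive difference of differences for a
    beneficial group (negative for an adverse group) favors the
    plant-centered score as the sharper discriminator of that food.
    """
    df = (table if table is not None else reference_extreme_quintile_means()).copy()
    required = {"group_id", "rating", "apdqs_q1", "apdqs_q5", "keys_q1", "keys_q5"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"contrast input missing columns: {sorted(missing)}")
    if df[["apdqs_q1", "apdqs_q5", "keys_q1", "keys_q5"]].isna().any().any():
        bad = df.loc[
            df[["apdqs_q1", "apdqs_q5", "keys_q1", "keys_q5"]].isna().any(axis=1),
            "group_id",
        ].tolist()
        raise ValueError(f"missing quintile means for groups: {bad}")
    df["apdqs_diff"] = df["apdqs_q5"] - df["apdqs_q1"]
    df["keys_diff"] = df["keys_q1"] - df["keys_q5"]
    df["dod"] = df["apdqs_diff"] - df["keys_diff"]

    num = ["apdqs_q1", "apdqs_q5", "apdqs_diff", "keys_q1", "keys_q5", "keys_diff", "dod"]
    blocks = []
    for rating in ("beneficial", "neutral", "adverse"):
        sub = df[df["rating"] == rating]
        if sub.empty:
            continue
        blocks.append(sub)
        total = sub[num].sum()
        blocks.append(
            pd.DataFrame(
                [{"group_id": f"subtotal_{rating}", "rating": rating, **total}]
            )
        )
    grand = df[num].sum()
    blocks.append(pd.DataFrame([{"group_id": "grand_total", "rating": "all", **grand}]))
    return pd.concat(blocks, ignore_index=True)


def render_contrast_table(dod: pd.DataFrame) -> str:
    """Aligned plain-text rendering (2-decimal display rounding)."""
    cols = ["group_id", "apdqs_q1", "apdqs_q5", "apdqs_diff", "keys_q1", "keys_q5", "keys_diff", "dod"]
    widths = {c: max(len(c), 12) for c in cols}
    header = "  ".join(c.ljust(widths[c]) for c in cols)
    lines = [header, "-" * len(header)]
    for _, r in dod.iterrows():
        cells = [str(r["group_id"]).ljust(widths["group_id"])]
        cells += [f"{r[c]:.2f}".rjust(widths[c]) for c in cols[1:]]
        lines.append("  ".join(cells))
    return "\n".join(lines)
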