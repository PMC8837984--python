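"""Time-varying cumulative-average exposures and the counting-process table.

The analysis uses each exposure's cumulative average over the exams
observed so far: the baseline (Y0) value predicts events on follow-up
years (0, 7], the mean of the available {Y0, Y7} values predicts (7, 20],
and the mean of the available {Y0, Y7, Y20} values predicts (20, 32].
When all post-baseline exams are missing, the Y0 value applies throughout.
Survival data are encoded as counting-process rows (start, stop] with the
interval-specific exposure and covariate values, split at years 7 and 20
and truncated at the event/censoring time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import INTERVAL_BOUNDARIES, REFERENCE_MOMENTS


def cumulative_average_exposure(
    values: pd.DataFrame,
    exam_years=(0, 7, 20),
    boundaries=INTERVAL_BOUNDARIES,
) -> pd.DataFrame:
    """Build per-interval exposure values from per-exam values.

    Parameters
    ----------
    values
        One row per participant (index = participant id), one column per
        exam year (missing exam values as NaN).  The baseline column must
        be non-missing for every participant.
    exam_years
        Exam times (years from baseline) matching the columns of
        ``values``; arbitrary schedules (e.g. interim lipid exams) are
        accepted.
    boundaries
        Follow-up interval boundaries; interval k covers
        (boundaries[k], boundaries[k+1]] and uses the mean of the
        non-missing exam values at years <= boundaries[k] (baseline
        interval: the Y0 value).

    Returns
    -------
    DataFrame indexed like ``values`` with one column per interval,
    named by the interval start year.
    """
    exam_years = [float(t) for t in exam_years]
    if sorted(exam_years) != exam_years:
        raise ValueError("exam_years must be increasing")
    mat = values.to_numpy(dtype=float)
    if mat.shape[1] != len(exam_years):
        raise ValueError("values must have one column per exam year")
    if np.isnan(mat[:, 0]).any():
        bad = values.index[np.isnan(mat[:, 0])][:5].tolist()
        raise ValueError(f"baseline exam value missing for participants {bad}")
    starts = list(boundaries[:-1])
    out = {}
    for s in starts:
        use = [k for k, t in enumerate(exam_years) if t <= max(s, exam_years[0])]
        sub = mat[:, use]
        with np.errstate(invalid="ignore"):
            avg = np.nanmean(sub, axis=1)
        out[s] = avg
    return pd.DataFrame(out, index=values.index)


def exam_matrix(
    long: pd.DataFrame, value_col: str, exam_years=(0, 7, 20)
) -> pd.DataFrame:
    """Pivot a long participant/exam table into participants x exam years."""
    wide = long.pivot_table(
        index="participant_id", columns="exam", values=value_col, aggfunc="first"
    )
    return wide.reindex(columns=[float(t) for t in exam_years])


def build_counting_process(
    schedules: dict[str, pd.DataFrame],
    events: pd.DataFrame,
    outcome: str,
    boundaries=INTERVAL_BOUNDARIES,
    baseline: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Encode follow-up as (start, stop] risk intervals with exposures.

    Parameters
    ----------
    schedules
        Mapping column name -> per-interval exposure frame as returned by
        :func:`cumulative_average_exposure` (index = participant id).
    events
        One row per participant with columns ``participant_id``,
        ``{outcome}_time`` and ``{outcome}_event`` (time = first event,
        death or administrative censoring, whichever came first).
    outcome
        Outcome label, e.g. ``"chd"`` or ``"stroke"``.
    baseline
        Optional frame of time-fixed covariates (indexed by or containing
        ``participant_id``) merged onto every row.

    Returns
    -------
    Long DataFrame with columns participant_id, start, stop, event and one
    column per schedule entry; the event flag is 1 only on a participant's
    final row and only if the outcome occurred.
    """
    tcol, ecol = f"{outcome}_time", f"{outcome}_event"
    for c in ("participant_id", tcol, ecol):
        if c not in events.columns:
            raise KeyError(f"events table missing column {c!r}")
    t = events[tcol].to_numpy(dtype=float)
    if np.any(t <= 0) or np.any(t > boundaries[-1]):
        raise ValueError(
            f"event/censor times must lie in (0, {boundaries[-1]}]"
        )
    pid = events["participant_id"].to_numpy()
    ev = events[ecol].to_numpy(dtype=int)

    rows = []
    for k in range(len(boundaries) - 1):
        s, e = boundaries[k], boundaries[k + 1]
        in_seg = t > s
        stop = np.minimum(t, e)
        last = in_seg & (t <= e)
        seg = pd.DataFrame(
            {
                "participant_id": pid[in_seg],
                "start": s,
                "stop": stop[in_seg],
                "event": np.where(last[in_seg], ev[in_seg], 0),
            }
        )
        for name, sched in schedules.items():
            seg[name] = sched[boundaries[k]].reindex(seg["participant_id"]).to_numpy()
        rows.append(seg)
    table = pd.concat(rows, ignore_index=True)
    if baseline is not None:
        bl = baseline.reset_index() if baseline.index.name == "participant_id" else baseline
        table = table.merge(bl, on="participant_id", how="left")
    return table.sort_values(["participant_id", "start"], ignore_index=True)


def per_sd(values, variable: str | None = None, sd: float | None = None):
    """Scale an exposure to reference-SD units.

    Either pass ``sd`` directly (its absolute value is used; the Keys
    Score convention reports effects per 11-point *decrease*, i.e. a
    negative nominal SD) or name a ``variable`` with a registered
    reference SD (apdqs 13, keys_score 11, ldl_c 0.80, non_hdl_c 0.87 ...).
    """
    if sd is None:
        if variable is None or variable not in REFERENCE_MOMENTS:
            raise ValueError(f"no reference SD registered for {variable!r}")
        sd = REFERENCE_MOMENTS[variable][1]
    if sd == 0:
        raise ValueError("SD must be nonzero")
    out = np.asarray(values, dtype=float) / abs(sd)
    return float(out) if out.ndim == 0 else out


def quintile_categorize(values, labels_prefix: str = "Q"):
    """Quintile labels (Q1..Q5) and cut points for an exposure vector.

    Cut points are the 20/40/60/80th percentiles of the non-missing
    values; ties at a cut point fall in the lower quintile.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[~np.isnan(arr)]
    if np.unique(finite).size < 5:
        raise ValueError("need >= 5 distinct values to form quintiles")
    cuts = np.percentile(finite, [20, 40, 60, 80])
    cat = (arr[:, None] > cuts[None, :]).sum(axis=1).astype(float)
    cat[np.isnan(arr)] = np.nan
    labels = np.array(
        [None if np.isnan(c) else f"{labels_prefix}{int(c) + 1}" for c in cat],
        dtype=object,
    )
    if isinstance(values, pd.Series):
        labels = pd.Series(labels, index=values.index, name="quintile")
    return labels, cuts


def person_time(table: pd.DataFrame) -> float:
    """Total person-years represented by a counting-process table."""
    return float((table["stop"] - table["start"]).sum())
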