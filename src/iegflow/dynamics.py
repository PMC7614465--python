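"""Expression and activity dynamics across learning conditions.

Timecourses of mean activity / mean normalized expression per mouse and
session, condition-boundary change statistics, linear trends, and
rank-order expression-pattern similarity matrices.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coupling import _last_snapshot_per_session, summarize_activity
from .errors import AnalysisError
from .imaging import normalize_ieg
from .stats import regression_f_test, t_test_paired
from .types import MouseDataset


def build_timecourse(
    datasets: Sequence[MouseDataset],
    quantity: str = "ieg",
    smooth_tau_s: Optional[float] = 0.2,
) -> pd.DataFrame:
    """Tidy per-mouse per-session timecourse.

    ``quantity='activity'``: mean dF/F over all segments of the session,
    averaged over neurons.  ``quantity='ieg'``: mean normalized
    expression at the session's last snapshot.  Columns: mouse,
    session_index, timepoint_h, condition, value.
    """
    if quantity not in ("activity", "ieg"):
        raise AnalysisError(f"quantity must be 'activity' or 'ieg', got {quantity!r}")
    rows = []
    for ds in datasets:
        cond = ds.schedule.condition_ids
        times = ds.schedule.session_times_h
        if quantity == "activity":
            act = summarize_activity(ds, mode="mean", smooth_tau_s=smooth_tau_s)
            per_session = np.nanmean(act.values, axis=0)
            sessions = ds.session_indices
        else:
            ieg = _last_snapshot_per_session(normalize_ieg(ds.ieg_raw))
            per_session = ieg.values.mean(axis=0)
            sessions = list(ieg.session_index) if ieg.session_index is not None \
                else list(range(ieg.n_timepoints))
        for j, s in enumerate(sessions):
            rows.append(
                {
                    "mouse": ds.mouse_id,
                    "session_index": int(s),
                    "timepoint_h": float(times[int(s)]),
                    "condition": int(cond[int(s)]),
                    "value": float(per_session[j]),
                }
            )
    return pd.DataFrame(rows)


def condition_change(tc: pd.DataFrame, boundary=(2, 3)) -> dict:
    """Expression/activity change across a condition boundary.

    Per mouse: mean of the first two sessions of the following condition
    minus mean of the last two sessions of the previous condition.
    Returns per-mouse changes, mean +/- SEM, and the paired t-test
    across mice on the two window means (omitted for < 2 mice).
    """
    prev_c, next_c = boundary
    changes, before, after = [], [], []
    for mouse, g in tc.groupby("mouse"):
        g = g.sort_values("session_index")
        prev = g[g["condition"] == prev_c]["value"].to_numpy()
        nxt = g[g["condition"] == next_c]["value"].to_numpy()
        if prev.size < 2 or nxt.size < 2:
            raise AnalysisError(
                f"mouse {mouse!r}: need >= 2 sessions on each side of the "
                f"{prev_c}->{next_c} boundary"
            )
        b = float(prev[-2:].mean())
        a = float(nxt[:2].mean())
        before.append(b)
        after.append(a)
        changes.append(a - b)
    changes = np.array(changes)
    out = {
        "change": changes,
        "mean": float(changes.mean()),
        "sem": float(changes.std(ddof=1) / np.sqrt(changes.size))
        if changes.size > 1 else np.nan,
        "test": None,
    }
    if changes.size >= 2:
        out["test"] = t_test_paired(np.array(after), np.array(before))
    return out


def linear_trend(tc: pd.DataFrame, condition_ids=(2, 3)) -> dict:
    """Linear trend of the timecourse over the selected conditions.

    OLS of value on timepoint, treating each mouse-timepoint observation
    as independent; reports slope, R^2 and the overall F-test p.  The
    plotted fit line is the average of per-mouse first-degree fits.
    """
    sel = tc[tc["condition"].isin(condition_ids)]
    if sel["timepoint_h"].nunique() < 3:
        raise AnalysisError("linear trend needs >= 3 timepoints")
    res = regression_f_test(sel["timepoint_h"].to_numpy(),
                            sel["value"].to_numpy())
    slopes, intercepts = [], []
    for _, g in sel.groupby("mouse"):
        if g["timepoint_h"].nunique() >= 2:
            p = np.polyfit(g["timepoint_h"], g["value"], 1)
            slopes.append(p[0])
            intercepts.append(p[1])
    res["fit_line"] = {
        "slope": float(np.mean(slopes)) if slopes else np.nan,
        "intercept": float(np.mean(intercepts)) if intercepts else np.nan,
    }
    return res


def pattern_similarity(
    datasets: Sequence[MouseDataset],
    method: str = "spearman",
) -> np.ndarray:
    """Rank-order expression-pattern similarity across timepoints.

    Per mouse, the Spearman (or Kendall) correlation across neurons
    between normalized expression vectors of every timepoint pair;
    matrices are averaged over mice.  Timepoints with a constant
    expression vector are marked missing (NaN row/column, unit
    diagonal).
    """
    if method not in ("spearman", "kendall"):
        raise AnalysisError("method must be 'spearman' or 'kendall'")
    mats = []
    n_tp = None
    for ds in datasets:
        ieg = _last_snapshot_per_session(normalize_ieg(ds.ieg_raw))
        v = ieg.values
        if v.shape[0] < 3 or v.shape[1] < 2:
            raise AnalysisError("pattern similarity needs >=3 neurons and "
                                ">=2 timepoints")
        if n_tp is None:
            n_tp = v.shape[1]
        m = np.full((n_tp, n_tp), np.nan)
        constant = v.std(axis=0) == 0
        for i in range(n_tp):
            m[i, i] = 1.0
            for j in range(i + 1, n_tp):
                if constant[i] or constant[j]:
                    continue
                if method == "spearman":
                    r = sps.spearmanr(v[:, i], v[:, j]).statistic
                else:
                    r = sps.kendalltau(v[:, i], v[:, j]).statistic
                m[i, j] = m[j, i] = r
        mats.append(m)
    with np.errstate(invalid="ignore"):
        return np.nanmean(np.stack(mats), axis=0)
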