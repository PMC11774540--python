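"""Weber fractions, attentional cost and the grouped-ungrouped cost delta.

The pipeline, in analysis order:

1. :func:`filter_outliers` — drop trials whose response deviates more than
   k SDs from its cell mean (cell = participant x task x arrangement x
   numerosity) or whose log response time deviates more than k SDs from
   its participant x task mean (single pass, two-sided, k = 3).
2. :func:`cell_statistics` — per-cell mean response, sample SD, count.
3. :func:`weber_fractions` — Wf = SD / N per cell (scalar variability
   makes this a numerosity-free precision index).
4. :func:`summary_wf` — unweighted mean Wf over a numerosity range
   (5-8 by default, the range showing the grouping advantage) per
   participant x task x arrangement.
5. :func:`attentional_cost` — AC = (Wf_DT - Wf_ST) / (Wf_ST + Wf_DT) x 100,
   the sum-normalized percent precision loss under a concurrent task.
6. :func:`delta_ac` — dAC = AC_grouped - AC_ungrouped, positive when the
   concurrent task hurts grouped arrays more.

The single-task reference for grouped attentional cost is the grouped
single task *with ignored distractors* (matching the visual stimulation of
the dual tasks); for ungrouped stimuli it is the plain single task, since
no ungrouped-with-distractors condition exists.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .observer import DUAL_TASKS

__all__ = [
    "filter_outliers",
    "cell_statistics",
    "weber_fraction",
    "weber_fractions",
    "summary_wf",
    "attentional_cost",
    "attentional_cost_table",
    "delta_ac",
    "delta_ac_table",
    "perceived_numerosity_table",
]

CELL_KEYS = ["participant", "task", "arrangement", "numerosity"]

# Single-task reference condition per arrangement (task, arrangement):
ST_REFERENCE = {
    "grouped": ("single_distractor", "grouped"),
    "ungrouped": ("single", "ungrouped"),
}


def _outlier_mask(trials: pd.DataFrame, k: float) -> pd.Series:
    grp = trials.groupby(CELL_KEYS)["response"]
    mu = grp.transform("mean")
    sd = grp.transform("std")
    resp_out = (sd > 0) & ((trials["response"] - mu).abs() > k * sd)

    logrt = np.log(trials["rt_ms"].astype(float))
    grp_rt = logrt.groupby([trials["participant"], trials["task"]])
    mu_rt = grp_rt.transform("mean")
    sd_rt = grp_rt.transform("std")
    rt_out = (sd_rt > 0) & ((logrt - mu_rt).abs() > k * sd_rt)
    return (resp_out | rt_out).fillna(False)


def filter_outliers(trials: pd.DataFrame, k: float = 3.0, max_sweeps: int = 10
                    ) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Remove response and response-time outliers (two-sided k-SD rule).

    Responses are judged within participant x task x arrangement x
    numerosity cells; response times (log scale) within participant x task,
    pooled over numerosities since RT does not scale with N the way
    responses do. The sweep is repeated until no trial exceeds the
    criterion, so the filter is a fixed point of itself (in practice the
    first sweep does essentially all the work and convergence takes one or
    two extra sweeps removing a handful of trials). Returns
    ``(kept, removed, removed_fraction)``.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    if trials.empty:
        raise ValueError("trials table is empty")

    kept = trials
    removed_parts = []
    for _ in range(max_sweeps):
        bad = _outlier_mask(kept, k)
        if not bad.any():
            break
        removed_parts.append(kept[bad])
        kept = kept[~bad]
    removed = (pd.concat(removed_parts).sort_index() if removed_parts
               else trials.iloc[0:0])
    return kept, removed, len(removed) / len(trials)


def cell_statistics(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean response, sample SD (n-1) and trial count per cell.

    Cells with fewer than two trials have no defined SD; they are dropped
    with a warning.
    """
    cells = (trials.groupby(CELL_KEYS)["response"]
             .agg(mean_response="mean", sd="std", n_trials="count")
             .reset_index())
    thin = cells["n_trials"] < 2
    if thin.any():
        warnings.warn(
            f"excluded {int(thin.sum())} cell(s) with < 2 trials (SD undefined)",
            stacklevel=2)
        cells = cells[~thin].reset_index(drop=True)
    return cells


def weber_fraction(sd, numerosity):
    """Wf = SD / N (vectorized)."""
    return np.asarray(sd, dtype=float) / np.asarray(numerosity, dtype=float)


def weber_fractions(cells: pd.DataFrame) -> pd.DataFrame:
    """Append the per-cell Weber fraction ``wf`` to a cell-statistics table."""
    out = cells.copy()
    out["wf"] = weber_fraction(out["sd"], out["numerosity"])
    return out


def summary_wf(wfs: pd.DataFrame,
               numerosity_range: tuple[int, int] = (5, 8)) -> pd.DataFrame:
    """Unweighted mean Wf over a numerosity range, per participant x
    task x arrangement."""
    lo, hi = numerosity_range
    if lo > hi:
        raise ValueError(f"empty numerosity range {numerosity_range}")
    sub = wfs[(wfs["numerosity"] >= lo) & (wfs["numerosity"] <= hi)]
    if sub.empty:
        raise ValueError(f"no Weber fractions in numerosity range {numerosity_range}")
    return (sub.groupby(["participant", "task", "arrangement"])["wf"]
            .mean().reset_index())


def attentional_cost(wf_st, wf_dt):
    """AC = (Wf_DT - Wf_ST) / (Wf_ST + Wf_DT) x 100 (percent).

    Antisymmetric under swapping the two Wfs; zero iff they are equal.
    """
    wf_st = np.asarray(wf_st, dtype=float)
    wf_dt = np.asarray(wf_dt, dtype=float)
    total = wf_st + wf_dt
    if np.any(total <= 0):
        raise ValueError("attentional cost undefined when Wf_ST + Wf_DT <= 0")
    out = (wf_dt - wf_st) / total * 100.0
    return float(out) if out.ndim == 0 else out


def attentional_cost_table(summary: pd.DataFrame,
                           dual_tasks: tuple[str, ...] = DUAL_TASKS) -> pd.DataFrame:
    """Per-participant attentional cost for every dual task x arrangement.

    The single-task reference follows :data:`ST_REFERENCE` (grouped with
    ignored distractors for grouped arrays, plain single task for
    ungrouped arrays).
    """
    idx = summary.set_index(["participant", "task", "arrangement"])["wf"]
    rows = []
    for (participant, task, arrangement), wf_dt in idx.items():
        if task not in dual_tasks:
            continue
        ref_task, ref_arr = ST_REFERENCE[arrangement]
        try:
            wf_st = idx[(participant, ref_task, ref_arr)]
        except KeyError:
            raise ValueError(
                f"missing single-task reference ({ref_task}, {ref_arr}) "
                f"for participant {participant}") from None
        rows.append({"participant": participant, "dual_task": task,
                     "arrangement": arrangement, "wf_st": wf_st, "wf_dt": wf_dt,
                     "ac": attentional_cost(wf_st, wf_dt)})
    out = pd.DataFrame(rows)
    return out.sort_values(["participant", "dual_task", "arrangement"]).reset_index(drop=True)


def delta_ac(ac_g, ac_u):
    """dAC = AC_grouped - AC_ungrouped (percent)."""
    out = np.asarray(ac_g, dtype=float) - np.asarray(ac_u, dtype=float)
    return float(out) if out.ndim == 0 else out


def delta_ac_table(ac_table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant dAC for each dual task from an attentional-cost table."""
    wide = ac_table.pivot_table(index=["participant", "dual_task"],
                                columns="arrangement", values="ac")
    missing = wide[wide.isna().any(axis=1)]
    if not missing.empty:
        raise ValueError(f"incomplete AC pairs for {list(missing.index)}")
    out = wide.reset_index().rename(
        columns={"grouped": "ac_grouped", "ungrouped": "ac_ungrouped"})
    out.columns.name = None
    out["delta_ac"] = delta_ac(out["ac_grouped"], out["ac_ungrouped"])
    return out


def perceived_numerosity_table(cells: pd.DataFrame,
                               numerosity_range: tuple[int, int] = (5, 8),
                               per_participant: bool = False) -> pd.DataFrame:
    """Mean perceived numerosity per task x arrangement.

    The cell mean responses are first averaged over the numerosity range
    within each participant, then across participants (the returned ``std``
    is the between-participant SD). With ``per_participant=True`` the
    participant-level means are returned instead.
    """
    lo, hi = numerosity_range
    if lo > hi:
        raise ValueError(f"empty numerosity range {numerosity_range}")
    sub = cells[(cells["numerosity"] >= lo) & (cells["numerosity"] <= hi)]
    per = (sub.groupby(["participant", "task", "arrangement"])["mean_response"]
           .mean().reset_index(name="perceived"))
    if per_participant:
        return per
    return (per.groupby(["task", "arrangement"])["perceived"]
            .agg(mean="mean", std="std").reset_index())
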