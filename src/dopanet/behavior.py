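"""Behavioural performance metrics for the n-back task.

* pRT — proportional penalized reaction time: within each subject x load
  cell, every incorrect or omitted trial contributes `ratio` times the mean
  RT of the *correct* trials of that cell, correct trials contribute their
  own RT, and pRT is the mean over all trials.
* -dpRT ("robustness") — the negated OLS slope of pRT on load (0/1/2);
  zero means performance is unaffected by load, negative values mean
  performance degrades as the load rises.
* d' — Z(hit rate) - Z(false-alarm rate), with perfect scores adjusted to
  1 - 1/(2n) and zero rates to 1/(2n), n being the whole-task count of
  targets (hits) or non-targets (false alarms) by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

LOADS = (0, 1, 2)

__all__ = [
    "BehaviorError", "is_correct", "penalized_rt", "performance_slope",
    "dprime", "dprime_slope", "behavioural_summary",
]


class BehaviorError(ValueError):
    pass


def _validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    required = {"subject_id", "block", "load", "target", "response", "rt"}
    missing = required - set(trials.columns)
    if missing:
        raise BehaviorError(f"trial table lacks columns: {sorted(missing)}")
    trials = trials.reset_index(drop=True)   # guard against duplicate labels
    bad_load = ~trials["load"].isin(LOADS)
    if bad_load.any():
        raise BehaviorError("trial loads must be 0, 1 or 2")
    omitted = trials["response"] == "omitted"
    if trials.loc[~omitted, "rt"].isna().any():
        raise BehaviorError("non-omitted trials must carry an RT")
    rts = trials.loc[~omitted, "rt"]
    if ((rts <= 0) | (rts > 2.0)).any():
        raise BehaviorError("RTs must lie in (0, 2] seconds")
    return trials


def is_correct(trials: pd.DataFrame) -> pd.Series:
    """A trial is correct iff the response matches target presence and is
    not omitted; wrong-key responses and omissions are equally incorrect."""
    expected = np.where(trials["target"].astype(bool), "target", "non-target")
    return (trials["response"] == expected) & (trials["response"] != "omitted")


def penalized_rt(trials: pd.DataFrame, ratio: float = 2.5) -> pd.DataFrame:
    """Per-(subject, load) pRT.

    Returns columns subject_id, load, prt, baseline_rt, n_trials, n_correct.
    A cell without a single correct trial has no baseline and raises.
    """
    if ratio < 1:
        raise BehaviorError("penalization ratio must be >= 1")
    trials = _validate_trials(trials)
    correct = is_correct(trials)
    rows = []
    bad_cells = []
    for (subj, load), cell in trials.groupby(["subject_id", "load"],
                                             sort=True):
        ok = correct.loc[cell.index]
        if not ok.any():
            bad_cells.append((subj, load))
            continue
        baseline = cell.loc[ok, "rt"].mean()
        contrib = np.where(ok, cell["rt"].fillna(0.0), ratio * baseline)
        rows.append({
            "subject_id": subj, "load": load,
            "prt": float(contrib.mean()),
            "baseline_rt": float(baseline),
            "n_trials": int(len(cell)), "n_correct": int(ok.sum()),
        })
    if bad_cells:
        raise BehaviorError(
            f"no correct trials in subject x load cell(s): {bad_cells}")
    return pd.DataFrame(rows)


def performance_slope(prt: pd.DataFrame,
                      value_col: str = "prt") -> pd.DataFrame:
    """OLS slope of pRT on load per subject; robustness is its negation.

    Requires exactly the loads 0, 1, 2 per subject. Returns columns
    subject_id, delta_prt, robustness (= -delta_prt).
    """
    rows = []
    for subj, grp in prt.groupby("subject_id", sort=True):
        if sorted(grp["load"]) != list(LOADS):
            raise BehaviorError(
                f"subject {subj}: need exactly loads 0,1,2, "
                f"got {sorted(grp['load'])}")
        grp = grp.sort_values("load")
        y = grp[value_col].to_numpy(dtype=float)
        slope = float((y[2] - y[0]) / 2.0)   # OLS on x = 0,1,2
        rows.append({"subject_id": subj, "delta_prt": slope,
                     "robustness": -slope})
    return pd.DataFrame(rows)


def dprime(trials: pd.DataFrame, scope: str = "task") -> pd.DataFrame:
    """Per-(subject, load) discriminability d' = Z(hit) - Z(fa).

    `scope` controls the n in the 1/(2n) extreme-score adjustment:
    "task" (default) uses the whole-task count of targets/non-targets,
    "load" the per-load count.
    """
    if scope not in ("task", "load"):
        raise BehaviorError("scope must be 'task' or 'load'")
    trials = _validate_trials(trials)
    said_target = trials["response"] == "target"
    target = trials["target"].astype(bool)
    rows = []
    for subj, subj_trials in trials.groupby("subject_id", sort=True):
        n_targets_task = int(target.loc[subj_trials.index].sum())
        n_nontargets_task = int((~target.loc[subj_trials.index]).sum())
        if n_targets_task == 0 or n_nontargets_task == 0:
            raise BehaviorError(
                f"subject {subj}: needs both targets and non-targets")
        for load, cell in subj_trials.groupby("load", sort=True):
            tgt = target.loc[cell.index]
            st = said_target.loc[cell.index]
            n_t, n_nt = int(tgt.sum()), int((~tgt).sum())
            if n_t == 0 or n_nt == 0:
                raise BehaviorError(
                    f"subject {subj} load {load}: needs both targets "
                    f"and non-targets")
            hit = float((st & tgt).sum() / n_t)
            fa = float((st & ~tgt).sum() / n_nt)
            n_hit = n_targets_task if scope == "task" else n_t
            n_fa = n_nontargets_task if scope == "task" else n_nt
            if hit >= 1.0:
                hit = 1.0 - 1.0 / (2 * n_hit)
            if fa <= 0.0:
                fa = 1.0 / (2 * n_fa)
            # symmetric guard for the opposite extremes
            if hit <= 0.0:
                hit = 1.0 / (2 * n_hit)
            if fa >= 1.0:
                fa = 1.0 - 1.0 / (2 * n_fa)
            rows.append({
                "subject_id": subj, "load": load,
                "hit_rate": hit, "fa_rate": fa,
                "n_targets": n_t, "n_nontargets": n_nt,
                "dprime": float(norm.ppf(hit) - norm.ppf(fa)),
            })
    return pd.DataFrame(rows)


def dprime_slope(dp: pd.DataFrame) -> pd.DataFrame:
    """OLS slope of d' on load per subject (columns subject_id, dprime_slope)."""
    out = performance_slope(dp, value_col="dprime")
    return out.rename(columns={"delta_prt": "dprime_slope"}) \
              .drop(columns="robustness")


def behavioural_summary(trials: pd.DataFrame,
                        ratios=(2.5, 3.0, 3.5, 4.0),
                        dprime_scope: str = "task") -> pd.DataFrame:
    """Tidy per-subject summary: robustness per ratio plus the d' slope."""
    pieces = []
    for ratio in ratios:
        prt = penalized_rt(trials, ratio)
        slope = performance_slope(prt)
        slope["ratio"] = ratio
        pieces.append(slope)
    robust = pd.concat(pieces, ignore_index=True)
    dp = dprime_slope(dprime(trials, scope=dprime_scope))
    return robust.merge(dp, on="subject_id", how="left")
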