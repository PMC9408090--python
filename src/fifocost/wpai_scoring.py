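"""WPAI-GH productivity-loss scoring under a 4-week recall.

The Work Productivity and Activity Impairment (General Health) instrument
yields three per-worker loss percentages:

* absenteeism  = missed / (missed + worked) x 100, from health-related work
  hours missed and actual hours worked;
* presenteeism = impairment rating (0-10) x 10;
* total loss   = absenteeism + (1 - absenteeism) x presenteeism, computed on
  the fraction scale and reported as a percentage.

Items recalled over 4 weeks are divided by 4 to align with the instrument's
native 7-day window before scoring. All computations are carried at full
precision; rounding happens only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ProductivityLoss:
    """Loss percentages for one worker, all in [0, 100]."""

    worker_id: object
    absenteeism_pct: float
    presenteeism_pct: float
    total_loss_pct: float
    hours_missed_wk: float
    hours_worked_wk: float


class UndefinedLossError(ValueError):
    """Raised when missed and worked hours are both zero (loss undefined)."""


def rescale_recall(hours_4w):
    """Convert hours over a 4-week recall to hours per 7-day week."""
    hours = np.asarray(hours_4w, dtype=float)
    if np.any(hours < 0):
        raise ValueError("recall hours must be non-negative")
    out = hours / 4.0
    return out if out.ndim else float(out)


def absenteeism(hours_missed_wk, hours_worked_wk):
    """Percent of scheduled hours missed: 100 * missed / (missed + worked)."""
    missed = np.asarray(hours_missed_wk, dtype=float)
    worked = np.asarray(hours_worked_wk, dtype=float)
    if np.any(missed < 0) or np.any(worked < 0):
        raise ValueError("hours must be non-negative")
    denom = missed + worked
    if np.any(denom == 0):
        raise UndefinedLossError(
            "absenteeism undefined: zero hours missed and worked")
    out = 100.0 * missed / denom
    return out if out.ndim else float(out)


def presenteeism(rating_0_10):
    """Percent impairment while at work: rating x 10."""
    rating = np.asarray(rating_0_10)
    if not np.issubdtype(rating.dtype, np.integer):
        as_float = np.asarray(rating, dtype=float)
        if np.any(as_float != np.round(as_float)):
            raise ValueError("impairment rating must be an integer 0-10")
        rating = as_float.astype(int)
    if np.any(rating < 0) or np.any(rating > 10):
        raise ValueError("impairment rating must lie in 0-10")
    out = rating * 10.0
    return out if out.ndim else float(out)


def total_loss(absenteeism_pct, presenteeism_pct):
    """Combined loss: a + (1 - a) * p on the fraction scale, as a percent."""
    a = np.asarray(absenteeism_pct, dtype=float) / 100.0
    p = np.asarray(presenteeism_pct, dtype=float) / 100.0
    if np.any((a < 0) | (a > 1)) or np.any((p < 0) | (p > 1)):
        raise ValueError("loss percentages must lie in [0, 100]")
    out = 100.0 * (a + (1.0 - a) * p)
    return out if out.ndim else float(out)


def score_cohort(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Score every worker's WPAI items and summarise the cohort.

    ``cohort`` needs columns ``wpai_hours_missed_4w``, ``wpai_hours_worked_4w``
    and ``wpai_impairment_0_10``. Workers whose missed and worked hours are
    both zero (not working in the recall window) are excluded with a logged
    reason.

    Returns ``(losses, summary, excluded)`` where ``losses`` has one row per
    included worker (absenteeism/presenteeism/total percentages and weekly
    hours) and ``summary`` holds the zero-inflation fractions and loss
    moments.
    """
    required = ("wpai_hours_missed_4w", "wpai_hours_worked_4w",
                "wpai_impairment_0_10")
    for col in required:
        if col not in cohort.columns:
            raise ValueError(f"cohort is missing WPAI column {col!r}")
    complete = cohort[list(required)].notna().all(axis=1)
    df = cohort.loc[complete]
    missed_4w = df["wpai_hours_missed_4w"].to_numpy(dtype=float)
    worked_4w = df["wpai_hours_worked_4w"].to_numpy(dtype=float)
    defined = (missed_4w + worked_4w) > 0
    keep = df.index[defined]
    dropped_idx = cohort.index.difference(keep)
    excluded = pd.DataFrame({
        "worker_id": cohort.loc[dropped_idx].get("worker_id", dropped_idx),
        "reason": ["missing WPAI item" if not complete.get(i, False)
                   else "zero missed and worked hours"
                   for i in dropped_idx],
    })
    if len(excluded):
        logger.info("WPAI scoring: %d record(s) excluded", len(excluded))

    df = df.loc[keep]
    missed_wk = rescale_recall(df["wpai_hours_missed_4w"].to_numpy(dtype=float))
    worked_wk = rescale_recall(df["wpai_hours_worked_4w"].to_numpy(dtype=float))
    a_pct = absenteeism(missed_wk, worked_wk)
    p_pct = presenteeism(df["wpai_impairment_0_10"].to_numpy())
    t_pct = total_loss(a_pct, p_pct)

    losses = pd.DataFrame({
        "worker_id": df.get("worker_id", df.index),
        "absenteeism_pct": a_pct,
        "presenteeism_pct": p_pct,
        "total_loss_pct": t_pct,
        "hours_missed_wk": missed_wk,
        "hours_worked_wk": worked_wk,
    }, index=keep)

    n = len(losses)
    if n == 0:
        raise ValueError("no scorable records in cohort")
    summary = {
        "n": n,
        "n_excluded": int(len(excluded)),
        "any_absenteeism_pct": 100.0 * float(np.mean(a_pct > 0)),
        "any_presenteeism_pct": 100.0 * float(np.mean(p_pct > 0)),
        "absenteeism_mean": float(np.mean(a_pct)),
        "absenteeism_sd": float(np.std(a_pct, ddof=1)) if n > 1 else 0.0,
        "presenteeism_mean": float(np.mean(p_pct)),
        "presenteeism_sd": float(np.std(p_pct, ddof=1)) if n > 1 else 0.0,
        "total_loss_mean": float(np.mean(t_pct)),
        "total_loss_sd": float(np.std(t_pct, ddof=1)) if n > 1 else 0.0,
        "hours_missed_wk_mean": float(np.mean(missed_wk)),
    }
    return losses, summary, excluded
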