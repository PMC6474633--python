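"""The confidence-reset test and related group-level analyses.

The qualitative hallmark of hierarchical learning in this task: a streak
of repetitions that looks unlikely in context ("suspicious") should make a
learner with an internal model of *coupled* change points uncertain about
both transition probabilities — including the one it observed nothing
about during the streak.  A flat learner also loses confidence during a
streak (its counts for the unobserved transition leak away) but identically
for suspicious and non-suspicious streaks.  The test therefore contrasts
the pre-to-post change in confidence about the non-repeating transition
between streak types.

This module classifies streaks, computes pre/post effects, runs the group
contrasts and the subject-versus-optimal regressions, applies the
performance-based exclusion rule, and measures apparent learning rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trace import ObserverTrace

__all__ = ["GroupStat", "classify_streaks", "pre_post_change",
           "streak_type_contrast", "group_ttest", "subject_regression",
           "first_order_covariates", "residual_confidence_test",
           "exclusion_filter", "apparent_learning_rate"]

EXCLUSION_RHO = 0.18  # minimum subject-vs-optimal Pearson rho to include


@dataclass
class GroupStat:
    """One-sample group statistic over a per-subject quantity."""

    mean: float
    sem: float
    t: float
    df: int
    p: float

    @classmethod
    def from_values(cls, values) -> "GroupStat":
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        n = v.size
        if n < 2:
            raise ValueError("need at least 2 subjects")
        res = stats.ttest_1samp(v, 0.0)
        return cls(mean=float(v.mean()),
                   sem=float(v.std(ddof=1) / np.sqrt(n)),
                   t=float(res.statistic), df=n - 1,
                   p=float(res.pvalue))


def group_ttest(values) -> GroupStat:
    """One-sample t-test of a per-subject quantity against zero."""
    return GroupStat.from_values(values)


def classify_streaks(trace_hier: ObserverTrace, streaks: list) -> list:
    """Label each streak suspicious or non-suspicious, in place.

    A streak is suspicious when the hierarchical observer's confidence
    about the *repeated* transition decreases on average over the streak —
    i.e. the repetitions look unlikely enough to hint at a change point.
    With pc = 0 the observer never entertains changes and its confidence
    only grows, so every streak degenerates to non-suspicious; callers
    should use a change-aware observer.
    """
    T = len(trace_hier)
    for s in streaks:
        if s.start < 0 or s.end >= T:
            raise IndexError("streak outside trace range")
        col = 0 if s.symbol == 1 else 1
        with np.errstate(divide="ignore"):
            conf_rep = -np.log(trace_hier.post_var[s.start:s.end + 1, col])
        mean_step = float(np.mean(np.diff(conf_rep)))
        s.label = "suspicious" if mean_step < 0 else "non_suspicious"
    return streaks


def pre_post_change(prob_values: np.ndarray, conf_values: np.ndarray,
                    design) -> pd.DataFrame:
    """Per-streak post-minus-pre differences at the designated questions.

    ``prob_values`` and ``conf_values`` are full-length per-trial arrays
    (a model trace or a subject's report columns); only the pre/post
    question trials of the selected streaks are read.  Streaks with a
    missing value at either question are dropped with a warning.
    """
    rows = []
    for streak, pre, post in design.prepost_pairs():
        vals = (prob_values[pre], prob_values[post],
                conf_values[pre], conf_values[post])
        if not np.all(np.isfinite(vals)):
            warnings.warn(f"missing report at streak {streak.start}; dropped")
            continue
        rows.append({
            "start": streak.start,
            "label": streak.label,
            "length": streak.length,
            "d_prob": float(prob_values[post] - prob_values[pre]),
            "d_conf": float(conf_values[post] - conf_values[pre]),
        })
    return pd.DataFrame(rows)


def streak_type_contrast(effects_per_subject: list,
                         on: str = "d_conf") -> GroupStat:
    """Group test of the streak-type interaction.

    Per subject: mean effect over non-suspicious streaks minus mean effect
    over suspicious ones (this sign makes the hierarchical confidence
    hallmark positive, since confidence drops after suspicious streaks).
    Subjects missing one streak type are dropped with a warning.
    """
    diffs = []
    for eff in effects_per_subject:
        by = eff.groupby("label")[on].mean()
        if "suspicious" not in by or "non_suspicious" not in by:
            warnings.warn("subject lacks one streak type; dropped")
            continue
        diffs.append(by["non_suspicious"] - by["suspicious"])
    if len(diffs) < 2:
        raise ValueError("need at least 2 subjects with both streak types")
    return GroupStat.from_values(diffs)


def subject_regression(y_per_subject: list, x_per_subject: list):
    """Per-subject OLS of reports on optimal values, with intercept.

    Returns (betas, rhos, GroupStat over beta).  Raises when a subject's
    explanatory variable is constant.
    """
    betas, rhos = [], []
    for y, x in zip(y_per_subject, x_per_subject):
        y = np.asarray(y, dtype=float)
        x = np.asarray(x, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 3 or np.ptp(x) == 0:
            raise ValueError("constant or insufficient explanatory variable")
        res = stats.linregress(x, y)
        betas.append(res.slope)
        rhos.append(res.rvalue)
    return (np.array(betas), np.array(rhos),
            GroupStat.from_values(betas))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def first_order_covariates(prob_report: np.ndarray,
                           next_stim: np.ndarray,
                           eps: float = 1e-6) -> np.ndarray:
    """Metrics a confidence report could inherit from the first-order
    estimate alone: distance of the report from 0.5, Shannon entropy of
    the reported probability, and surprise -ln p(observed next stimulus)
    under the report.  Columns are in that order, not yet z-scored."""
    p = np.clip(np.asarray(prob_report, dtype=float), eps, 1.0 - eps)
    dist = np.abs(p - 0.5)
    entropy = -(p * np.log(p) + (1.0 - p) * np.log(1.0 - p))
    p_obs = np.where(np.asarray(next_stim) == 1, p, 1.0 - p)
    surprise = -np.log(p_obs)
    return np.column_stack([dist, entropy, surprise])


def _ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def residual_confidence_test(conf_per_subject: list,
                             optimal_conf_per_subject: list,
                             covariates_per_subject: list) -> GroupStat:
    """Does confidence carry information beyond first-order estimates?

    Per subject, the confidence reports are regressed on the (z-scored)
    first-order covariates; the residuals are then regressed on the
    z-scored optimal confidence and the slope is tested at the group
    level.  A positive slope means confidence co-varies with the optimal
    log-precision over and above what the probability reports imply.
    Collinear covariate columns are dropped with a warning.
    """
    slopes = []
    for y, opt, cov in zip(conf_per_subject, optimal_conf_per_subject,
                           covariates_per_subject):
        y = np.asarray(y, dtype=float)
        opt = np.asarray(opt, dtype=float)
        cov = np.asarray(cov, dtype=float)
        ok = np.isfinite(y) & np.isfinite(opt) & np.all(
            np.isfinite(cov), axis=1)
        y, opt, cov = y[ok], opt[ok], cov[ok]
        cols = []
        for j in range(cov.shape[1]):
            z = _zscore(cov[:, j])
            if np.ptp(z) == 0 or any(
                    np.allclose(z, c) for c in cols):
                warnings.warn(f"covariate {j} constant or collinear; dropped")
                continue
            cols.append(z)
        resid = _ols_residuals(y, np.column_stack(cols)) if cols else y - y.mean()
        slope = float(np.polyfit(_zscore(opt), resid, 1)[0])
        slopes.append(slope)
    return GroupStat.from_values(slopes)


def exclusion_filter(subjects: list, optimal_traces: list):
    """Apply the performance-based exclusion rule.

    A subject is excluded when the Pearson correlation between their
    probability reports and the optimal estimates at question trials is
    below 0.18 (strict inequality; 0.18 itself is included).  Returns
    (included subjects, per-subject rho, number excluded).
    """
    included, rhos = [], []
    n_excluded = 0
    for subj, trace in zip(subjects, optimal_traces):
        q = subj.question_trials
        rho = float(stats.pearsonr(subj.prob_report[q],
                                   trace.p_next[q, 0]).statistic)
        rhos.append(rho)
        if rho < EXCLUSION_RHO:
            n_excluded += 1
        else:
            included.append(subj)
    return included, np.array(rhos), n_excluded


def apparent_learning_rate(estimate: np.ndarray, outcomes: np.ndarray,
                           tol: float = 1e-6) -> np.ma.MaskedArray:
    """Update size over prediction error,
    (theta_{t+1} - theta_t) / (y_{t+1} - theta_t).

    ``estimate`` is the per-trial first-order estimate of the tracked
    statistic and ``outcomes`` the binary observations on the same scale
    (1 when the tracked symbol occurred, else 0).  Trials with
    |prediction error| < ``tol`` are masked; a pure delta rule with rate
    alpha yields a constant alpha everywhere.
    """
    theta = np.asarray(estimate, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    update = theta[1:] - theta[:-1]
    pe = y[1:] - theta[:-1]
    mask = np.abs(pe) < tol
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mask, 0.0, update / np.where(mask, 1.0, pe))
    return np.ma.MaskedArray(ratio, mask=mask)
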