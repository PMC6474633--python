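"""Grid-search fitting of the observers and MSE model comparison.

Each observer has a single free parameter — the leak ``omega`` for the
flat model, the change prior ``pc`` for the hierarchical model — adjusted
by grid search to minimize a sum of squared errors (SSE).  The target is
either the generative probabilities of the observed stimuli (all trials)
or a subject's reports (question trials only).  Subject confidence lives
on a bounded slider while model confidence is an unbounded log-precision,
so the confidence objective is the residual sum of squares of a linear
regression of the subject's confidence on the model's.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .flat_observer import FlatParams, run_flat
from .hier_observer import HierParams, run_hier
from .trace import ObserverTrace

__all__ = ["ModelSpec", "FitResult", "default_grid",
           "fit_to_generative", "fit_to_subject_prob",
           "fit_to_subject_conf", "compare_models_mse",
           "generative_p1"]


@dataclass
class ModelSpec:
    """Which observer to fit and with what fixed structure."""

    kind: str = "hier"  # "hier" | "flat"
    coupling: str = "coupled"
    statistic: str = "transitions"
    grid_n: int = 50
    prior_counts: float = 1.0

    @property
    def param_name(self) -> str:
        return "pc" if self.kind == "hier" else "omega"

    def params(self, value: float):
        if self.kind == "hier":
            return HierParams(pc=value, grid_n=self.grid_n,
                              coupling=self.coupling,
                              statistic=self.statistic)
        return FlatParams(omega=value, prior_counts=self.prior_counts,
                          statistic=self.statistic)

    def run(self, seq, value: float) -> ObserverTrace:
        if self.kind == "hier":
            return run_hier(seq, self.params(value))
        return run_flat(seq, self.params(value))


@dataclass
class FitResult:
    param_name: str
    param_grid: np.ndarray
    objective: np.ndarray
    best: float
    target_kind: str

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.objective))


def default_grid(kind: str, n: int = 61) -> np.ndarray:
    """Log-spaced search grids: pc in 1e-4..0.5, omega in 1..1e3."""
    if kind == "hier":
        return np.geomspace(1e-4, 0.5, n)
    return np.geomspace(1.0, 1e3, n)


def generative_p1(seq) -> np.ndarray:
    """Generative probability that trial t is stimulus 1, given trial t-1.

    The first trial of each block is equiprobable (0.5).
    """
    T = len(seq)
    p1 = np.full(T, 0.5)
    if seq.statistic == "frequency":
        return seq.theta[:, 0].copy()
    for sl in seq.block_slices():
        x = seq.stimuli[sl]
        th = seq.theta[sl]
        prev1 = x[:-1] == 1
        p1[sl][1:] = np.where(prev1, th[1:, 0], 1.0 - th[1:, 1])
    return p1


def _argmin_smallest(grid: np.ndarray, sse: np.ndarray) -> float:
    """Ties broken toward the smaller parameter value."""
    order = np.argsort(grid)
    g, s = np.asarray(grid)[order], np.asarray(sse)[order]
    return float(g[np.argmin(s)])


def fit_to_generative(spec: ModelSpec, sequences: Sequence,
                      param_grid: np.ndarray = None) -> FitResult:
    """Minimize the SSE between the model's predictive probability of each
    observation and its generative probability, over all trials of all
    sequences.

    The model's prediction for trial t+1 is read from the trace at trial t
    and compared with the generative probability in effect at t+1; the
    comparison never crosses a block boundary.
    """
    if param_grid is None:
        param_grid = default_grid(spec.kind)
    param_grid = np.asarray(param_grid, dtype=float)
    if param_grid.size == 0:
        raise ValueError("empty parameter grid")
    sse = np.zeros(param_grid.size)
    for i, value in enumerate(param_grid):
        total = 0.0
        for seq in sequences:
            trace = spec.run(seq, value)
            gen = generative_p1(seq)
            for sl in seq.block_slices():
                pred = trace.p_next[sl][:-1, 0]
                total += float(np.sum((pred - gen[sl][1:]) ** 2))
        sse[i] = total
    if not np.all(np.isfinite(sse)):
        raise FloatingPointError("non-finite SSE on the grid")
    return FitResult(spec.param_name, param_grid, sse,
                     _argmin_smallest(param_grid, sse), "generative")


def fit_to_subject_prob(spec: ModelSpec, subject,
                        param_grid: np.ndarray = None) -> FitResult:
    """SSE over question trials between the model's predictive probability
    of stimulus 1 and the subject's probability report."""
    if param_grid is None:
        param_grid = default_grid(spec.kind)
    param_grid = np.asarray(param_grid, dtype=float)
    if param_grid.size == 0:
        raise ValueError("empty parameter grid")
    q = subject.question_trials
    if q.size == 0:
        raise ValueError("subject has no question trials")
    seq = subject.to_sequence()
    reports = subject.prob_report[q]
    sse = np.empty(param_grid.size)
    for i, value in enumerate(param_grid):
        trace = spec.run(seq, value)
        sse[i] = float(np.sum((trace.p_next[q, 0] - reports) ** 2))
    return FitResult(spec.param_name, param_grid, sse,
                     _argmin_smallest(param_grid, sse), "subject_prob")


def _regression_rss(y: np.ndarray, x: np.ndarray) -> float:
    """Residual sum of squares of OLS y ~ 1 + x."""
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def fit_to_subject_conf(spec: ModelSpec, subject,
                        param_grid: np.ndarray = None) -> FitResult:
    """For each grid point, regress the subject's confidence reports on
    the model's log-precision confidence (with intercept) and use the
    residual sum of squares as the objective.  The affine map absorbs the
    scale difference between slider and log-precision units."""
    if param_grid is None:
        param_grid = default_grid(spec.kind)
    param_grid = np.asarray(param_grid, dtype=float)
    if param_grid.size == 0:
        raise ValueError("empty parameter grid")
    q = subject.question_trials
    if q.size < 3:
        raise ValueError("need at least 3 question trials")
    seq = subject.to_sequence()
    reports = subject.conf_report[q]
    sse = np.empty(param_grid.size)
    for i, value in enumerate(param_grid):
        trace = spec.run(seq, value)
        sse[i] = _regression_rss(reports, trace.conf[q])
    return FitResult(spec.param_name, param_grid, sse,
                     _argmin_smallest(param_grid, sse), "subject_conf")


def compare_models_mse(subject, trace_hier: ObserverTrace,
                       trace_flat: ObserverTrace, on: str = "prob") -> float:
    """Paired goodness-of-fit difference MSE(hier) - MSE(flat) at the
    subject's question trials (negative = hierarchical fits better).

    Probability reports are compared directly; confidence reports are
    compared through the residuals of the per-subject affine regression,
    as the two live on different scales.
    """
    if len(trace_hier) != len(trace_flat) or len(trace_hier) != len(
            subject.stimulus):
        raise ValueError("traces and subject are misaligned")
    q = subject.question_trials
    if on == "prob":
        y = subject.prob_report[q]
        mse_h = float(np.mean((trace_hier.p_next[q, 0] - y) ** 2))
        mse_f = float(np.mean((trace_flat.p_next[q, 0] - y) ** 2))
    elif on == "conf":
        y = subject.conf_report[q]
        mse_h = _regression_rss(y, trace_hier.conf[q]) / q.size
        mse_f = _regression_rss(y, trace_flat.conf[q]) / q.size
    else:
        raise ValueError("on must be 'prob' or 'conf'")
    return mse_h - mse_f
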