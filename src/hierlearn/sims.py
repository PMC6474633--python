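"""Simulation studies comparing the two observers on classic tasks.

Two studies on the single-statistic (reward-rate) change-point task:

* apparent-learning-rate dynamics: with each model's single parameter
  fixed across conditions (fitted to the generative probabilities of both
  volatility conditions jointly), both the hierarchical and the flat
  observer show transient increases of their apparent learning rate after
  change points, and a higher average rate under higher volatility — so
  such modulations alone do not identify hierarchical inference;

* model-correlation maps: across a grid of volatility and odds-step
  levels, the two models' probability estimates are almost perfectly
  correlated while their confidence (log-precision) levels correlate far
  less — confidence, not the first-order estimate, is the informative
  read-out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fit import ModelSpec, default_grid, fit_to_generative
from .hallmark import apparent_learning_rate
from .taskgen import generate_frequency_sequence

__all__ = ["LearningRateConfig", "run_learning_rate_study", "run_correlation_map",
           "EXPERIMENT_VOLATILITY", "EXPERIMENT_STEP"]

# the regime of the behavioral experiment: volatility 1/75 and a fourfold
# minimum odds-ratio step at change points
EXPERIMENT_VOLATILITY = 0.013
EXPERIMENT_STEP = 4.0


@dataclass
class LearningRateConfig:
    """Fixed change-point schedules for the learning-rate study.

    The high-volatility schedule is the low-volatility one plus extra
    change points, as in the classic reward-rate design this emulates.
    """

    n_trials: int = 800
    low_cps: Sequence[int] = (100, 200, 300, 400, 500, 600, 700)
    high_extra_cps: Sequence[int] = (50, 150, 250, 350, 450, 550, 650, 750)
    n_reps: int = 1000
    n_fit_reps: int = 10
    prior_counts: float = 1.0
    grid_n: int = 50
    param_grid_size: int = 31
    post_window: int = 10
    pre_window: int = 10

    @property
    def high_cps(self) -> tuple:
        return tuple(sorted(set(self.low_cps) | set(self.high_extra_cps)))


def _schedule_sequence(cfg: LearningRateConfig, cps, rng) -> object:
    return generate_frequency_sequence(
        cfg.n_trials, rng, change_points=cps,
        prob_low=0.1, prob_high=0.9, min_odds_fold=None)


def _fit_models(cfg: LearningRateConfig, rng) -> dict:
    train = []
    for _ in range(cfg.n_fit_reps):
        train.append(_schedule_sequence(cfg, cfg.low_cps, rng))
        train.append(_schedule_sequence(cfg, cfg.high_cps, rng))
    out = {}
    for kind in ("hier", "flat"):
        spec = ModelSpec(kind=kind, statistic="frequency",
                         grid_n=cfg.grid_n, prior_counts=cfg.prior_counts)
        grid = default_grid(kind, cfg.param_grid_size)
        out[kind] = (spec, fit_to_generative(spec, train, grid).best)
    return out


def _cp_windows(values: np.ndarray, cps, post: int, pre: int):
    """Mean of ``values`` just after vs. just before each change point.

    ``values`` indexes updates: entry t is the update into trial t+1, so
    the first update driven by post-change data sits at index cp - 1.
    """
    post_vals, pre_vals = [], []
    for c in cps:
        post_vals.append(values[c - 1:c - 1 + post])
        pre_vals.append(values[c - 1 - pre:c - 1])
    return (float(np.ma.mean(np.ma.concatenate(post_vals))),
            float(np.ma.mean(np.ma.concatenate(pre_vals))))


def run_learning_rate_study(cfg: LearningRateConfig, rng: np.random.Generator,
                            n_reps: int = None) -> dict:
    """Apparent-learning-rate time courses of both models in a low- and a
    high-volatility condition, parameters fixed across conditions.

    Returns the fitted parameters, the mean learning-rate curve per model
    and condition, and per-repetition summaries: the post-minus-pre
    change-point contrast and the mean rate per condition.
    """
    n_reps = cfg.n_reps if n_reps is None else n_reps
    fitted = _fit_models(cfg, rng)
    conds = {"low": cfg.low_cps, "high": cfg.high_cps}
    curves = {(k, c): np.zeros(cfg.n_trials - 1)
              for k in fitted for c in conds}
    counts = {key: np.zeros(cfg.n_trials - 1) for key in curves}
    rows = []
    for rep in range(n_reps):
        for cond, cps in conds.items():
            seq = _schedule_sequence(cfg, cps, rng)
            y = (seq.stimuli == 1).astype(float)
            for kind, (spec, value) in fitted.items():
                trace = spec.run(seq, value)
                lr = apparent_learning_rate(trace.post_mean[:, 0], y)
                curves[(kind, cond)] += lr.filled(0.0)
                counts[(kind, cond)] += ~lr.mask
                post, pre = _cp_windows(lr, cps, cfg.post_window,
                                        cfg.pre_window)
                rows.append({"rep": rep, "model": kind, "condition": cond,
                             "post": post, "pre": pre,
                             "cp_contrast": post - pre,
                             "mean_rate": float(lr.mean())})
    for key in curves:
        with np.errstate(invalid="ignore"):
            curves[key] = np.where(counts[key] > 0,
                                   curves[key] / counts[key], np.nan)
    return {
        "omega": fitted["flat"][1],
        "pc": fitted["hier"][1],
        "curves": curves,
        "rep_stats": pd.DataFrame(rows),
    }


def _cell_models(volatility: float, step: float, n_train: int,
                 seq_len: int, grid_n: int, param_grid_size: int,
                 prior_counts: float, max_period: int,
                 rng: np.random.Generator) -> dict:
    train = [generate_frequency_sequence(
        seq_len, rng, change_prob=volatility,
        min_odds_fold=step if step > 1 else None, max_period=max_period)
        for _ in range(n_train)]
    out = {}
    for kind in ("hier", "flat"):
        spec = ModelSpec(kind=kind, statistic="frequency", grid_n=grid_n,
                         prior_counts=prior_counts)
        grid = default_grid(kind, param_grid_size)
        out[kind] = (spec, fit_to_generative(spec, train, grid).best)
    return out


def run_correlation_map(vol_grid: Sequence[float],
                        step_grid: Sequence[float],
                        rng: np.random.Generator,
                        n_train: int = 25,
                        n_eval: int = 25,
                        seq_len: int = 380,
                        grid_n: int = 50,
                        param_grid_size: int = 31,
                        prior_counts: float = 1.0,
                        max_period: int = 300) -> dict:
    """Cross-model correlations over a volatility x odds-step grid.

    Per cell: each model's parameter is fitted to the generative
    probabilities of ``n_train`` training sequences, then both models run
    on ``n_eval`` fresh sequences and their pooled per-trial probability
    estimates and confidence levels are correlated (Pearson).  Returns the
    two maps plus the fitted parameters per cell.
    """
    shape = (len(vol_grid), len(step_grid))
    rho_est = np.empty(shape)
    rho_conf = np.empty(shape)
    omega = np.empty(shape)
    pc = np.empty(shape)
    for i, vol in enumerate(vol_grid):
        for j, step in enumerate(step_grid):
            models = _cell_models(vol, step, n_train, seq_len, grid_n,
                                  param_grid_size, prior_counts,
                                  max_period, rng)
            est = {k: [] for k in models}
            cnf = {k: [] for k in models}
            for _ in range(n_eval):
                seq = generate_frequency_sequence(
                    seq_len, rng, change_prob=vol,
                    min_odds_fold=step if step > 1 else None,
                    max_period=max_period)
                for kind, (spec, value) in models.items():
                    trace = spec.run(seq, value)
                    est[kind].append(trace.p_next[:, 0])
                    cnf[kind].append(trace.conf)
            eh = np.concatenate(est["hier"])
            ef = np.concatenate(est["flat"])
            ch = np.concatenate(cnf["hier"])
            cf = np.concatenate(cnf["flat"])
            rho_est[i, j] = stats.pearsonr(eh, ef).statistic
            rho_conf[i, j] = stats.pearsonr(ch, cf).statistic
            omega[i, j] = models["flat"][1]
            pc[i, j] = models["hier"][1]
    return {
        "vol_grid": np.asarray(vol_grid, dtype=float),
        "step_grid": np.asarray(step_grid, dtype=float),
        "rho_estimates": rho_est,
        "rho_confidence": rho_conf,
        "omega": omega,
        "pc": pc,
        "n_trials": len(vol_grid) and n_eval * seq_len,
    }
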