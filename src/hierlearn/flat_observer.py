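"""Flat (non-hierarchical) ideal observer: leaky-count Beta estimation.

The flat observer assumes the tracked statistic is fixed and estimates it
from exponentially decaying observation counts: the k-th past observation
carries weight e^(-k/omega).  Adding pseudo-counts, each statistic has a
Beta posterior whose mean is the probability estimate and whose
log-precision (-ln variance) is the confidence.  The model has no
representation of change points; its leak is what lets it track a drifting
environment.  With zero pseudo-counts its mean estimate converges to a
delta rule (exponential smoothing) with learning rate 1 - e^(-1/omega).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.signal import lfilter

from .trace import ObserverTrace

__all__ = ["FlatParams", "LeakyCounts", "BetaSummary",
           "update_counts", "posterior_summary", "run_flat"]

# count vector layout in transitions mode: [N(1|1), N(2|1), N(2|2), N(1|2)]
_PAIR_INDEX = {(1, 1): 0, (1, 2): 1, (2, 2): 2, (2, 1): 3}


@dataclass
class FlatParams:
    """Leak time-constant ``omega`` (trials; ``inf`` = perfect integration),
    pseudo-counts, and the tracked statistic.

    ``prior_counts`` may be a scalar (applied to every count; the classic
    choices are 0 and 1, the Laplace-Bayes prior) or a full vector in the
    count layout.
    """

    omega: float = 20.0
    prior_counts: Union[float, np.ndarray] = 1.0
    statistic: str = "transitions"

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise ValueError("omega must be positive (use inf for no leak)")
        if self.statistic not in ("transitions", "frequency"):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        n = 4 if self.statistic == "transitions" else 2
        self.prior_counts = np.broadcast_to(
            np.asarray(self.prior_counts, dtype=float), (n,)).copy()
        if np.any(self.prior_counts < 0):
            raise ValueError("pseudo-counts must be non-negative")

    @property
    def decay(self) -> float:
        return 1.0 if np.isinf(self.omega) else float(np.exp(-1.0 / self.omega))


@dataclass
class LeakyCounts:
    """Weighted observation counts.

    Transitions mode: four counts [N(1|1), N(2|1), N(2|2), N(1|2)];
    frequency mode: two counts [N(1), N(2)].
    """

    n: np.ndarray
    statistic: str = "transitions"

    @classmethod
    def empty(cls, params: FlatParams) -> "LeakyCounts":
        size = 4 if params.statistic == "transitions" else 2
        return cls(np.zeros(size), params.statistic)


@dataclass
class BetaSummary:
    """Beta(a, b) posterior of one tracked probability."""

    a: float
    b: float

    @property
    def mean(self) -> float:
        if self.a + self.b == 0:
            return 0.5  # degenerate: no data, no prior
        return self.a / (self.a + self.b)

    @property
    def variance(self) -> float:
        s = self.a + self.b
        if s == 0 or self.a == 0 or self.b == 0:
            return np.nan  # precision undefined (flagged, excluded upstream)
        return self.a * self.b / (s * s * (s + 1.0))

    @property
    def log_precision(self) -> float:
        v = self.variance
        return np.nan if np.isnan(v) else -float(np.log(v))


def update_counts(counts: LeakyCounts, prev_stim: int, new_stim: int,
                  params: FlatParams) -> LeakyCounts:
    """One observation step: decay every count by e^(-1/omega), then add 1
    to the count of the observed pair (or symbol, in frequency mode)."""
    n = counts.n * params.decay
    if params.statistic == "transitions":
        n[_PAIR_INDEX[(prev_stim, new_stim)]] += 1.0
    else:
        n[new_stim - 1] += 1.0
    return LeakyCounts(n, counts.statistic)


def posterior_summary(counts: LeakyCounts, params: FlatParams,
                      conditioning_stim: int = 1) -> BetaSummary:
    """Beta posterior of the repetition probability of
    ``conditioning_stim`` (transitions) or of p(stimulus==1) (frequency)."""
    pr = params.prior_counts
    if params.statistic == "transitions":
        if conditioning_stim == 1:
            a = counts.n[0] + pr[0]
            b = counts.n[1] + pr[1]
        else:
            a = counts.n[2] + pr[2]
            b = counts.n[3] + pr[3]
    else:
        a = counts.n[0] + pr[0]
        b = counts.n[1] + pr[1]
    return BetaSummary(float(a), float(b))


def _beta_moments(a: np.ndarray, b: np.ndarray):
    s = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = np.where(s > 0, a / np.where(s > 0, s, 1.0), 0.5)
        var = np.where((a > 0) & (b > 0),
                       a * b / (s * s * (s + 1.0)), np.nan)
    return mean, var


def run_flat(seq, params: FlatParams) -> ObserverTrace:
    """Run the flat observer over a stimulus sequence.

    Counts reset at block boundaries.  The trace at trial t summarizes the
    posterior after observing stimulus t: the predictive probability of
    the next stimulus and the log-precision confidence about the relevant
    statistic.
    """
    stimuli = np.asarray(seq.stimuli)
    T = len(stimuli)
    d = params.decay
    if params.statistic == "transitions":
        counts = np.zeros((T, 4))
        for sl in seq.block_slices():
            x = stimuli[sl]
            ind = np.zeros((len(x), 4))
            for (p, c), j in _PAIR_INDEX.items():
                ind[1:, j] = (x[:-1] == p) & (x[1:] == c)
            counts[sl] = lfilter([1.0], [1.0, -d], ind, axis=0)
        pr = params.prior_counts
        a11, b11 = counts[:, 0] + pr[0], counts[:, 1] + pr[1]
        a22, b22 = counts[:, 2] + pr[2], counts[:, 3] + pr[3]
        m11, v11 = _beta_moments(a11, b11)
        m22, v22 = _beta_moments(a22, b22)
        is1 = stimuli == 1
        p1 = np.where(is1, m11, 1.0 - m22)
        var_rel = np.where(is1, v11, v22)
        a_rel = np.where(is1, a11, a22)
        b_rel = np.where(is1, b11, b22)
        post_mean = np.column_stack([m11, m22])
        post_var = np.column_stack([v11, v22])
    else:
        counts = np.zeros((T, 2))
        for sl in seq.block_slices():
            x = stimuli[sl]
            ind = np.column_stack([(x == 1).astype(float),
                                   (x == 2).astype(float)])
            counts[sl] = lfilter([1.0], [1.0, -d], ind, axis=0)
        pr = params.prior_counts
        a_rel = counts[:, 0] + pr[0]
        b_rel = counts[:, 1] + pr[1]
        m, v = _beta_moments(a_rel, b_rel)
        p1, var_rel = m, v
        post_mean = m[:, None]
        post_var = v[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        conf = np.where(np.isnan(var_rel), np.nan, -np.log(var_rel))
    return ObserverTrace(
        p_next=np.column_stack([p1, 1.0 - p1]),
        conf=conf,
        post_mean=post_mean,
        post_var=post_var,
        statistic=params.statistic,
        extra={"a": a_rel, "b": b_rel},
    )
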