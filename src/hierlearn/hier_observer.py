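"""Hierarchical ideal observer: forward filtering of a change-point HMM.

The observer assumes the tracked statistic theta may be redrawn from its
prior at any observation with fixed probability ``pc``.  Casting this as a
hidden Markov model over theta, the joint distribution of theta and the
observations is filtered forward on a discretized grid: at each trial the
previous posterior is mixed with the re-injection prior (weights 1-pc and
pc), multiplied by the likelihood of the new observation, and
renormalized.  The predictive probability of the next stimulus is the mean
of the marginal posterior of the relevant transition probability, and the
confidence is its log-precision.

Variants: coupled (a single 2-D posterior over [p(1|1), p(2|2)] whose
change points reset both dimensions jointly — the main-task structure),
uncoupled (two independent 1-D filters, each with its own change process —
the control-task structure), and frequency (one 1-D filter over p(1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .trace import ObserverTrace

__all__ = ["HierParams", "JointDist", "init_joint", "forward_update",
           "predict", "confidence", "run_hier"]


class UnderflowError(FloatingPointError):
    """Total posterior mass vanished numerically."""


@dataclass
class HierParams:
    """Change probability ``pc``, grid resolution, and model structure."""

    pc: float = 1.0 / 75.0
    grid_n: int = 50
    coupling: str = "coupled"
    statistic: str = "transitions"

    def __post_init__(self) -> None:
        if not 0.0 <= self.pc <= 1.0:
            raise ValueError("pc must lie in [0, 1]")
        if self.grid_n < 5:
            raise ValueError("grid_n must be at least 5")
        if self.coupling not in ("coupled", "uncoupled"):
            raise ValueError(f"unknown coupling {self.coupling!r}")
        if self.statistic not in ("transitions", "frequency"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


@dataclass
class JointDist:
    """Posterior mass over the theta grid.

    ``grid`` holds the midpoints of a uniform partition of (0, 1).
    ``weights`` is (n, n) over (p(1|1), p(2|2)) for the coupled model, a
    tuple of two 1-D arrays for the uncoupled model, and a single 1-D
    array in frequency mode.  Weights are kept normalized to sum 1.
    """

    grid: np.ndarray
    weights: object
    coupling: str = "coupled"
    statistic: str = "transitions"
    log_evidence: float = field(default=0.0)

    def copy(self) -> "JointDist":
        if isinstance(self.weights, tuple):
            w = tuple(x.copy() for x in self.weights)
        else:
            w = self.weights.copy()
        return JointDist(self.grid, w, self.coupling, self.statistic,
                         self.log_evidence)


def make_grid(n: int) -> np.ndarray:
    """Midpoints of n equal bins on (0, 1)."""
    return (np.arange(n) + 0.5) / n


def init_joint(params: HierParams) -> JointDist:
    """Uniform (flat) prior over the grid."""
    g = make_grid(params.grid_n)
    n = params.grid_n
    if params.statistic == "frequency":
        w = np.full(n, 1.0 / n)
    elif params.coupling == "coupled":
        w = np.full((n, n), 1.0 / n**2)
    else:
        w = (np.full(n, 1.0 / n), np.full(n, 1.0 / n))
    return JointDist(g, w, params.coupling, params.statistic)


def _likelihood_1d(grid: np.ndarray, repeat: bool) -> np.ndarray:
    return grid if repeat else 1.0 - grid


def forward_update(joint: JointDist, prev_stim: int, new_stim: int,
                   params: HierParams) -> JointDist:
    """One filtering step of the change-point HMM.

    New weights are proportional to
    ``likelihood(new | theta, prev) * ((1-pc) * weights + pc * prior)``.
    The coupled model resets both dimensions jointly; in the uncoupled
    model each 1-D chain gets its own change mixture and only the chain
    conditioned on ``prev_stim`` receives a non-trivial likelihood.
    """
    out = joint.copy()
    pc = params.pc
    g = joint.grid
    n = len(g)
    if params.statistic == "frequency":
        w = (1.0 - pc) * joint.weights + pc / n
        w = w * _likelihood_1d(g, new_stim == 1)
        out.weights, out.log_evidence = _normalize(w, joint.log_evidence)
        return out
    if params.coupling == "coupled":
        w = (1.0 - pc) * joint.weights + pc / n**2
        lik = _likelihood_1d(g, new_stim == prev_stim)
        if prev_stim == 1:
            w = w * lik[:, None]
        else:
            w = w * lik[None, :]
        out.weights, out.log_evidence = _normalize(w, joint.log_evidence)
        return out
    w1, w2 = joint.weights
    w1 = (1.0 - pc) * w1 + pc / n
    w2 = (1.0 - pc) * w2 + pc / n
    lik = _likelihood_1d(g, new_stim == prev_stim)
    if prev_stim == 1:
        w1 = w1 * lik
    else:
        w2 = w2 * lik
    w1, le1 = _normalize(w1, 0.0)
    w2, le2 = _normalize(w2, 0.0)
    out.weights = (w1, w2)
    out.log_evidence = joint.log_evidence + le1 + le2
    return out


def _normalize(w: np.ndarray, log_evidence: float):
    z = w.sum()
    if not z > 0.0:
        raise UnderflowError("posterior mass underflowed to zero")
    return w / z, log_evidence + float(np.log(z))


def _marginals(joint: JointDist):
    """Marginal (mean, var) of each tracked probability."""
    g = joint.grid
    if joint.statistic == "frequency":
        ws = (joint.weights,)
    elif joint.coupling == "coupled":
        ws = (joint.weights.sum(axis=1), joint.weights.sum(axis=0))
    else:
        ws = joint.weights
    means, variances = [], []
    for w in ws:
        m = float(w @ g)
        v = float(w @ (g - m) ** 2)
        means.append(m)
        variances.append(v)
    return np.array(means), np.array(variances)


def predict(joint: JointDist, current_stim: int) -> Tuple[float, float]:
    """Predictive probability of (symbol 1, symbol 2) for the next trial:
    the posterior mean of the transition probability conditioned on
    ``current_stim`` (or of p(1) in frequency mode)."""
    means, _ = _marginals(joint)
    if joint.statistic == "frequency":
        p1 = means[0]
    elif current_stim == 1:
        p1 = means[0]
    else:
        p1 = 1.0 - means[1]
    return p1, 1.0 - p1


def confidence(joint: JointDist, current_stim: int) -> float:
    """Log-precision (-ln variance) of the relevant marginal posterior."""
    _, variances = _marginals(joint)
    if joint.statistic == "frequency":
        v = variances[0]
    else:
        v = variances[0] if current_stim == 1 else variances[1]
    if v <= 0.0:
        raise ValueError("zero posterior variance; grid too coarse")
    return -float(np.log(v))


def run_hier(seq, params: HierParams) -> ObserverTrace:
    """Filter a full sequence, resetting to the prior at block boundaries.

    The trace at trial t summarizes the *one-step-ahead* posterior over
    theta at trial t+1 given observations up to t — the distribution whose
    mean is the reported probability of the next stimulus.  It accounts
    for a possible change before the next observation, so at pc = 1 every
    prediction collapses to the prior (0.5).  In transitions mode the
    first stimulus of a block is uninformative (likelihood 1/2 for either
    symbol) and the posterior stays at the prior; in frequency mode it
    already updates the estimated rate.
    """
    stimuli = np.asarray(seq.stimuli)
    T = len(stimuli)
    n_stats = 1 if params.statistic == "frequency" else 2
    p1 = np.empty(T)
    conf = np.empty(T)
    post_mean = np.empty((T, n_stats))
    post_var = np.empty((T, n_stats))
    log_evidence = 0.0
    # prior moments on the grid, for the change-mixture look-ahead
    g = make_grid(params.grid_n)
    m_u = float(g.mean())
    v_u = float(((g - m_u) ** 2).mean())
    pc = params.pc
    for sl in seq.block_slices():
        joint = init_joint(params)
        x = stimuli[sl]
        base = sl.start
        for i in range(len(x)):
            if params.statistic == "frequency":
                joint = forward_update(joint, 0, int(x[i]), params)
            elif i > 0:
                joint = forward_update(joint, int(x[i - 1]), int(x[i]),
                                       params)
            else:
                joint.log_evidence += np.log(0.5)
            t = base + i
            means, variances = _marginals(joint)
            # moments of the predictive mixture
            # (1-pc) * filtered + pc * prior
            m_pred = (1.0 - pc) * means + pc * m_u
            e2 = (1.0 - pc) * (variances + means**2) \
                + pc * (v_u + m_u**2)
            v_pred = e2 - m_pred**2
            post_mean[t] = m_pred
            post_var[t] = v_pred
            if params.statistic == "frequency" or x[i] == 1:
                p1[t] = m_pred[0]
                v = v_pred[0]
            else:
                p1[t] = 1.0 - m_pred[1]
                v = v_pred[1]
            if v <= 0.0:
                raise ValueError("zero posterior variance; grid too coarse")
            conf[t] = -np.log(v)
        log_evidence += joint.log_evidence
    return ObserverTrace(
        p_next=np.column_stack([p1, 1.0 - p1]),
        conf=conf,
        post_mean=post_mean,
        post_var=post_var,
        statistic=params.statistic,
        extra={"log_evidence": log_evidence},
    )
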