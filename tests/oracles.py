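"""Independent brute-force oracles used by the tests.

These deliberately avoid the forward-filtering recursion: the posterior of
the change-point model is obtained by exhaustive enumeration over every
change-point configuration of a short sequence, summing exact segment
likelihoods on the same theta grid.  Tractable only for a handful of
trials; that is the point.
"""

from itertools import product

import numpy as np

from hierlearn.hier_observer import make_grid


def _segments(change_config):
    """Split trial indices 0..T-1 into stable segments.

    ``change_config[t]`` says theta was redrawn just before observation
    t+1 (length T-1).
    """
    T = len(change_config) + 1
    edges = [0] + [t + 1 for t, c in enumerate(change_config) if c] + [T]
    return [list(range(a, b)) for a, b in zip(edges[:-1], edges[1:])]


def _pair_lik(theta_a, theta_b, prev, new):
    if prev == 1:
        return theta_a if new == 1 else 1.0 - theta_a
    return theta_b if new == 2 else 1.0 - theta_b


def enumerate_posterior_coupled(stimuli, pc, grid_n):
    """Joint posterior over the final (p(1|1), p(2|2)) grid point by
    exhaustive enumeration of change-point configurations."""
    g = make_grid(grid_n)
    T = len(stimuli)
    post = np.zeros((grid_n, grid_n))
    prior_cell = 1.0 / grid_n**2
    for config in product([0, 1], repeat=T - 1):
        p_config = np.prod([pc if c else 1.0 - pc for c in config])
        segs = _segments(config)
        closed = 1.0
        for seg in segs[:-1]:
            acc = 0.0
            for ia in range(grid_n):
                for ib in range(grid_n):
                    lik = 1.0
                    for t in seg:
                        if t == 0:
                            lik *= 0.5
                        else:
                            lik *= _pair_lik(g[ia], g[ib],
                                             stimuli[t - 1], stimuli[t])
                    acc += prior_cell * lik
            closed *= acc
        final = np.empty((grid_n, grid_n))
        for ia in range(grid_n):
            for ib in range(grid_n):
                lik = 1.0
                for t in segs[-1]:
                    if t == 0:
                        lik *= 0.5
                    else:
                        lik *= _pair_lik(g[ia], g[ib],
                                         stimuli[t - 1], stimuli[t])
                final[ia, ib] = prior_cell * lik
        post += p_config * closed * final
    return post / post.sum()


def enumerate_posterior_frequency(stimuli, pc, grid_n):
    """1-D analogue for the stimulus-frequency statistic (every trial,
    including the first, is a Bernoulli draw of the tracked rate)."""
    g = make_grid(grid_n)
    T = len(stimuli)
    post = np.zeros(grid_n)
    prior_cell = 1.0 / grid_n
    for config in product([0, 1], repeat=T - 1):
        p_config = np.prod([pc if c else 1.0 - pc for c in config])
        segs = _segments(config)
        closed = 1.0
        for seg in segs[:-1]:
            acc = 0.0
            for i in range(grid_n):
                lik = 1.0
                for t in seg:
                    lik *= g[i] if stimuli[t] == 1 else 1.0 - g[i]
                acc += prior_cell * lik
            closed *= acc
        final = np.empty(grid_n)
        for i in range(grid_n):
            lik = 1.0
            for t in segs[-1]:
                lik *= g[i] if stimuli[t] == 1 else 1.0 - g[i]
            final[i] = prior_cell * lik
        post += p_config * closed * final
    return post / post.sum()


def enumerate_posterior_uncoupled(stimuli, pc, grid_n, which):
    """1-D posterior of one repetition probability when each chain has its
    own change process.  ``which`` is 1 or 2: the conditioning stimulus.
    Trials whose previous stimulus differs contribute likelihood 1."""
    g = make_grid(grid_n)
    T = len(stimuli)
    post = np.zeros(grid_n)
    prior_cell = 1.0 / grid_n
    for config in product([0, 1], repeat=T - 1):
        p_config = np.prod([pc if c else 1.0 - pc for c in config])
        segs = _segments(config)

        def seg_lik(i, seg):
            lik = 1.0
            for t in seg:
                if t == 0 or stimuli[t - 1] != which:
                    continue
                lik *= g[i] if stimuli[t] == stimuli[t - 1] else 1.0 - g[i]
            return lik

        closed = 1.0
        for seg in segs[:-1]:
            closed *= sum(prior_cell * seg_lik(i, seg)
                          for i in range(grid_n))
        final = np.array([prior_cell * seg_lik(i, segs[-1])
                          for i in range(grid_n)])
        post += p_config * closed * final
    return post / post.sum()
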