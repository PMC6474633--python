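"""Generative process of the change-point transition-probability task.

Binary sequences (symbols coded 1/2) are produced by two hidden transition
probabilities theta = [p(1|1), p(2|2)] that are piecewise constant between
change points.  Stable-period lengths follow a truncated geometric
distribution; at a change point the probabilities are redrawn uniformly,
subject to a minimum fold change in odds ratio so that the change is
effective.  Change points are either shared by the two probabilities
("coupled", the main task) or independent ("uncoupled", the control task).

The module also assembles full experiments: concatenated blocks, streak
detection, question placement (quasi-periodic random questions plus
pre/post questions bracketing selected streaks), and rejection sampling of
sequences that satisfy the selection criteria used in the behavioral study.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "GenerativeConfig",
    "SelectionConfig",
    "TransitionProbPair",
    "StimulusSequence",
    "Streak",
    "ExperimentDesign",
    "sample_stable_periods",
    "sample_transition_probs",
    "sample_single_prob",
    "generate_block",
    "generate_sequence",
    "generate_frequency_sequence",
    "find_streaks",
    "place_questions",
    "assemble_experiment",
]


class ConfigError(ValueError):
    """Invalid generative configuration."""


class SelectionError(RuntimeError):
    """Sequence selection did not converge within the candidate budget."""


@dataclass
class GenerativeConfig:
    """Parameters of the generative process and experiment layout.

    ``change_prob`` is the per-trial change-point probability (the task's
    volatility, 1/75); ``mean_period`` is its reciprocal, the expected
    stable-period length in trials.  Periods longer than ``max_period`` are
    resampled.  Transition probabilities are drawn uniformly on
    [``prob_low``, ``prob_high``] with at least a ``min_odds_fold`` change
    of the odds ratio p/(1-p) across each change point (on at least one
    probability when coupled, on the changed probability when uncoupled).
    """

    change_prob: float = 1.0 / 75.0
    mean_period: float = 75.0
    max_period: int = 300
    prob_low: float = 0.1
    prob_high: float = 0.9
    min_odds_fold: float = 4.0
    coupled: bool = True
    block_length: int = 380
    n_blocks: int = 4
    question_rate: int = 15
    n_questions_total: int = 100
    n_streak_questions: int = 32

    def __post_init__(self) -> None:
        if self.mean_period <= 0:
            raise ConfigError("mean_period must be positive")
        if not (0.0 < self.prob_low < self.prob_high < 1.0):
            raise ConfigError("need 0 < prob_low < prob_high < 1")
        if self.min_odds_fold < 1.0:
            raise ConfigError("min_odds_fold must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "GenerativeConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SelectionConfig:
    """Criteria for accepting a candidate experiment.

    ``conf_drop_threshold`` is the minimum mean pre-to-post drop, in
    log-precision units, of the model's confidence about the non-repeating
    transition across a candidate sequence's suspicious streaks.
    ``duration_tol`` bounds the difference between the mean durations of
    the two selected streak classes, in trials.  ``conf_match_tol``
    (log-precision units) bounds the class difference in the *expected
    confidence change under a change-blind reference observer*: an
    uncoupled filter is run over the same sequence and its pre-to-post
    confidence change about the probed transition is matched between
    classes.  Suspicious streaks otherwise follow alternation-rich
    stretches whose fresher evidence decays differently — a pure
    forgetting confound.  With the null observer's predicted change
    equalized by construction, a residual streak-type effect can only
    reflect inference about shared change points.
    """

    min_streaks_per_label: int = 8
    conf_drop_threshold: float = 0.5
    duration_tol: float = 0.25
    conf_match_tol: float = 0.05
    max_candidates: int = 500
    n_subset_tries: int = 800


@dataclass(frozen=True)
class TransitionProbPair:
    """The two repetition probabilities theta = [p(1|1), p(2|2)].

    The cross transitions are implied: p(2|1) = 1 - p(1|1) and
    p(1|2) = 1 - p(2|2).
    """

    p_rep_a: float
    p_rep_b: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_rep_a < 1.0 and 0.0 < self.p_rep_b < 1.0):
            raise ValueError("transition probabilities must lie in (0, 1)")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_rep_a, self.p_rep_b])


@dataclass
class StimulusSequence:
    """A stimulus stream with its hidden generative trajectory.

    ``stimuli`` are coded 1/2.  For transition statistics ``theta`` has
    shape (T, 2) holding [p(1|1), p(2|2)] in effect at each trial (the
    value governing the transition *into* that trial); for frequency
    statistics it has shape (T, 1) holding p(stimulus==1).
    ``change_points`` flags, per trial and per tracked probability, whether
    the value differs from the previous trial.
    """

    stimuli: np.ndarray
    theta: np.ndarray
    change_points: np.ndarray
    block_id: np.ndarray
    statistic: str = "transitions"

    def __len__(self) -> int:
        return len(self.stimuli)

    @property
    def n_blocks(self) -> int:
        return int(self.block_id.max()) + 1 if len(self) else 0

    def block_slices(self) -> list:
        bounds = np.flatnonzero(np.diff(self.block_id)) + 1
        edges = np.concatenate([[0], bounds, [len(self)]])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


@dataclass
class Streak:
    """A maximal run of >= 7 identical stimuli starting after the 15th
    stimulus of its block.  Indices are 0-based and inclusive, global to
    the concatenated experiment."""

    start: int
    end: int
    symbol: int
    label: str = "unclassified"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ExperimentDesign:
    """A selected experiment: sequence, questions, and labelled streaks.

    ``question_trials`` maps a trial index to its kind ('random', 'pre' or
    'post').  A question at trial t is asked after stimulus t has been
    observed and probes the probability of stimulus t+1.
    """

    sequence: StimulusSequence
    question_trials: dict
    streaks: list
    selected_streaks: list
    meta: dict = field(default_factory=dict)

    @property
    def question_index(self) -> np.ndarray:
        return np.array(sorted(self.question_trials), dtype=int)

    def prepost_pairs(self) -> list:
        """(streak, pre_trial, post_trial) for each selected streak."""
        return [(s, s.start - 1, s.end + 1) for s in self.selected_streaks]


def _odds(p: float) -> float:
    return p / (1.0 - p)


def _fold_ok(p_new: float, p_old: float, min_fold: float) -> bool:
    r = _odds(p_new) / _odds(p_old)
    return max(r, 1.0 / r) >= min_fold


def sample_stable_periods(cfg: GenerativeConfig, total_length: int,
                          rng: np.random.Generator) -> list:
    """Draw stable-period lengths covering ``total_length`` trials.

    Lengths are geometric with success probability 1/mean_period; draws
    exceeding ``max_period`` are resampled (truncation by resampling), so
    the distribution stays geometric below the bound.  The last period is
    cut to fit exactly.
    """
    if total_length <= 0:
        raise ValueError("total_length must be positive")
    p = 1.0 / cfg.mean_period
    periods: list = []
    covered = 0
    while covered < total_length:
        length = int(rng.geometric(p))
        while length > cfg.max_period:
            length = int(rng.geometric(p))
        if covered + length > total_length:
            length = total_length - covered
        periods.append(length)
        covered += length
    return periods


def sample_single_prob(cfg: GenerativeConfig, prev: Optional[float],
                       rng: np.random.Generator,
                       max_tries: int = 10_000) -> float:
    """One probability uniform on [prob_low, prob_high]; when ``prev`` is
    given, rejection-sample until the odds ratio changed at least
    ``min_odds_fold``-fold."""
    for _ in range(max_tries):
        p = float(rng.uniform(cfg.prob_low, cfg.prob_high))
        if prev is None or _fold_ok(p, prev, cfg.min_odds_fold):
            return p
    raise SelectionError(
        f"no admissible probability after {max_tries} draws "
        f"(min_odds_fold={cfg.min_odds_fold} within "
        f"[{cfg.prob_low}, {cfg.prob_high}])")


def sample_transition_probs(cfg: GenerativeConfig,
                            prev: Optional[TransitionProbPair],
                            rng: np.random.Generator,
                            max_tries: int = 10_000) -> TransitionProbPair:
    """A pair of repetition probabilities, uniform on the configured range.

    After the first period, the pair is rejection-sampled until at least
    one coordinate satisfies the odds-fold constraint, guaranteeing an
    effective change.
    """
    for _ in range(max_tries):
        pa = float(rng.uniform(cfg.prob_low, cfg.prob_high))
        pb = float(rng.uniform(cfg.prob_low, cfg.prob_high))
        if prev is None:
            return TransitionProbPair(pa, pb)
        if (_fold_ok(pa, prev.p_rep_a, cfg.min_odds_fold)
                or _fold_ok(pb, prev.p_rep_b, cfg.min_odds_fold)):
            return TransitionProbPair(pa, pb)
    raise SelectionError(
        f"no admissible probability pair after {max_tries} draws")


def _coupled_trajectory(cfg: GenerativeConfig, length: int,
                        rng: np.random.Generator):
    periods = sample_stable_periods(cfg, length, rng)
    theta = np.empty((length, 2))
    change = np.zeros((length, 2), dtype=bool)
    pos = 0
    pair: Optional[TransitionProbPair] = None
    for k, per in enumerate(periods):
        pair = sample_transition_probs(cfg, pair, rng)
        theta[pos:pos + per] = pair.as_array()
        if k > 0:
            change[pos] = True
        pos += per
    return theta, change


def _uncoupled_trajectory(cfg: GenerativeConfig, length: int,
                          rng: np.random.Generator):
    theta = np.empty((length, 2))
    change = np.zeros((length, 2), dtype=bool)
    for j in range(2):
        periods = sample_stable_periods(cfg, length, rng)
        pos = 0
        prev: Optional[float] = None
        for k, per in enumerate(periods):
            p = sample_single_prob(cfg, prev, rng)
            theta[pos:pos + per, j] = p
            if k > 0:
                change[pos, j] = True
            pos += per
            prev = p
    return theta, change


def generate_block(cfg: GenerativeConfig, rng: np.random.Generator,
                   block_index: int = 0) -> StimulusSequence:
    """One block of ``cfg.block_length`` stimuli.

    The first stimulus is equiprobable; each next stimulus is drawn from
    the repetition probability of the current trial conditioned on the
    previous stimulus.  Coupled: both probabilities are redrawn at shared
    change points; uncoupled: each probability has its own change points.
    """
    length = cfg.block_length
    if cfg.coupled:
        theta, change = _coupled_trajectory(cfg, length, rng)
    else:
        theta, change = _uncoupled_trajectory(cfg, length, rng)
    stimuli = np.empty(length, dtype=int)
    stimuli[0] = 1 if rng.random() < 0.5 else 2
    u = rng.random(length)
    for t in range(1, length):
        prev = stimuli[t - 1]
        p_rep = theta[t, 0] if prev == 1 else theta[t, 1]
        stimuli[t] = prev if u[t] < p_rep else (3 - prev)
    return StimulusSequence(
        stimuli=stimuli, theta=theta, change_points=change,
        block_id=np.full(length, block_index, dtype=int))


def generate_sequence(cfg: GenerativeConfig,
                      rng: np.random.Generator) -> StimulusSequence:
    """Concatenate ``cfg.n_blocks`` independently generated blocks."""
    blocks = [generate_block(cfg, rng, b) for b in range(cfg.n_blocks)]
    return StimulusSequence(
        stimuli=np.concatenate([b.stimuli for b in blocks]),
        theta=np.concatenate([b.theta for b in blocks]),
        change_points=np.concatenate([b.change_points for b in blocks]),
        block_id=np.concatenate([b.block_id for b in blocks]),
    )


def generate_frequency_sequence(length: int, rng: np.random.Generator,
                                change_prob: Optional[float] = None,
                                change_points: Optional[Sequence[int]] = None,
                                prob_low: float = 0.1,
                                prob_high: float = 0.9,
                                min_odds_fold: Optional[float] = None,
                                max_period: Optional[int] = None,
                                block_index: int = 0) -> StimulusSequence:
    """A Bernoulli sequence whose single rate p(stimulus==1) jumps at
    change points — the classic probability/reward learning task.

    Change points are either given explicitly (``change_points``, trial
    indices) or drawn per trial with probability ``change_prob``.  When
    ``min_odds_fold`` is set, the new rate must change the odds ratio at
    least that many fold.
    """
    if (change_prob is None) == (change_points is None):
        raise ValueError("give exactly one of change_prob / change_points")
    if change_points is None:
        flags = rng.random(length) < change_prob
        flags[0] = False
        if max_period is not None:
            # re-break overly long stable periods
            last = 0
            for t in range(1, length):
                if flags[t]:
                    last = t
                elif t - last >= max_period:
                    flags[t] = True
                    last = t
        cps = np.flatnonzero(flags)
    else:
        cps = np.asarray(sorted(change_points), dtype=int)
    helper_cfg = GenerativeConfig(prob_low=prob_low, prob_high=prob_high,
                                  min_odds_fold=min_odds_fold or 1.0)
    theta = np.empty((length, 1))
    change = np.zeros((length, 1), dtype=bool)
    edges = np.concatenate([[0], cps, [length]])
    prev: Optional[float] = None
    for a, b in zip(edges[:-1], edges[1:]):
        if a == b:
            continue
        p = sample_single_prob(helper_cfg,
                               prev if min_odds_fold else None, rng)
        theta[a:b, 0] = p
        if a > 0:
            change[a, 0] = True
        prev = p
    stimuli = np.where(rng.random(length) < theta[:, 0], 1, 2)
    return StimulusSequence(
        stimuli=stimuli, theta=theta, change_points=change,
        block_id=np.full(length, block_index, dtype=int),
        statistic="frequency")


# streaks start strictly after the 15th stimulus of their block (0-based
# start index >= 15) so the observer has context to judge them
MIN_STREAK_LENGTH = 7
MIN_STREAK_START = 15


def find_streaks(seq: StimulusSequence) -> list:
    """Maximal runs of identical stimuli qualifying as streaks."""
    streaks: list = []
    for sl in seq.block_slices():
        x = seq.stimuli[sl]
        offset = sl.start
        t = 0
        n = len(x)
        while t < n:
            u = t
            while u + 1 < n and x[u + 1] == x[t]:
                u += 1
            run_len = u - t + 1
            if run_len >= MIN_STREAK_LENGTH and t >= MIN_STREAK_START:
                streaks.append(Streak(start=offset + t, end=offset + u,
                                      symbol=int(x[t])))
            t = u + 1
    return streaks


def _streak_eligible(streak: Streak, seq: StimulusSequence) -> bool:
    """Pre/post questions must stay inside the streak's block."""
    post = streak.end + 1
    return (post < len(seq)
            and seq.block_id[post] == seq.block_id[streak.start]
            and streak.start >= 1
            and seq.block_id[streak.start - 1] == seq.block_id[streak.start])


def place_questions(seq: StimulusSequence, selected_streaks: list,
                    cfg: GenerativeConfig, rng: np.random.Generator,
                    max_tries: int = 50) -> dict:
    """Question trials: pre/post around each selected streak plus
    quasi-periodic random questions (gap 15 +/- 5), no two adjacent.

    The pre question sits on the last trial before the streak and the post
    question on the trial that terminates it, so both probe the transition
    from the non-repeated stimulus.
    """
    total = len(seq)
    questions: dict = {}
    for s in selected_streaks:
        pre, post = s.start - 1, s.end + 1
        if not _streak_eligible(s, seq):
            raise SelectionError("selected streak collides with block edge")
        questions[pre] = "pre"
        questions[post] = "post"
    n_random = cfg.n_questions_total - len(questions)
    if n_random < 0:
        raise ConfigError("more streak questions than total questions")
    jitter = cfg.question_rate // 3
    for _ in range(max_tries):
        taken = set(questions)
        random_qs: list = []
        pos = int(rng.integers(3, cfg.question_rate + 1))
        while pos < total - 1 and len(random_qs) < n_random:
            cand = pos
            # shift within a small window to avoid adjacency collisions
            for shift in (0, 1, -1, 2, -2, 3, -3):
                c = cand + shift
                if 0 < c < total - 1 and not any(
                        (c + d) in taken for d in (-1, 0, 1)):
                    random_qs.append(c)
                    taken.add(c)
                    break
            pos += int(cfg.question_rate
                       + rng.integers(-jitter, jitter + 1))
        if len(random_qs) < n_random:
            # fill remaining slots anywhere admissible
            free = [t for t in range(1, total - 1)
                    if not any((t + d) in taken for d in (-1, 0, 1))]
            rng.shuffle(free)
            need = n_random - len(random_qs)
            fill = []
            for t in free:
                if not any((t + d) in taken for d in (-1, 0, 1)):
                    fill.append(t)
                    taken.add(t)
                if len(fill) == need:
                    break
            random_qs.extend(fill)
        if len(random_qs) > n_random:
            keep = rng.choice(len(random_qs), size=n_random, replace=False)
            random_qs = [random_qs[i] for i in sorted(keep)]
        if len(random_qs) == n_random:
            for t in random_qs:
                questions[t] = "random"
            return questions
    raise SelectionError("could not place the random questions")


def _pick_matched_subsets(susp: list, nonsusp: list, k: int,
                          selection: "SelectionConfig",
                          null_d_conf: dict,
                          rng: np.random.Generator):
    """Choose k streaks per label with approximately equal mean durations
    and mean null-observer confidence changes (random subset search)."""
    best = None
    best_cost = np.inf
    ls = np.array([s.length for s in susp], dtype=float)
    ln = np.array([s.length for s in nonsusp], dtype=float)
    cs = np.array([null_d_conf[id(s)] for s in susp])
    cn = np.array([null_d_conf[id(s)] for s in nonsusp])
    for _ in range(selection.n_subset_tries):
        i = rng.choice(len(susp), size=k, replace=False)
        j = rng.choice(len(nonsusp), size=k, replace=False)
        cost = max(abs(ls[i].mean() - ln[j].mean())
                   / selection.duration_tol,
                   abs(cs[i].mean() - cn[j].mean())
                   / selection.conf_match_tol)
        if cost < best_cost:
            best_cost = cost
            best = (i, j)
        if best_cost <= 1.0:
            break
    if best is None or best_cost > 1.0:
        return None
    i, j = best
    return [susp[a] for a in i], [nonsusp[b] for b in j]


def _concat_blocks(blocks: list) -> StimulusSequence:
    return StimulusSequence(
        stimuli=np.concatenate([b.stimuli for b in blocks]),
        theta=np.concatenate([b.theta for b in blocks]),
        change_points=np.concatenate([b.change_points for b in blocks]),
        block_id=np.concatenate(
            [np.full(len(b), i, dtype=int) for i, b in enumerate(blocks)]),
        statistic=blocks[0].statistic,
    )


def assemble_experiment(cfg: GenerativeConfig,
                        seed: int,
                        hier_params=None,
                        selection: Optional[SelectionConfig] = None,
                        ) -> ExperimentDesign:
    """Rejection-sample experiments until the selection criteria hold.

    An accepted 4-block experiment contains at least 8 suspicious and 8
    non-suspicious streaks with at least one of each per block, a matched
    subset of 8 + 8 streaks with approximately equal mean durations whose
    suspicious members show a sizeable model-confidence drop, and room for
    all 100 questions.  Because the observers reset at block boundaries
    (blocks are separate sequences, concatenated only for selection),
    candidate blocks are generated and evaluated independently and the
    experiment is assembled from admissible ones — equivalent to rejecting
    whole 4-block sequences, but far cheaper.  The accepted design records
    the seed, so it regenerates bit-exactly.
    """
    from .hier_observer import HierParams, run_hier
    from .hallmark import classify_streaks

    selection = selection or SelectionConfig()
    if hier_params is None:
        hier_params = HierParams(pc=cfg.change_prob, coupling="coupled")
    k = cfg.n_streak_questions // 4  # 8 selected streaks per label
    need = selection.min_streaks_per_label
    if 2 * k * (MIN_STREAK_LENGTH + 2) > cfg.block_length * cfg.n_blocks:
        raise SelectionError("streak demand infeasible for block length")
    unc_params = HierParams(pc=hier_params.pc, grid_n=hier_params.grid_n,
                            coupling="uncoupled",
                            statistic=hier_params.statistic)
    rng = np.random.default_rng(seed)
    # per entry: (block, labelled streaks, n_susp, n_non, sum of the
    # model's pre-to-post confidence drops over its suspicious streaks,
    # per-streak pre-confidence of the uncoupled reference observer);
    # blocks are self-contained because the observer resets between them
    pool: list = []
    for cand in range(selection.max_candidates):
        block = generate_block(cfg, rng, 0)
        streaks = [s for s in find_streaks(block)
                   if _streak_eligible(s, block)]
        trace = run_hier(block, hier_params)
        classify_streaks(trace, streaks)
        n_susp = sum(s.label == "suspicious" for s in streaks)
        n_non = sum(s.label == "non_suspicious" for s in streaks)
        if n_susp < 1 or n_non < 1:
            continue
        sum_drop = sum(trace.conf[s.start - 1] - trace.conf[s.end + 1]
                       for s in streaks if s.label == "suspicious")
        unc_trace = run_hier(block, unc_params)
        null_d_conf = [unc_trace.conf[s.end + 1] - unc_trace.conf[s.start - 1]
                       for s in streaks]
        pool.append((block, streaks, n_susp, n_non, sum_drop, null_d_conf))
        if len(pool) < cfg.n_blocks:
            continue
        # the four admissible blocks richest in the rare (suspicious) label
        order = sorted(range(len(pool)), key=lambda q: -pool[q][2])
        chosen = sorted(order[:cfg.n_blocks])
        if (sum(pool[q][2] for q in chosen) < need
                or sum(pool[q][3] for q in chosen) < need):
            continue
        # the candidate's suspicious streaks must show a sizeable mean
        # confidence decrease (a property of the whole candidate
        # sequence, not of the matched subset, which would select on the
        # outcome)
        tot_susp = sum(pool[q][2] for q in chosen)
        mean_drop = sum(pool[q][4] for q in chosen) / tot_susp
        if mean_drop < selection.conf_drop_threshold:
            # evict the weakest block so the combination changes
            worst = min(chosen, key=lambda q: pool[q][4] / pool[q][2])
            pool.pop(worst)
            continue
        blocks = [pool[q][0] for q in chosen]
        seq = _concat_blocks(blocks)
        streaks = []
        null_d_conf = {}
        for b_idx, q in enumerate(chosen):
            offset = b_idx * cfg.block_length
            for s, c in zip(pool[q][1], pool[q][5]):
                shifted = Streak(start=s.start + offset,
                                 end=s.end + offset,
                                 symbol=s.symbol, label=s.label)
                streaks.append(shifted)
                null_d_conf[id(shifted)] = c
        susp = [s for s in streaks if s.label == "suspicious"]
        nonsusp = [s for s in streaks if s.label == "non_suspicious"]
        picked = _pick_matched_subsets(susp, nonsusp, k, selection,
                                       null_d_conf, rng)
        failed = picked is None
        if not failed:
            sel_susp, sel_nonsusp = picked
            # pre/post question trials must be pairwise non-adjacent
            trials = sorted(t for s in sel_susp + sel_nonsusp
                            for t in (s.start - 1, s.end + 1))
            failed = np.min(np.diff(trials)) < 2
        if not failed:
            try:
                questions = place_questions(seq, sel_susp + sel_nonsusp,
                                            cfg, rng)
            except SelectionError:
                failed = True
        if failed:
            pool.pop(int(rng.choice(chosen)))
            continue
        return ExperimentDesign(
            sequence=seq,
            question_trials=questions,
            streaks=streaks,
            selected_streaks=sel_susp + sel_nonsusp,
            meta={"seed": seed, "n_candidate_blocks": cand + 1,
                  "config": cfg.to_dict(),
                  "hier_pc": hier_params.pc,
                  "hier_grid_n": hier_params.grid_n},
        )
    raise SelectionError(
        f"no admissible experiment within {selection.max_candidates} "
        f"candidate blocks (seed={seed}); consider relaxing SelectionConfig")
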