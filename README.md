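# hierlearn

Ideal-observer models for learning in volatile binary environments, built
to ask one question: does a learner carry an internal *hierarchical* model
of its world — one that represents change points — or does it merely
forget old evidence?

The package targets a transition-probability learning task: a stream of
two stimuli (coded 1/2) is generated by two hidden repetition
probabilities θ = [p(1|1), p(2|2)] that jump at unpredictable change
points (per-trial probability p_c = 1/75, values uniform on 0.1–0.9 with
at least a fourfold odds-ratio step). Subjects occasionally report the
probability of the next stimulus and their confidence in that estimate.

## Models

Both observers compute a full posterior over θ by Bayes' rule and report

* the **probability estimate**: the posterior mean of the transition
  probability conditioned on the current stimulus (Beta mean for the flat
  observer, grid posterior mean for the hierarchical one), and
* the **confidence**: the log-precision −ln Var of that posterior.

The **flat observer** assumes θ is fixed and counts transition pairs with
an exponential leak: the k-th past observation weighs e^(−k/ω). With
pseudo-counts N^prior, each transition has a Beta(N + N^prior, …)
posterior. With zero pseudo-counts the mean estimate is exactly a delta
rule with learning rate 1 − e^(−1/ω) — leaky counting is adaptive without
representing change at all.

The **hierarchical observer** represents the change process: θ may be
redrawn from its prior at any observation with probability p_c. Forward
filtering of the resulting hidden Markov model on a discretized grid,

  p(θ_{t+1}, y_{1:t+1}) ∝ p(y_{t+1}|θ_{t+1}, y_t) ·
      [(1 − p_c) p(θ_t = θ_{t+1}, y_{1:t}) + p_c · p(θ_{t+1}) ],

yields the exact posterior. Variants: **coupled** (both transition
probabilities share change points — one 2-D posterior), **uncoupled**
(independent change processes — two 1-D filters), and **frequency**
(tracking a single rate p(1), the classic reward-rate task).

The qualitative hallmark the package tests: after a *suspicious* streak of
repetitions (one that is unlikely in context and hints at a change
point), only the coupled hierarchical observer also loses confidence
about the *other* transition it observed nothing about — a flat or
uncoupled learner cannot generalize this way.

## Worked example

```python
from hierlearn import (GenerativeConfig, HierParams, FlatParams,
                       assemble_experiment, run_hier, run_flat)
from hierlearn.hallmark import pre_post_change

design = assemble_experiment(GenerativeConfig(), seed=7)
seq = design.sequence          # 4 blocks x 380 trials, 100 questions,
                               # 8 suspicious + 8 non-suspicious streaks
hier = run_hier(seq, HierParams(pc=1/75))
flat = run_flat(seq, FlatParams(omega=20.0))

for name, tr in (("hier", hier), ("flat", flat)):
    eff = pre_post_change(tr.p_next[:, 0], tr.conf, design)
    by = eff.groupby("label").d_conf.mean()
    print(f"{name}: d_conf suspicious {by['suspicious']:+.3f}, "
          f"non-suspicious {by['non_suspicious']:+.3f}")
```

prints

```
hier: d_conf suspicious -0.587, non-suspicious -0.209
flat: d_conf suspicious -0.259, non-suspicious -0.301
```

`d_conf` is the change in confidence (log-precision units) about the
non-repeated transition from just before to just after each selected
streak. The hierarchical observer's confidence drops far more after
suspicious streaks (−0.59 vs −0.21): suspecting a global change, it
resets what it knew about the unobserved probability. The flat observer
forgets during any streak, with no dependence on streak type — the
dissociation the task is designed to expose.

A command-line interface mirrors the library
(`hierlearn generate / run-model / fit / simulate / make-cohort`); see
`hierlearn --help`.

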