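"""End-to-end synthetic-cohort experiments.

Glue for the full pipeline: assemble selected experiments, run the
observers on them, simulate cohorts of report-giving subjects, and compute
the group-level streak-type contrast.  This is the harness behind the
dissociation test: cohorts whose reports come from the coupled
hierarchical observer should show a positive confidence contrast, while
flat-observer cohorts (and cohorts performing the uncoupled control task,
reporting from the uncoupled observer) should show none.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .flat_observer import FlatParams, run_flat
from .hallmark import GroupStat, pre_post_change, streak_type_contrast
from .hier_observer import HierParams, run_hier
from .subjects_io import NoiseModel, generate_subject
from .taskgen import (ExperimentDesign, GenerativeConfig, SelectionConfig,
                      assemble_experiment)

__all__ = ["DesignPool", "prepare_design_pool", "draw_cohort",
           "cohort_contrast", "model_level_contrast"]

SOURCES = ("hier", "flat", "hier_uncoupled")


@dataclass
class DesignPool:
    """Selected experiments with precomputed observer traces.

    ``traces[i]`` maps an observer name ('hier' = coupled hierarchical,
    'flat', 'hier_uncoupled') to its trace on design i.
    """

    designs: list
    traces: list
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.designs)


def prepare_design_pool(n_designs: int, seed: int,
                        cfg: Optional[GenerativeConfig] = None,
                        selection: Optional[SelectionConfig] = None,
                        pc: float = 1.0 / 75.0,
                        omega: float = 20.0,
                        grid_n: int = 50) -> DesignPool:
    """Assemble ``n_designs`` experiments and run all three observers.

    Each design gets its own derived seed, so the pool is reproducible
    from (``seed``, ``n_designs``) alone.
    """
    cfg = cfg or GenerativeConfig()
    classify_params = HierParams(pc=pc, grid_n=grid_n, coupling="coupled")
    designs, traces = [], []
    for k in range(n_designs):
        design = assemble_experiment(cfg, seed=seed * 10_000 + k,
                                     hier_params=classify_params,
                                     selection=selection)
        seq = design.sequence
        traces.append({
            "hier": run_hier(seq, classify_params),
            "hier_uncoupled": run_hier(
                seq, HierParams(pc=pc, grid_n=grid_n,
                                coupling="uncoupled")),
            "flat": run_flat(
                seq, FlatParams(omega=omega, prior_counts=1.0)),
        })
        designs.append(design)
    return DesignPool(designs, traces,
                      meta={"seed": seed, "pc": pc, "omega": omega,
                            "grid_n": grid_n, "coupled": cfg.coupled})


def draw_cohort(pool: DesignPool, source: str, n_subjects: int,
                noise: NoiseModel, rng: np.random.Generator):
    """Simulate one cohort, assigning each subject a design from the pool
    (a random subset without replacement when the pool is large enough,
    as each participant saw their own selected sequences).

    Returns (subjects, effects): per-subject records and per-subject
    pre/post streak-effect tables.
    """
    if source not in SOURCES:
        raise ValueError(f"source must be one of {SOURCES}")
    if len(pool) >= n_subjects:
        assignment = rng.permutation(len(pool))[:n_subjects]
    else:
        assignment = np.arange(n_subjects) % len(pool)
    subjects, effects = [], []
    for i in range(n_subjects):
        k = int(assignment[i])
        design = pool.designs[k]
        trace = pool.traces[k][source]
        subj = generate_subject(trace, design, noise, rng,
                                modality_first=i % 2)
        subjects.append(subj)
        effects.append(pre_post_change(subj.prob_report, subj.conf_report,
                                       design))
    return subjects, effects


def cohort_contrast(pool: DesignPool, source: str, n_subjects: int,
                    noise: NoiseModel, rng: np.random.Generator) -> dict:
    """Streak-type contrast of one simulated cohort, on confidence and on
    probability reports."""
    _, effects = draw_cohort(pool, source, n_subjects, noise, rng)
    return {
        "conf": streak_type_contrast(effects, on="d_conf"),
        "prob": streak_type_contrast(effects, on="d_prob"),
    }


def model_level_contrast(pool: DesignPool, source: str) -> dict:
    """The contrast computed directly on the observer traces (one 'exact'
    subject per design, no report noise)."""
    effects = [pre_post_change(tr[source].p_next[:, 0], tr[source].conf, d)
               for d, tr in zip(pool.designs, pool.traces)]
    return {
        "conf": streak_type_contrast(effects, on="d_conf"),
        "prob": streak_type_contrast(effects, on="d_prob"),
    }
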