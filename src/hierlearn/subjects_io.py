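"""Synthetic subjects and I/O in the deposited trial-matrix layout.

A subject is a per-trial matrix with nine columns: sensory modality,
block number (1-4), the observed stimulus (1/2), the generative cross
transition probabilities p(1|2) and p(2|1), the probability and confidence
reports (NaN outside question trials), and the two reaction times.
Cohorts are stored as three cell variables in a MATLAB container (subjects
included in the main task, excluded from the main task, and the control
cohort), or as one plain CSV per subject with the same column semantics.

Synthetic subjects are generated from an observer trace: the probability
report is a noisy, clipped mapping of the predictive probability and the
confidence report a noisy, clipped affine mapping of the model's
log-precision onto the unit slider.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import io as sio

from .taskgen import ExperimentDesign, StimulusSequence
from .trace import ObserverTrace

__all__ = ["SubjectRecord", "NoiseModel", "generate_subject",
           "read_dataset", "write_dataset",
           "read_subject_csv", "write_subject_csv"]

COLUMNS = ["modality", "block", "stimulus", "gen_p_1_after_2",
           "gen_p_2_after_1", "prob_report", "conf_report",
           "rt_prob", "rt_conf"]


class DatasetFormatError(ValueError):
    """Trial matrix does not follow the 9-column layout."""


@dataclass
class SubjectRecord:
    """One subject's trial matrix, split into named per-trial columns.

    ``block`` is 1-based as in the stored layout.  The generative columns
    hold the *cross* transition probabilities p(1|2) and p(2|1); the
    internal repetition convention is recovered as p(1|1) = 1 - p(2|1)
    and p(2|2) = 1 - p(1|2).
    """

    modality: np.ndarray
    block: np.ndarray
    stimulus: np.ndarray
    gen_p_1_after_2: np.ndarray
    gen_p_2_after_1: np.ndarray
    prob_report: np.ndarray
    conf_report: np.ndarray
    rt_prob: np.ndarray
    rt_conf: np.ndarray

    def __len__(self) -> int:
        return len(self.stimulus)

    @property
    def question_trials(self) -> np.ndarray:
        return np.flatnonzero(np.isfinite(self.prob_report))

    def to_sequence(self) -> StimulusSequence:
        """Rebuild the StimulusSequence (internal repetition convention)."""
        theta = np.column_stack([1.0 - self.gen_p_2_after_1,
                                 1.0 - self.gen_p_1_after_2])
        change = np.zeros_like(theta, dtype=bool)
        change[1:] = theta[1:] != theta[:-1]
        block0 = self.block.astype(int) - 1
        change[np.flatnonzero(np.diff(block0)) + 1] = False
        return StimulusSequence(stimuli=self.stimulus.astype(int),
                                theta=theta, change_points=change,
                                block_id=block0)

    def to_matrix(self) -> np.ndarray:
        return np.column_stack([getattr(self, c).astype(float)
                                for c in COLUMNS])

    @classmethod
    def from_matrix(cls, mat: np.ndarray) -> "SubjectRecord":
        mat = np.atleast_2d(np.asarray(mat, dtype=float))
        if mat.ndim != 2 or mat.shape[1] != len(COLUMNS):
            raise DatasetFormatError(
                f"expected {len(COLUMNS)} columns, got {mat.shape}")
        stim = mat[:, 2]
        if len(stim) and not np.all(np.isin(stim, (1.0, 2.0))):
            raise DatasetFormatError(
                "column 3 (stimulus) must be coded 1/2")
        kwargs = {c: mat[:, j].copy() for j, c in enumerate(COLUMNS)}
        kwargs["block"] = kwargs["block"].astype(int)
        kwargs["stimulus"] = kwargs["stimulus"].astype(int)
        return cls(**kwargs)


@dataclass
class NoiseModel:
    """Report-generation model mapping observer outputs to slider reports.

    The probability report compresses the predictive probability toward
    0.5 with slope ``prob_slope`` and adds Gaussian noise ``prob_sd``; the
    confidence report is an affine map of log-precision
    (``conf_intercept`` + ``conf_slope`` * conf) plus noise ``conf_sd``.
    Both are clipped to the unit slider.  Defaults are calibrated so that
    a default synthetic cohort reproduces the group-level statistics
    humans show on this task: probability reports regress on the optimal
    estimates with slope near 0.66 and Pearson rho near 0.55, and the
    confidence slider carries the streak-type effect with a magnitude
    near 0.10 and between-subject s.e.m. near 0.03.  This is a
    calibration of report reliability, not a claim about the subjects'
    true report-generating process.
    """

    prob_sd: float = 0.2
    prob_slope: float = 0.7
    conf_slope: float = 0.21
    conf_intercept: float = -0.3
    conf_sd: float = 0.10

    def __post_init__(self) -> None:
        if self.prob_sd < 0 or self.conf_sd < 0:
            raise ValueError("noise s.d. must be non-negative")


def generate_subject(trace: ObserverTrace, design: ExperimentDesign,
                     noise: NoiseModel, rng: np.random.Generator,
                     modality_first: int = 0) -> SubjectRecord:
    """Simulate one subject's reports from an observer trace.

    Reports appear exactly at the design's question trials; everything
    else is NaN, including reaction times (not modeled).
    """
    seq = design.sequence
    T = len(seq)
    if len(trace) != T:
        raise ValueError("trace and design are misaligned")
    q = design.question_index
    prob = np.full(T, np.nan)
    conf = np.full(T, np.nan)
    p = trace.p_next[q, 0]
    raw_p = 0.5 + noise.prob_slope * (p - 0.5) \
        + noise.prob_sd * rng.standard_normal(q.size)
    prob[q] = np.clip(raw_p, 0.0, 1.0)
    raw_c = noise.conf_intercept + noise.conf_slope * trace.conf[q] \
        + noise.conf_sd * rng.standard_normal(q.size)
    conf[q] = np.clip(raw_c, 0.0, 1.0)
    block1 = seq.block_id + 1
    modality = ((seq.block_id + modality_first) % 2).astype(float)
    return SubjectRecord(
        modality=modality,
        block=block1.astype(int),
        stimulus=seq.stimuli.astype(int),
        gen_p_1_after_2=1.0 - seq.theta[:, 1],
        gen_p_2_after_1=1.0 - seq.theta[:, 0],
        prob_report=prob,
        conf_report=conf,
        rt_prob=np.full(T, np.nan),
        rt_conf=np.full(T, np.nan),
    )


_MAT_KEYS = ("main_included", "main_excluded", "control")


def _as_cell(records: list) -> np.ndarray:
    cell = np.empty(len(records), dtype=object)
    for i, rec in enumerate(records):
        cell[i] = rec.to_matrix()
    return cell


def write_dataset(cohorts: dict, path) -> None:
    """Write three cohorts of SubjectRecord to a .mat container.

    ``cohorts`` maps 'main_included' / 'main_excluded' / 'control' to
    lists of SubjectRecord (missing cohorts are written empty).
    """
    payload = {k: _as_cell(cohorts.get(k, [])) for k in _MAT_KEYS}
    sio.savemat(str(path), payload, long_field_names=True)


def read_dataset(path) -> dict:
    """Read a dataset in the deposited .mat layout.

    Returns the three cohorts as lists of SubjectRecord.  Files written by
    :func:`write_dataset` are recognized by key; otherwise the first three
    cell variables are taken, in order, as (main included, main excluded,
    control).
    """
    raw = sio.loadmat(str(path), squeeze_me=False)
    data_keys = [k for k in raw if not k.startswith("__")]
    if all(k in raw for k in _MAT_KEYS):
        keys = list(_MAT_KEYS)
    elif len(data_keys) >= 3:
        keys = data_keys[:3]
    else:
        raise DatasetFormatError(
            f"expected 3 cohort variables, found {data_keys}")
    out = {}
    for name, key in zip(_MAT_KEYS, keys):
        cell = np.asarray(raw[key]).ravel()
        out[name] = [SubjectRecord.from_matrix(np.asarray(m)) for m in cell
                     if np.asarray(m).size]
    return out


def write_subject_csv(record: SubjectRecord, path) -> None:
    """One subject as a plain CSV with the 9 documented columns."""
    pd.DataFrame(record.to_matrix(), columns=COLUMNS).to_csv(
        path, index=False)


def read_subject_csv(path) -> SubjectRecord:
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"missing columns: {missing}")
    return SubjectRecord.from_matrix(df[COLUMNS].to_numpy(dtype=float))
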