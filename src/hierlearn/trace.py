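"""Per-trial output of an ideal observer."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ObserverTrace:
    """Trial-by-trial posterior summaries of one observer on one sequence.

    ``p_next[t]`` holds the predictive probabilities of symbols (1, 2) for
    trial t+1, given observations up to trial t.  ``conf[t]`` is the
    log-precision (-ln variance) of the posterior over the *relevant*
    statistic: the repetition probability of the stimulus shown at trial
    t (transition statistics), or the stimulus frequency (frequency
    statistics).  For a change-point observer these are moments of the
    one-step-ahead posterior (the quantity a report is about).
    ``post_mean``/``post_var`` hold the marginal moments of each tracked
    probability: columns [p(1|1), p(2|2)] for transitions, a single
    column [p(1)] for frequencies.
    """

    p_next: np.ndarray
    conf: np.ndarray
    post_mean: np.ndarray
    post_var: np.ndarray
    statistic: str = "transitions"
    extra: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.conf)

    def to_frame(self, seq=None) -> pd.DataFrame:
        """Tidy table, one row per trial."""
        df = pd.DataFrame({
            "trial": np.arange(len(self)),
            "p_next_1": self.p_next[:, 0],
            "conf": self.conf,
        })
        for j in range(self.post_mean.shape[1]):
            df[f"post_mean_{j}"] = self.post_mean[:, j]
            df[f"post_var_{j}"] = self.post_var[:, j]
        for key, val in self.extra.items():
            arr = np.asarray(val)
            if arr.ndim == 1 and len(arr) == len(self):
                df[key] = arr
            elif arr.ndim == 2 and len(arr) == len(self):
                for j in range(arr.shape[1]):
                    df[f"{key}_{j}"] = arr[:, j]
        if seq is not None:
            df.insert(1, "block", seq.block_id)
            df.insert(2, "stimulus", seq.stimuli)
        return df
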