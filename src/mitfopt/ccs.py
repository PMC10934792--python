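"""Correlation-based channel selection (CCS).

Channels engaged by the same task carry shared signal, so a channel's mean
Pearson correlation with all other channels ranks its task relevance.  Per
trial (after per-trial, per-channel z-scoring) the N x N correlation matrix
is computed, channels are ranked by decreasing row mean, and the top ``Ns``
of each of ``Nt`` trials vote; the ``Ns`` most frequent channels win.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io_fixture import EpochSet

__all__ = ["ChannelSelection", "zscore", "pearson_matrix", "rank_channels", "select_channels"]


@dataclass
class ChannelSelection:
    """Result of the voting procedure.

    ``votes[c]`` counts how often channel ``c`` appeared among a trial's
    top-``Ns``; the vote total is ``Nt * Ns``.  ``selected`` holds the
    winning channel indices ordered by decreasing vote count.
    """

    row_means: np.ndarray  # (Nt, N) per-trial mean correlation per channel
    votes: np.ndarray  # (N,) appearance counts
    selected: list  # Ns channel indices
    n_trials_used: int


def zscore(epochs: EpochSet) -> EpochSet:
    """Per-trial, per-channel standardization to mean 0 and SD 1.

    Uses the population SD (ddof=0), the sklearn scaler convention.  A
    zero-variance channel is an error because its correlation with anything
    is undefined.
    """
    mean = epochs.data.mean(axis=-1, keepdims=True)
    sd = epochs.data.std(axis=-1, keepdims=True)
    bad = np.argwhere(sd[:, :, 0] == 0)
    if bad.size:
        tr, ch = bad[0]
        raise ValueError(f"zero-variance channel: trial {tr}, channel {ch} ({epochs.channel_names[ch]})")
    return EpochSet(
        (epochs.data - mean) / sd, epochs.labels, epochs.sfreq, list(epochs.channel_names), epochs.t0
    )


def pearson_matrix(trial: np.ndarray) -> np.ndarray:
    """Sample Pearson correlation matrix of a (channel, sample) trial.

    Uses the 1/(n-1) convention with sample standard deviations, i.e. the
    ordinary sample correlation; symmetric with unit diagonal.
    """
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2 or trial.shape[1] < 2:
        raise ValueError("trial must be (channels, samples) with >= 2 samples")
    if np.any(trial.std(axis=-1) == 0):
        raise ValueError("zero-variance channel in trial")
    R = np.corrcoef(trial)
    # corrcoef can exceed |1| by eps; keep the invariant exact
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    return R


def rank_channels(R: np.ndarray, exclude_diagonal: bool = False) -> np.ndarray:
    """Channel indices ordered by decreasing row mean; ties by ascending index.

    The diagonal (self-correlation 1) is included in the row mean by
    default; it shifts all rows equally so the ranking is unaffected unless
    explicitly excluded.
    """
    R = np.asarray(R, dtype=float)
    n = R.shape[0]
    if exclude_diagonal and n > 1:
        means = (R.sum(axis=1) - np.diag(R)) / (n - 1)
    else:
        means = R.mean(axis=1)
    # lexsort: primary key -means (descending mean), secondary implicit index order
    return np.lexsort((np.arange(n), -means))


def select_channels(
    epochs: EpochSet,
    n_select: Optional[int] = None,
    n_trials: Optional[int] = None,
    exclude_diagonal: bool = False,
) -> ChannelSelection:
    """Vote the ``n_select`` most frequently top-ranked channels over trials.

    Defaults: ``n_select=None`` keeps all channels, ``n_trials=None`` uses
    every available trial.  Vote ties are broken by the channel's mean
    row-mean correlation across the voting trials, then by ascending index.
    """
    N = epochs.n_channels
    Ns = N if n_select is None else int(n_select)
    Nt = epochs.n_trials if n_trials is None else int(n_trials)
    if Ns > N or Ns < 1:
        raise ValueError(f"n_select={Ns} outside [1, {N}]")
    if Nt > epochs.n_trials or Nt < 1:
        raise ValueError(f"n_trials={Nt} outside [1, {epochs.n_trials}]")

    z = zscore(epochs)
    row_means = np.empty((Nt, N))
    votes = np.zeros(N, dtype=int)
    for tr in range(Nt):
        R = pearson_matrix(z.data[tr])
        if exclude_diagonal and N > 1:
            row_means[tr] = (R.sum(axis=1) - np.diag(R)) / (N - 1)
        else:
            row_means[tr] = R.mean(axis=1)
        top = rank_channels(R, exclude_diagonal=exclude_diagonal)[:Ns]
        votes[top] += 1

    mean_row_means = row_means.mean(axis=0)
    order = np.lexsort((np.arange(N), -mean_row_means, -votes))
    selected = [int(c) for c in order[:Ns]]
    return ChannelSelection(row_means=row_means, votes=votes, selected=selected, n_trials_used=Nt)
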