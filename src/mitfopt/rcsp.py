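"""Regularized common spatial patterns (RCSP).

CSP finds spatial filters w maximizing the variance ratio
w' C1 w / w' C2 w between two classes, via the generalized eigenproblem
Q1 w = lambda Q2 w.  RCSP regularizes the class covariances twice:

- ``alpha`` blends two per-trial covariance estimators — the normalized
  covariance ``E E' / trace(E E')`` (scale-free, no mean removal) and the
  ordinary sample covariance (mean-removed, 1/(n-1)) — averaged over the
  class's trials:  P = [(1-alpha) * sum C_i + alpha * sum Chat_i] / Ntr.
- ``beta`` shrinks toward a scaled identity:
  Q = (1-beta) * P + beta * (trace(P)/Nch) * I,
  which preserves the trace and guarantees positive definiteness for
  beta > 0.

The filter bank keeps the eigenvectors of the m largest and m smallest
generalized eigenvalues (columns ordered by descending eigenvalue, largest
m first).  Features are the log variance of each spatially filtered trial.
Defaults m=2, alpha=0.4, beta=0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .io_fixture import EpochSet

__all__ = [
    "RCSPModel",
    "normalized_covariance",
    "pairwise_covariance",
    "average_covariance",
    "regularize_covariance",
    "fit",
    "transform",
]

RESIDUAL_RTOL = 1e-8


@dataclass
class RCSPModel:
    """Fitted spatial filter bank with its regularized class covariances.

    ``classes_[0]`` (the smaller label) maps to Q1, so the first m filter
    columns maximize that class's variance ratio.  Eigenvectors are scaled
    to w' Q2 w = 1 with first non-negligible component positive, making
    fitted models byte-reproducible.
    """

    Q1: np.ndarray
    Q2: np.ndarray
    omega2m: np.ndarray  # (Nch, 2m)
    eigenvalues: np.ndarray  # (2m,)
    m: int
    alpha: float
    beta: float
    classes_: tuple
    channel_names: list


def normalized_covariance(trial: np.ndarray) -> np.ndarray:
    """Trace-normalized scatter matrix ``E E' / trace(E E')`` (no mean removal)."""
    E = np.asarray(trial, dtype=float)
    if E.ndim != 2:
        raise ValueError("trial must be a (channels, samples) matrix")
    S = E @ E.T
    tr = np.trace(S)
    if tr <= 0:
        raise ValueError("zero-energy trial: trace(E E') is not positive")
    return S / tr


def pairwise_covariance(trial: np.ndarray) -> np.ndarray:
    """Sample covariance across channels, mean removed, 1/(n-1) convention."""
    E = np.asarray(trial, dtype=float)
    if E.ndim != 2 or E.shape[1] < 2:
        raise ValueError("trial must be (channels, samples) with >= 2 samples")
    return np.cov(E, ddof=1)


def average_covariance(trials: np.ndarray, alpha: float) -> np.ndarray:
    """Blend of summed normalized and pairwise covariances over a class.

    ``P = [(1-alpha) * sum_i C_i + alpha * sum_i Chat_i] / Ntr`` for the
    class's ``Ntr`` trials.
    """
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 3 or trials.shape[0] == 0:
        raise ValueError("trials must be a non-empty (trial, channel, sample) array")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    ntr = trials.shape[0]
    nch = trials.shape[1]
    acc = np.zeros((nch, nch))
    for E in trials:
        acc += (1.0 - alpha) * normalized_covariance(E)
        acc += alpha * pairwise_covariance(E)
    return acc / ntr


def regularize_covariance(P: np.ndarray, beta: float, n_channels: int) -> np.ndarray:
    """Shrink toward the scaled identity: ``(1-beta) P + beta (tr P / Nch) I``."""
    P = np.asarray(P, dtype=float)
    if not (0.0 <= beta <= 1.0):
        raise ValueError("beta must be in [0, 1]")
    return (1.0 - beta) * P + beta * (np.trace(P) / n_channels) * np.eye(n_channels)


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Make each column's first non-negligible component positive."""
    V = V.copy()
    for j in range(V.shape[1]):
        col = V[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12 * max(np.abs(col).max(), 1e-300))[0]
        if nz.size and col[nz[0]] < 0:
            V[:, j] = -col
    return V


def fit(epochs: EpochSet, m: int = 2, alpha: float = 0.4, beta: float = 0.01) -> RCSPModel:
    """Fit the 2m-filter RCSP bank on a two-class epoch set.

    Solves ``Q1 w = lambda Q2 w`` with Q1 from the smaller label's trials.
    Every returned eigenpair is verified by its residual
    ``||Q1 w - lambda Q2 w|| <= 1e-8 ||Q1 w||`` rather than trusted from
    the solver.
    """
    epochs.validate(require_two_classes=True)
    nch = epochs.n_channels
    if 2 * m > nch:
        raise ValueError(f"2m = {2 * m} filters exceed {nch} channels")

    classes = tuple(sorted(np.unique(epochs.labels).tolist()))
    covs = []
    for cls in classes:
        trials = epochs.data[epochs.labels == cls]
        P = average_covariance(trials, alpha)
        covs.append(regularize_covariance(P, beta, nch))
    Q1, Q2 = covs

    try:
        w, V = linalg.eigh(Q1, Q2)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "generalized eigenproblem failed: Q2 is numerically singular "
            "(possible at beta=0); set beta > 0 to shrink toward the identity"
        ) from exc

    order = np.argsort(w)[::-1]  # descending eigenvalue
    keep = np.concatenate([order[:m], order[-m:]])
    eigvals = w[keep]
    omega = V[:, keep]
    # eigh normalizes V' Q2 V = I already; enforce explicitly for robustness
    scale = np.sqrt(np.einsum("ij,jk,ki->i", omega.T, Q2, omega))
    omega = omega / scale
    omega = _fix_signs(omega)

    resid = Q1 @ omega - Q2 @ omega * eigvals
    lhs = Q1 @ omega
    for j in range(omega.shape[1]):
        if np.linalg.norm(resid[:, j]) > RESIDUAL_RTOL * np.linalg.norm(lhs[:, j]):
            raise np.linalg.LinAlgError(
                f"generalized eigenpair {j} failed the residual check; "
                "covariances may be ill-conditioned — increase beta"
            )

    return RCSPModel(
        Q1=Q1,
        Q2=Q2,
        omega2m=omega,
        eigenvalues=eigvals,
        m=m,
        alpha=alpha,
        beta=beta,
        classes_=classes,
        channel_names=list(epochs.channel_names),
    )


def transform(model: RCSPModel, epochs: EpochSet) -> np.ndarray:
    """Log-variance features: ``f = ln var(omega2m' E)`` per trial.

    Sample variance over the time axis (mean removed, 1/(n-1)); no
    normalization by the summed variances.  Returns (n_trials, 2m).
    """
    if epochs.n_channels != model.omega2m.shape[0]:
        raise ValueError(
            f"channel count {epochs.n_channels} does not match the fitted model "
            f"({model.omega2m.shape[0]})"
        )
    projected = np.einsum("cf,tcs->tfs", model.omega2m, epochs.data)
    variances = projected.var(axis=-1, ddof=1)
    if np.any(variances <= 0):
        t, f = np.argwhere(variances <= 0)[0]
        raise ValueError(f"degenerate trial {t}: zero variance under filter {f}")
    return np.log(variances)
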