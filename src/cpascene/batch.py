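"""Batch corrected-projections estimation.

Given T observations s(t) and a dictionary {b_i}, the corrected-projections
estimate of the signal is

    s_hat(t) = sum_i c_i * p_i(t) * b_i,      p_i(t) = s(t) . b_i,

i.e. each element's contribution is gated by its instantaneous similarity
p_i(t) to the observation.  The presence parameters c (one per element,
constant over the scene) are found by least squares over all T observations.
Because of the similarity gating this minimization has a unique solution
without any sparseness penalty, and for orthogonal present sources the
solution is exactly 1 for present and 0 for absent elements.

The normal equations have a compact form: with P the (T, n) projection matrix
and G the dictionary Gram matrix,

    [ (P' P) o G ] c = sum_t p(t)^2        (o = elementwise product),

an n-by-n system, which is what this module solves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .dictionary import Dictionary, gram_matrix
from .scenes import AuditoryScene

__all__ = [
    "ProjectionSet",
    "PresenceEstimate",
    "projections",
    "cpa_signal_estimate",
    "fit_cpa",
    "template_match_rms",
    "rank_detect",
    "write_presence",
    "read_presence",
]


@dataclass(frozen=True)
class ProjectionSet:
    """Similarities p_i(t) = s(t) . b_i, shape (T, n)."""

    values: np.ndarray

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class PresenceEstimate:
    """Fitted presence parameters with least-squares diagnostics."""

    c: np.ndarray
    residual_sse: float
    condition_estimate: float
    ridge: float
    rank_deficient: bool = False


def _obs_matrix(scene) -> np.ndarray:
    if isinstance(scene, AuditoryScene):
        return scene.observations
    return np.atleast_2d(np.asarray(scene, dtype=float))


def projections(scene: AuditoryScene | np.ndarray, d: Dictionary) -> ProjectionSet:
    """Project every observation onto every dictionary element."""
    obs = _obs_matrix(scene)
    if obs.shape[1] != d.f:
        raise ValueError("feature-count mismatch between scene and dictionary")
    return ProjectionSet(obs @ d.matrix.T)


def cpa_signal_estimate(c: np.ndarray, p: np.ndarray, d: Dictionary) -> np.ndarray:
    """Reconstruction s_hat = sum_i c_i p_i b_i for one time step."""
    c = np.asarray(c, dtype=float)
    p = np.asarray(p, dtype=float)
    if c.shape != (d.n,) or p.shape != (d.n,):
        raise ValueError("c and p must both have one entry per dictionary element")
    return (c * p) @ d.matrix


def default_ridge(n: int, f: int, T: int) -> float:
    """0 when the data can determine all n parameters, else a small ridge.

    The n-by-n normal matrix has rank at most f*T, so with n > f*T the plain
    least-squares problem is singular and a small Tikhonov term (1e-8) keeps
    the solve well-posed.
    """
    return 0.0 if n <= f * T else 1e-8


_STACKED_BUDGET = 20_000_000  # max T*f*n entries for the SVD path


def fit_cpa(
    scene: AuditoryScene | np.ndarray,
    d: Dictionary,
    ridge: float | None = None,
) -> PresenceEstimate:
    """Least-squares presence parameters over all observations of a scene.

    Minimizes  sum_t || s(t) - sum_i c_i p_i(t) b_i ||^2 + ridge * ||c||^2.
    With ridge=0 this is the unique corrected-projections solution whenever
    the stacked design has full column rank; a rank-deficient design yields
    the minimum-norm solution and is flagged ``rank_deficient``.

    The unregularized problem is solved on the stacked (T*f, n) design by
    SVD, which stays accurate when the squared (normal-equation) system is
    numerically singular -- a real hazard for small f, where projections of
    a few sources span a low-dimensional subspace.  The ridge>0 and
    very-large-problem paths use the compact n-by-n normal equations.
    """
    obs = _obs_matrix(scene)
    P = projections(obs, d).values
    T, n = P.shape
    if ridge is None:
        ridge = default_ridge(n, d.f, T)
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")

    rank_deficient = False
    if ridge == 0 and T * d.f * n <= _STACKED_BUDGET:
        # stacked design: rows are (t, feature) pairs, column i is p_i(t) b_i
        M = (P[:, np.newaxis, :] * d.matrix.T[np.newaxis, :, :]).reshape(T * d.f, n)
        c, _, rank, sv = np.linalg.lstsq(M, obs.ravel(), rcond=None)
        rank_deficient = rank < n
        cond = float((sv[0] / sv[rank - 1]) ** 2) if rank > 0 else np.inf
        if rank_deficient:
            cond = np.inf
    else:
        G = gram_matrix(d)
        A = (P.T @ P) * G
        if ridge:
            A[np.diag_indices_from(A)] += ridge
        rhs = np.sum(P**2, axis=0)
        cond = float(np.linalg.cond(A))
        try:
            c = scipy.linalg.solve(A, rhs, assume_a="pos")
            if not np.all(np.isfinite(c)):
                raise np.linalg.LinAlgError
        except (np.linalg.LinAlgError, scipy.linalg.LinAlgError, ValueError):
            c = np.linalg.pinv(A) @ rhs
            rank_deficient = True
    resid = obs - (P * c) @ d.matrix
    sse = float(np.sum(resid**2))
    return PresenceEstimate(c, sse, cond, float(ridge), rank_deficient)


def template_match_rms(p: ProjectionSet) -> np.ndarray:
    """Template-matching score: root-mean-square similarity over time, per element."""
    return np.sqrt(np.mean(p.values**2, axis=0))


def rank_detect(scores: Sequence[float] | np.ndarray, m: int) -> np.ndarray:
    """Indices of the m largest scores; ties broken toward the lower index."""
    scores = np.asarray(scores, dtype=float)
    if m > scores.size:
        raise ValueError("m cannot exceed the number of scores")
    return np.argsort(-scores, kind="stable")[:m]


def write_presence(est: PresenceEstimate, labels: Sequence[str], path) -> None:
    """Two-column delimited text (label, c), sorted by descending c."""
    df = pd.DataFrame({"label": list(labels), "c": est.c})
    df.sort_values("c", ascending=False, kind="stable").to_csv(path, sep="\t", index=False)


def read_presence(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
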