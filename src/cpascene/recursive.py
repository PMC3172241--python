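"""Iterative corrected-projections estimation (recursive least squares).

Instead of storing all T observations, the iterative estimator keeps a running
presence-parameter vector c and an n-by-n uncertainty matrix P and absorbs one
observation per step.  With the observation s arranged into the f-by-n matrix

    B,  column i = p_i * b_i,   p_i = s . b_i,

one step performs the standard recursive-least-squares measurement update with
unit observation-noise covariance:

    s_hat  = B c
    e      = s - s_hat
    K      = P B' (I_f + B P B')^-1        (gain, n x f)
    delta_c = K e
    c     <- c + delta_c
    P     <- P - K B P

Only an f-by-f system is solved per step, so the recursion is numerically
well-behaved even when n >> f.  After T steps the estimate equals the
regularized batch solution

    argmin_c  sum_t ||s(t) - B(t) c||^2 + (c - c0)' P0^-1 (c - c0),

which for a diffuse prior (large P0) recovers the batch corrected-projections
fit.  ``batch_equivalent_fit`` computes that solution densely and
``large_n_fit`` computes it matrix-free (preconditioned conjugate gradients)
for dictionaries far too large to materialize P or the Gram matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.sparse.linalg import LinearOperator, cg

from .batch import PresenceEstimate
from .dictionary import Dictionary
from .scenes import AuditoryScene

__all__ = [
    "StepDiagnostics",
    "EstimatorState",
    "init_state",
    "projection_matrix",
    "update",
    "run_icpa",
    "batch_equivalent_fit",
    "large_n_fit",
    "export_trajectory",
]


@dataclass(frozen=True)
class StepDiagnostics:
    """Intermediate quantities of the most recent update."""

    B: np.ndarray  # (f, n) similarity-weighted dictionary
    s_hat: np.ndarray  # (f,) signal estimate
    e: np.ndarray  # (f,) estimation error
    K: np.ndarray  # (n, f) gain / uncertainty-weighted sensitivity
    delta_c: np.ndarray  # (n,) presence-parameter correction


@dataclass(frozen=True)
class EstimatorState:
    """Presence parameters c, uncertainty matrix P, and step counter."""

    c: np.ndarray
    P: np.ndarray
    step: int = 0
    diagnostics: StepDiagnostics | None = None

    @property
    def n(self) -> int:
        return self.c.shape[0]


def init_state(
    n: int,
    c0: float | Sequence[float] | np.ndarray = 0.0,
    p0_diag: float = 1.0,
) -> EstimatorState:
    """Initial state: c = c0 (scalar fill or vector), P = p0_diag * I."""
    if p0_diag <= 0:
        raise ValueError("uncertainty must be positive")
    c = np.asarray(c0, dtype=float)
    if c.ndim == 0:
        c = np.full(n, float(c))
    elif c.shape != (n,):
        raise ValueError("c0 must be scalar or a length-n vector")
    return EstimatorState(c.copy(), p0_diag * np.eye(n), 0, None)


def projection_matrix(s: np.ndarray, d: Dictionary) -> np.ndarray:
    """f-by-n matrix whose column i is the projection of s onto b_i, times b_i."""
    s = np.asarray(s, dtype=float)
    if s.shape != (d.f,):
        raise ValueError("feature-count mismatch between observation and dictionary")
    p = d.matrix @ s
    return d.matrix.T * p


def update(state: EstimatorState, s: np.ndarray, d: Dictionary) -> EstimatorState:
    """Absorb one observation; returns the new state with full diagnostics."""
    s = np.asarray(s, dtype=float)
    if s.shape != (d.f,):
        raise ValueError("feature-count mismatch between observation and dictionary")
    if not np.all(np.isfinite(s)):
        raise ValueError("invalid observation: non-finite values")
    if state.c.shape[0] != d.n:
        raise ValueError("state size does not match dictionary")

    B = projection_matrix(s, d)
    s_hat = B @ state.c
    e = s - s_hat
    PBt = state.P @ B.T  # (n, f)
    S = B @ PBt
    S[np.diag_indices_from(S)] += 1.0  # I_f + B P B'
    cf = scipy.linalg.cho_factor(S, lower=True, check_finite=False)
    K = scipy.linalg.cho_solve(cf, PBt.T, check_finite=False).T  # (n, f)
    delta_c = K @ e
    c_new = state.c + delta_c
    P_new = state.P - K @ PBt.T
    P_new = 0.5 * (P_new + P_new.T)  # guard symmetry against FP drift
    diag = StepDiagnostics(B=B, s_hat=s_hat, e=e, K=K, delta_c=delta_c)
    return EstimatorState(c_new, P_new, state.step + 1, diag)


def run_icpa(
    scene: AuditoryScene | np.ndarray,
    d: Dictionary,
    init: EstimatorState | None = None,
    keep: str = "all",
) -> list[EstimatorState]:
    """Sequentially absorb all rows of a scene.

    ``keep="all"`` returns one state per observation (post-update, with
    diagnostics); ``keep="last"`` returns only the final state, which avoids
    holding T copies of P for long scenes.
    """
    obs = scene.observations if isinstance(scene, AuditoryScene) else np.atleast_2d(scene)
    if keep not in ("all", "last"):
        raise ValueError("keep must be 'all' or 'last'")
    state = init if init is not None else init_state(d.n)
    out: list[EstimatorState] = []
    for s in obs:
        state = update(state, s, d)
        if keep == "all":
            out.append(state)
    return out if keep == "all" else [state]


def _ridge_system_parts(scene, d: Dictionary):
    obs = scene.observations if isinstance(scene, AuditoryScene) else np.atleast_2d(scene)
    if obs.shape[1] != d.f:
        raise ValueError("feature-count mismatch between scene and dictionary")
    Pm = obs @ d.matrix.T  # (T, n) projections
    return obs, Pm


def batch_equivalent_fit(
    scene: AuditoryScene | np.ndarray,
    d: Dictionary,
    p0_diag: float = 1.0,
    c0: float | np.ndarray = 0.0,
) -> PresenceEstimate:
    """Dense closed form of the iterative estimate after all observations.

    Solves [(P'P) o G + (1/p0) I] c = sum_t p(t)^2 + c0 / p0, which equals the
    final c of ``run_icpa`` started from (c0, p0_diag * I).  Practical for
    moderate n where the n-by-n system fits in memory.
    """
    if p0_diag <= 0:
        raise ValueError("uncertainty must be positive")
    obs, Pm = _ridge_system_parts(scene, d)
    n = d.n
    c0v = np.full(n, float(c0)) if np.ndim(c0) == 0 else np.asarray(c0, dtype=float)
    G = d.matrix @ d.matrix.T
    A = (Pm.T @ Pm) * G
    A[np.diag_indices_from(A)] += 1.0 / p0_diag
    rhs = np.sum(Pm**2, axis=0) + c0v / p0_diag
    c = scipy.linalg.solve(A, rhs, assume_a="pos")
    resid = obs - (Pm * c) @ d.matrix
    cond = float(np.linalg.cond(A)) if n <= 2000 else float(A.diagonal().max() / A.diagonal().min())
    return PresenceEstimate(c, float(np.sum(resid**2)), cond, 1.0 / p0_diag)


def large_n_fit(
    scene: AuditoryScene | np.ndarray,
    d: Dictionary,
    p0_diag: float = 1.0,
    c0: float | np.ndarray = 0.0,
    rtol: float = 1e-10,
    maxiter: int = 2000,
) -> PresenceEstimate:
    """Matrix-free equivalent of the iterative estimate for very large n.

    The normal operator  v -> sum_t p(t) o G (p(t) o v) + v / p0  is applied
    through dictionary-matrix products only (never forming G or P), and the
    system is solved by Jacobi-preconditioned conjugate gradients.  Matches
    ``run_icpa``'s final c on instances small enough to run both.
    """
    if p0_diag <= 0:
        raise ValueError("uncertainty must be positive")
    obs, Pm = _ridge_system_parts(scene, d)
    n = d.n
    Bm = d.matrix  # (n, f)
    inv_p0 = 1.0 / p0_diag
    c0v = np.full(n, float(c0)) if np.ndim(c0) == 0 else np.asarray(c0, dtype=float)

    def matvec(v: np.ndarray) -> np.ndarray:
        W = Pm * v  # (T, n): p(t) o v per row
        Y = W @ Bm  # (T, f): sum_i p_i v_i b_i per row
        Z = Y @ Bm.T  # (T, n): projections of those back onto the dictionary
        return np.einsum("ti,ti->i", Pm, Z) + inv_p0 * v

    A = LinearOperator((n, n), matvec=matvec, dtype=float)
    diag = np.sum(Pm**2, axis=0) + inv_p0  # exact diagonal (G_ii = 1)
    M = LinearOperator((n, n), matvec=lambda v: v / diag, dtype=float)
    rhs = np.sum(Pm**2, axis=0) + inv_p0 * c0v
    c, info = cg(A, rhs, rtol=rtol, atol=0.0, maxiter=maxiter, M=M)
    if info != 0:
        res = float(np.linalg.norm(matvec(c) - rhs) / np.linalg.norm(rhs))
        raise RuntimeError(f"did not converge after {maxiter} CG iterations; relative residual {res:.3e}")
    resid = obs - (Pm * c) @ Bm
    cond_proxy = float(diag.max() / diag.min())
    return PresenceEstimate(c, float(np.sum(resid**2)), cond_proxy, inv_p0)


def export_trajectory(
    trajectory: Sequence[EstimatorState],
    labels: Sequence[str],
    path,
    top_k: int = 5,
) -> None:
    """Per-step delimited-text records: step (1-based), ||e||, top-k c values."""
    rows = []
    for st in trajectory:
        if st.diagnostics is None:
            raise ValueError("trajectory lacks diagnostics")
        order = np.argsort(-st.c, kind="stable")[:top_k]
        row = {"step": st.step, "error_norm": float(np.linalg.norm(st.diagnostics.e))}
        for r, i in enumerate(order, start=1):
            row[f"top{r}_label"] = labels[i]
            row[f"top{r}_c"] = float(st.c[i])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
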