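"""PCA identification baseline and the observation-efficiency comparison.

PCA identifies candidate sources from the observations alone (leading
principal components matched to their nearest dictionary elements by absolute
cosine similarity); the iterative corrected-projections estimator uses the
dictionary as prior information and therefore needs far fewer observations to
reach the same identification performance.  ``efficiency_experiment`` runs
that comparison: ten lognormally modulated sources from a 1000-element
dictionary of 500-feature vectors, Gaussian noise, performance = fraction of
the ten true generators among each method's top ten.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from ._util import derive_seed
from .dictionary import Dictionary, make_random_dictionary
from .scenes import generate_scene

__all__ = [
    "PerformanceCurve",
    "pca_identify",
    "identification_performance",
    "efficiency_experiment",
    "default_grid",
    "write_curve",
]


@dataclass(frozen=True)
class PerformanceCurve:
    """Mean +/- SD identification performance per observation count and method."""

    observation_counts: tuple[int, ...]
    mean_performance: dict  # method -> array over counts, values in [0, 1]
    sd_performance: dict
    replicates: int

    def minimal_observations(self, method: str, threshold: float = 0.8) -> int | None:
        """Smallest observation count whose mean performance reaches the threshold."""
        means = self.mean_performance[method]
        for T, m in zip(self.observation_counts, means):
            if m >= threshold:
                return int(T)
        return None


def pca_identify(
    observations: np.ndarray,
    d: Dictionary,
    m: int = 10,
    center: bool = False,
) -> np.ndarray:
    """Match the m leading principal components to their closest elements.

    Components are computed from the (by default uncentered) observations via
    SVD; each is matched to the dictionary element with the largest absolute
    cosine similarity (principal-component signs are arbitrary).  The returned
    index list may contain duplicates; a duplicated match can still contribute
    only one true element to the performance score.
    """
    obs = np.asarray(observations, dtype=float)
    if obs.ndim != 2:
        raise ValueError("observations must be a (T, f) matrix")
    if obs.shape[0] < m:
        raise ValueError("insufficient observations: T < m")
    if center:
        obs = obs - obs.mean(axis=0)
    _, _, Vt = scipy.linalg.svd(obs, full_matrices=False)
    comps = Vt[:m]  # unit-norm rows
    sims = np.abs(comps @ d.matrix.T)  # |cosine|: elements are unit-norm too
    return np.argmax(sims, axis=1)


def identification_performance(selected, truth) -> float:
    """Fraction of the true generating elements among the selected indices."""
    truth = set(int(i) for i in truth)
    if not truth:
        raise ValueError("truth set is empty")
    return len(set(int(i) for i in selected) & truth) / len(truth)


def default_grid() -> tuple[int, ...]:
    """Observation counts: unit steps where the estimator converges, coarser later."""
    return tuple(list(range(1, 16)) + list(range(16, 41, 2)) + list(range(44, 97, 4)))


def efficiency_experiment(
    T_grid=None,
    replicates: int = 30,
    seed: int = 0,
    n: int = 1000,
    f: int = 500,
    n_sources: int = 10,
    log_sd: float = 2.0,
    noise_sd: float = 0.5,
    p0_diag: float = 1.0,
) -> PerformanceCurve:
    """Identification performance vs observation count, iCPA against PCA.

    Per replicate: a fresh uniform-[0,1) dictionary, ``n_sources`` elements
    chosen at random, lognormal (log-sd ``log_sd``) amplitudes uncorrelated
    across sources and time, additive Gaussian noise.  For each T in the grid
    both methods score the fraction of true generators among their top
    ``n_sources`` candidates.  The iterative estimate (c0 = 0, P0 = I) is
    evaluated through its batch-equivalent closed form, which is exactly the
    state the recursion reaches after T observations.
    """
    grid = tuple(int(t) for t in (T_grid if T_grid is not None else default_grid()))
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("T_grid must be strictly increasing")
    T_max = grid[-1]
    perf = {"icpa": np.zeros((replicates, len(grid))), "pca": np.zeros((replicates, len(grid)))}
    for r in range(replicates):
        rep_seed = derive_seed(seed, 1000 + r)
        d = make_random_dictionary(n, f, "uniform01", seed=derive_seed(rep_seed, 0))
        rng = np.random.default_rng(derive_seed(rep_seed, 1))
        truth = rng.choice(n, size=n_sources, replace=False)
        scene = generate_scene(
            d, truth, T_max, amplitude_model="lognormal", log_sd=log_sd,
            noise_sd=noise_sd, seed=derive_seed(rep_seed, 2),
        )
        obs = scene.observations
        Pm = obs @ d.matrix.T
        G = d.matrix @ d.matrix.T
        PtP = np.zeros((n, n))
        t_done = 0
        for j, T in enumerate(grid):
            block = Pm[t_done:T]
            PtP += block.T @ block
            t_done = T
            A = PtP * G
            A[np.diag_indices_from(A)] += 1.0 / p0_diag
            rhs = np.sum(Pm[:T] ** 2, axis=0)
            c = scipy.linalg.solve(A, rhs, assume_a="pos")
            top = np.argsort(-c, kind="stable")[:n_sources]
            perf["icpa"][r, j] = identification_performance(top, truth)
            if T >= n_sources:
                sel = pca_identify(obs[:T], d, m=n_sources)
                perf["pca"][r, j] = identification_performance(sel, truth)
    return PerformanceCurve(
        observation_counts=grid,
        mean_performance={k: v.mean(axis=0) for k, v in perf.items()},
        sd_performance={k: v.std(axis=0, ddof=1 if replicates > 1 else 0) for k, v in perf.items()},
        replicates=replicates,
    )


def write_curve(curve: PerformanceCurve, path) -> None:
    """Curve as tab-delimited text: T, method, mean, sd."""
    rows = []
    for method in curve.mean_performance:
        for T, m, s in zip(
            curve.observation_counts,
            curve.mean_performance[method],
            curve.sd_performance[method],
        ):
            rows.append({"T": T, "method": method, "mean": m, "sd": s})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
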