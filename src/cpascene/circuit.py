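"""Mapping estimator internals to predicted cortical activity.

The recursion exposes two per-step quantities with a natural frequency
(feature) preference: the gain K (n-by-f) and the per-feature contributions
K_hi * e_i to the presence-parameter correction delta_c_h = sum_i K_hi e_i.
Reading each matrix entry as the firing rate of one frequency-tuned unit
(absolute values, since rates are nonnegative) yields two predicted response
classes:

* "uncertainty" units, |K_hi| — active even in silence (K reflects accumulated
  uncertainty, not the instantaneous input) and adapting weakly over a pulse
  train;
* "parameter-error" units, |K_hi * e_i| — gated multiplicatively by the
  estimation error e, hence nearly silent in silence and adapting strongly as
  the estimate converges.

The click-train experiment quantifies this with per-unit response metrics
(spontaneous rate, first-pulse response, last/first normalized response) and
Spearman rank correlations across the pooled unit population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from ._util import rng_from
from .dictionary import make_random_dictionary
from .recursive import EstimatorState, init_state, run_icpa
from .scenes import ClickTrain, generate_click_train

__all__ = [
    "CircuitActivity",
    "decompose_activity",
    "response_metrics",
    "spearman_with_ci",
    "click_train_experiment",
    "fit_adaptation",
    "write_unit_table",
]

EVOKED_FLOOR = 1e-12  # units with first-pulse response below this are excluded


@dataclass(frozen=True)
class CircuitActivity:
    """Per-step nonnegative activities of both predicted unit classes.

    ``k_activity[t, h, i]`` = |K_hi| after observation t;
    ``d_activity[t, h, i]`` = |K_hi * e_i|, the per-frequency contribution to
    the presence-parameter correction of element h.
    """

    k_activity: np.ndarray  # (steps, n, f)
    d_activity: np.ndarray  # (steps, n, f)
    pulse_steps: tuple[int, ...]
    lead_steps: tuple[int, ...]


def decompose_activity(
    trajectory: Sequence[EstimatorState],
    pulse_steps: Sequence[int],
    lead_steps: Sequence[int],
) -> CircuitActivity:
    """Extract |K| and |K o e| activities from a diagnostics-bearing trajectory."""
    if any(st.diagnostics is None for st in trajectory):
        raise ValueError("trajectory lacks diagnostics")
    k_act = np.stack([np.abs(st.diagnostics.K) for st in trajectory])
    d_act = np.stack(
        [np.abs(st.diagnostics.K * st.diagnostics.e[np.newaxis, :]) for st in trajectory]
    )
    return CircuitActivity(
        k_act, d_act, tuple(int(p) for p in pulse_steps), tuple(int(s) for s in lead_steps)
    )


def _unit_frame(act: np.ndarray, population: str, pulses, lead) -> pd.DataFrame:
    steps, n, f = act.shape
    spont = act[list(lead)].mean(axis=0).ravel()
    first = act[pulses[0]].ravel()
    last = act[pulses[-1]].ravel()
    h, i = np.unravel_index(np.arange(n * f), (n, f))
    with np.errstate(divide="ignore", invalid="ignore"):
        norm_last = np.where(first >= EVOKED_FLOOR, last / first, np.nan)
    return pd.DataFrame(
        {
            "population": population,
            "element": h,
            "feature": i,
            "spontaneous": spont,
            "evoked_first": first,
            "normalized_last": norm_last,
        }
    )


def response_metrics(act: CircuitActivity) -> pd.DataFrame:
    """Per-unit spontaneous / first-pulse / normalized-last responses.

    One row per unit (population in {"K", "D"}, element h, feature i).
    Spontaneous activity is the mean over the leading-silence steps; the
    evoked response to a pulse is the activity at the update step that
    consumed that pulse observation.  Units whose first-pulse response is
    below ``EVOKED_FLOOR`` get NaN ``normalized_last`` (excluded from
    correlations); their count is stored in ``df.attrs["n_excluded"]``.
    """
    if len(act.pulse_steps) < 2:
        raise ValueError("need at least 2 pulses to quantify adaptation")
    if not act.lead_steps:
        raise ValueError("no spontaneous window: empty leading silence")
    frames = [
        _unit_frame(act.k_activity, "K", act.pulse_steps, act.lead_steps),
        _unit_frame(act.d_activity, "D", act.pulse_steps, act.lead_steps),
    ]
    df = pd.concat(frames, ignore_index=True)
    df.attrs["n_excluded"] = int(df["normalized_last"].isna().sum())
    return df


def spearman_with_ci(x, y, alpha: float = 0.05) -> dict:
    """Spearman rho with two-sided p and a Fisher-z confidence interval.

    The CI uses the rank-based large-sample variance 1/(n-3) on the
    z-transformed coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("need two equal-length vectors with at least 4 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation for constant input")
    rho, p = scipy.stats.spearmanr(x, y)
    z = np.arctanh(rho)
    half = scipy.stats.norm.ppf(1 - alpha / 2) / np.sqrt(x.size - 3)
    return {
        "rho": float(rho),
        "p_value": float(p),
        "ci_low": float(np.tanh(z - half)),
        "ci_high": float(np.tanh(z + half)),
        "n": int(x.size),
    }


def click_train_experiment(
    seed: int = 0,
    n: int = 150,
    f: int = 100,
    n_pulses: int = 9,
    gap: int = 30,
    lead_silence: int = 30,
    noise_sd: float = 0.002,
    c0_mean: float = 0.012,
    c0_sd: float = 0.006,
    p0_diag: float = 0.5,
    element_index: int = 0,
) -> dict:
    """Full click-train circuit simulation and its correlation statistics.

    Pulses one dictionary element (unit amplitude, one step per pulse) through
    the iterative estimator, decomposes the gain into uncertainty (|K|) and
    parameter-error (|K o e|) unit activities, pools both populations
    (2 * n * f units), and correlates spontaneous activity and first-pulse
    response against the normalized last-pulse response.
    """
    d = make_random_dictionary(n, f, "uniform01", seed=rng_from(seed, 10).integers(2**31))
    train = generate_click_train(
        d, element_index, n_pulses, gap=gap, lead_silence=lead_silence,
        pulse_amplitude=1.0, noise_sd=noise_sd, seed=seed,
    )
    c0 = c0_mean + c0_sd * rng_from(seed, 11).standard_normal(n)
    state0 = init_state(n, c0=c0, p0_diag=p0_diag)
    traj = run_icpa(train, d, init=state0, keep="all")
    act = decompose_activity(traj, train.pulse_steps, train.lead_steps)
    units = response_metrics(act)
    pooled = units.dropna(subset=["normalized_last"])
    rho_spont = spearman_with_ci(pooled["spontaneous"], pooled["normalized_last"])
    rho_evoked = spearman_with_ci(pooled["evoked_first"], pooled["normalized_last"])
    error_norms = np.array([np.linalg.norm(st.diagnostics.e) for st in traj])
    return {
        "rho_spont_adapt": rho_spont,
        "rho_evoked_adapt": rho_evoked,
        "unit_table": units,
        "n_excluded": units.attrs["n_excluded"],
        "pulse_error_norms": error_norms[list(train.pulse_steps)],
        "final_c": traj[-1].c,
        "pulsed_element": int(element_index),
        "dictionary": d,
        "train": train,
    }


def fit_adaptation(responses: Sequence[float] | np.ndarray) -> dict:
    """Fit r(k) = A exp(-k / tau) + B over pulse index k = 1..len(responses).

    Returns amplitude A, decay_rate tau, offset B, and the relative fit error
    ||fit - data|| / ||data||.  Raises on optimizer failure.
    """
    r = np.asarray(responses, dtype=float)
    if r.size < 3:
        raise ValueError("need at least 3 pulses to fit an exponential")
    k = np.arange(1, r.size + 1, dtype=float)

    def model(k, A, tau, B):
        return A * np.exp(-k / tau) + B

    span = float(r.max() - r.min())
    p0 = (span if span > 0 else 1.0, max(r.size / 3.0, 1.0), float(r.min()))
    try:
        popt, _ = scipy.optimize.curve_fit(
            model, k, r, p0=p0,
            bounds=([-np.inf, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"fit failed: {exc}") from exc
    fit = model(k, *popt)
    denom = float(np.linalg.norm(r))
    rel_err = float(np.linalg.norm(fit - r) / denom) if denom > 0 else float(np.linalg.norm(fit - r))
    return {
        "amplitude": float(popt[0]),
        "decay_rate": float(popt[1]),
        "offset": float(popt[2]),
        "fit_error": rel_err,
    }


def write_unit_table(units: pd.DataFrame, path) -> None:
    """Unit table as tab-delimited text."""
    units.to_csv(path, sep="\t", index=False)
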