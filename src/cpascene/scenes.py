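"""Synthetic auditory scenes.

A scene is a sequence of ``T`` observations of an ``f``-dimensional signal,

    s(t) = sum_k a_k(t) * b_k + eta(t),

a superposition of a few dictionary elements ``b_k``, each modulated by an
independent amplitude ``a_k(t)``, plus i.i.d. Gaussian noise ``eta``.  Click
trains (a single element pulsed at regular intervals) and scenes perturbed by
an out-of-dictionary source are also generated here.

Time steps are dimensionless; reports use 1-based step indices.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._util import rng_from
from .dictionary import Dictionary

__all__ = [
    "AuditoryScene",
    "ClickTrain",
    "generate_scene",
    "scale_source_amplitude",
    "generate_click_train",
    "click_schedule",
    "add_unknown_source",
    "read_scene",
    "write_scene",
]


@dataclass(frozen=True)
class AuditoryScene:
    """T observations of an f-dimensional mixture plus its ground truth."""

    observations: np.ndarray  # (T, f)
    active_indices: tuple[int, ...]
    amplitudes: np.ndarray  # (T, k), k = number of active sources
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        obs = np.asarray(self.observations, dtype=float)
        amp = np.asarray(self.amplitudes, dtype=float)
        if obs.ndim != 2 or obs.shape[0] < 1:
            raise ValueError("observations must be a (T, f) matrix with T >= 1")
        if amp.shape != (obs.shape[0], len(self.active_indices)):
            raise ValueError("amplitudes must be (T, #active sources)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        object.__setattr__(self, "observations", obs)
        object.__setattr__(self, "amplitudes", amp)
        object.__setattr__(self, "active_indices", tuple(int(i) for i in self.active_indices))

    @property
    def T(self) -> int:
        return self.observations.shape[0]

    @property
    def f(self) -> int:
        return self.observations.shape[1]


@dataclass(frozen=True)
class ClickTrain(AuditoryScene):
    """A pulsed single-element scene, with its pulse/silence schedule (0-based)."""

    pulse_steps: tuple[int, ...] = ()
    lead_steps: tuple[int, ...] = ()


_AMPLITUDE_MODELS = ("standard_normal", "lognormal")


def _draw_amplitudes(rng, model: str, T: int, k: int, log_sd: float) -> np.ndarray:
    if model == "standard_normal":
        return rng.standard_normal((T, k))
    if model == "lognormal":
        return rng.lognormal(mean=0.0, sigma=log_sd, size=(T, k))
    raise ValueError(f"unknown amplitude model {model!r}; choose from {_AMPLITUDE_MODELS}")


def generate_scene(
    d: Dictionary,
    active_indices: Sequence[int],
    T: int,
    amplitude_model: str = "standard_normal",
    noise_sd: float = 0.0,
    seed: int = 0,
    log_sd: float = 2.0,
    amplitude_scales: Sequence[float] | None = None,
) -> AuditoryScene:
    """Superpose amplitude-modulated dictionary elements with additive noise.

    Amplitudes are i.i.d. across sources and time, drawn from ``amplitude_model``
    (``log_sd`` applies to the lognormal model only).  ``amplitude_scales``
    optionally multiplies each source's amplitudes by a constant, e.g. to make
    one source 10-fold quieter.  Deterministic given ``seed``.
    """
    active = [int(i) for i in active_indices]
    if len(set(active)) != len(active):
        raise ValueError("active_indices must be distinct")
    if any(i < 0 or i >= d.n for i in active):
        raise ValueError("active index out of range")
    if T < 1:
        raise ValueError("T must be >= 1")
    k = len(active)
    if not active and noise_sd == 0:
        warnings.warn("degenerate silent scene: no active sources and no noise")

    rng_amp = rng_from(seed, 1)
    rng_noise = rng_from(seed, 2)
    amp = _draw_amplitudes(rng_amp, amplitude_model, T, k, log_sd)
    if amplitude_scales is not None:
        scales = np.asarray(amplitude_scales, dtype=float)
        if scales.shape != (k,):
            raise ValueError("need one amplitude scale per active source")
        amp = amp * scales
    obs = amp @ d.matrix[active] if k else np.zeros((T, d.f))
    if noise_sd > 0:
        obs = obs + noise_sd * rng_noise.standard_normal((T, d.f))
    return AuditoryScene(obs, tuple(active), amp, noise_sd, seed)


def scale_source_amplitude(
    d: Dictionary,
    active_indices: Sequence[int],
    T: int,
    index: int,
    sd_scale: float,
    **kwargs,
) -> AuditoryScene:
    """Scene as ``generate_scene`` but with one source's amplitude SD rescaled."""
    active = [int(i) for i in active_indices]
    if int(index) not in active:
        raise ValueError(f"index {index} is not a generating source")
    if sd_scale <= 0:
        raise ValueError("sd_scale must be positive")
    scales = np.ones(len(active))
    scales[active.index(int(index))] = sd_scale
    return generate_scene(d, active, T, amplitude_scales=scales, **kwargs)


def click_schedule(n_pulses: int, gap: int, lead_silence: int) -> tuple[np.ndarray, np.ndarray, int]:
    """0-based pulse steps, lead-silence steps, and total length of a click train."""
    pulses = lead_silence + np.arange(n_pulses) * (gap + 1)
    total = int(pulses[-1]) + 1
    return pulses, np.arange(lead_silence), total


def generate_click_train(
    d: Dictionary,
    element_index: int,
    n_pulses: int,
    gap: int = 30,
    lead_silence: int = 30,
    pulse_amplitude: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ClickTrain:
    """One dictionary element applied for single steps, separated by silences.

    The pulse at unit (or ``pulse_amplitude``) amplitude occupies exactly one
    time step; ``gap`` silent steps separate consecutive pulses and
    ``lead_silence`` silent steps precede the first pulse.  Gaussian noise of
    ``noise_sd`` is added at every step, silences included.
    """
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    if not 0 <= int(element_index) < d.n:
        raise ValueError("element index out of range")
    pulses, lead, total = click_schedule(n_pulses, gap, lead_silence)
    amp = np.zeros((total, 1))
    amp[pulses, 0] = pulse_amplitude
    obs = amp @ d.matrix[[int(element_index)]]
    if noise_sd > 0:
        obs = obs + noise_sd * rng_from(seed, 2).standard_normal(obs.shape)
    return ClickTrain(
        obs,
        (int(element_index),),
        amp,
        noise_sd,
        seed,
        pulse_steps=tuple(int(p) for p in pulses),
        lead_steps=tuple(int(s) for s in lead),
    )


def add_unknown_source(
    scene: AuditoryScene,
    v: np.ndarray,
    amplitude_sd: float,
    seed: int = 0,
) -> AuditoryScene:
    """Add an amplitude-modulated out-of-dictionary source to every observation.

    ``v`` should be normalized like a dictionary element (zero mean, unit
    norm); its amplitudes are i.i.d. standard normal times ``amplitude_sd``.
    The returned scene keeps the original ground-truth indices: the unknown
    source is, by construction, not a dictionary element.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (scene.f,):
        raise ValueError("feature-count mismatch between unknown source and scene")
    if amplitude_sd <= 0:
        raise ValueError("amplitude_sd must be positive")
    a = amplitude_sd * rng_from(seed, 3).standard_normal(scene.T)
    obs = scene.observations + np.outer(a, v)
    return AuditoryScene(obs, scene.active_indices, scene.amplitudes, scene.noise_sd, scene.seed)


def write_scene(scene: AuditoryScene, path) -> None:
    """Observations as tab-delimited text plus a JSON metadata sidecar."""
    path = Path(path)
    np.savetxt(path, scene.observations, delimiter="\t")
    meta = {
        "active_indices": list(scene.active_indices),
        "noise_sd": scene.noise_sd,
        "seed": scene.seed,
        "amplitudes": scene.amplitudes.tolist(),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))


def read_scene(path) -> AuditoryScene:
    path = Path(path)
    obs = np.loadtxt(path, delimiter="\t", ndmin=2)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    return AuditoryScene(
        obs,
        tuple(meta["active_indices"]),
        np.asarray(meta["amplitudes"], dtype=float).reshape(obs.shape[0], -1),
        float(meta["noise_sd"]),
        int(meta["seed"]),
    )
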