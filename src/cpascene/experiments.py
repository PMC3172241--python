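"""Scripted simulation experiments.

These functions bundle the synthetic protocols used throughout the package:
the 18-element two-source comparison against template matching (including the
10-fold-quieter source), the large-dictionary and scaling sweeps of the
iterative estimator, and the unknown-source robustness runs.  They exist so
that tests, the CLI, and the acceptance script all execute one shared,
seeded definition of each protocol.
"""

from __future__ import annotations

import numpy as np

from ._util import derive_seed, rng_from
from .batch import fit_cpa, projections, rank_detect, template_match_rms
from .dictionary import Dictionary, dictionary_from_vectors, normalize_element
from .dictionary import make_random_dictionary
from .recursive import large_n_fit
from .scenes import add_unknown_source, generate_scene, scale_source_amplitude

__all__ = [
    "two_source_dictionary",
    "two_source_trial",
    "intensity_invariance_experiment",
    "large_dictionary_trial",
    "source_count_sweep",
    "feature_count_sweep",
    "unknown_source_trial",
]


#: Dictionary seed for the packaged two-source demo.  At f=10 a random
#: 18-element dictionary occasionally contains a distractor that nearly
#: duplicates a source (|b_i . b_source| > 0.8), in which case no method can
#: tell the two apart; the demo fixes a draw without such a near-duplicate,
#: matching the regime the published example illustrates.  The quantitative
#: invariance statistics below do not depend on this choice.
DEMO_DICTIONARY_SEED = 2


def two_source_dictionary(seed: int = DEMO_DICTIONARY_SEED, n_extra: int = 16, f: int = 10) -> Dictionary:
    """Two lognormal source elements plus ``n_extra`` Gaussian distractors.

    The two sources (indices 0 and 1) are drawn from a lognormal with log-mean
    0 and log-sd 1 — skewed, strictly positive raw spectra, chosen so the two
    sources are visually distinctive — the distractors from a standard normal.
    All elements are mean-subtracted and unit-normalized.
    """
    rng = rng_from(seed, 30)
    sources = rng.lognormal(mean=0.0, sigma=1.0, size=(2, f))
    extras = rng.standard_normal((n_extra, f))
    return dictionary_from_vectors(np.vstack([sources, extras]))


def two_source_trial(
    seed: int = 0,
    quiet_scale: float = 1.0,
    T: int = 180,
    dictionary_seed: int = DEMO_DICTIONARY_SEED,
) -> dict:
    """One two-source scene scored by both presence fit and template matching.

    ``seed`` drives the amplitude modulations; the dictionary defaults to the
    packaged demo draw (see ``DEMO_DICTIONARY_SEED``).  ``quiet_scale``
    rescales the amplitude SD of source 1 (e.g. 0.1 for the 10-fold-quieter
    condition).  Returns each method's top-2 detections.
    """
    d = two_source_dictionary(dictionary_seed)
    if quiet_scale == 1.0:
        scene = generate_scene(d, (0, 1), T, seed=derive_seed(seed, 31))
    else:
        scene = scale_source_amplitude(d, (0, 1), T, index=1, sd_scale=quiet_scale,
                                       seed=derive_seed(seed, 31))
    est = fit_cpa(scene, d)
    rms = template_match_rms(projections(scene, d))
    return {
        "cpa_top2": set(int(i) for i in rank_detect(est.c, 2)),
        "rms_top2": set(int(i) for i in rank_detect(rms, 2)),
        "truth": {0, 1},
        "estimate": est,
    }


def intensity_invariance_experiment(n_trials: int = 100, seed: int = 0) -> dict:
    """Count, over seeded trials, how each method handles a 10-fold-quieter source.

    For each trial the same dictionary/amplitude seeds are run at equal
    loudness and with source 1 ten-fold quieter.  Tallies how often the
    presence-fit top-2 changes between the two conditions and how often
    template matching loses the quiet source.
    """
    cpa_rank_changes = 0
    rms_quiet_missed = 0
    cpa_quiet_missed = 0
    for k in range(n_trials):
        s = derive_seed(seed, 100 + k)
        equal = two_source_trial(s, quiet_scale=1.0, dictionary_seed=s)
        quiet = two_source_trial(s, quiet_scale=0.1, dictionary_seed=s)
        if equal["cpa_top2"] != quiet["cpa_top2"]:
            cpa_rank_changes += 1
        if 1 not in quiet["rms_top2"]:
            rms_quiet_missed += 1
        if 1 not in quiet["cpa_top2"]:
            cpa_quiet_missed += 1
    return {
        "n_trials": n_trials,
        "cpa_rank_changes": cpa_rank_changes,
        "rms_quiet_missed": rms_quiet_missed,
        "cpa_quiet_missed": cpa_quiet_missed,
    }


def large_dictionary_trial(
    n: int = 68000,
    f: int = 400,
    n_sources: int = 2,
    T: int = 10,
    seed: int = 0,
    p0_diag: float = 1.0,
) -> dict:
    """Identify a few random sources from a very large dictionary (matrix-free).

    Returns the generating indices, the estimator's top-``n_sources`` indices,
    and summary statistics of present vs absent presence parameters.
    """
    d = make_random_dictionary(n, f, "uniform01", seed=derive_seed(seed, 40))
    rng = rng_from(seed, 41)
    truth = np.sort(rng.choice(n, size=n_sources, replace=False))
    scene = generate_scene(d, truth, T, seed=derive_seed(seed, 42))
    est = large_n_fit(scene, d, p0_diag=p0_diag)
    top = rank_detect(est.c, n_sources)
    absent = np.delete(est.c, truth)
    return {
        "truth": set(int(i) for i in truth),
        "top": set(int(i) for i in top),
        "present_c": est.c[truth],
        "absent_c_sd": float(absent.std()),
        "absent_c_max": float(np.abs(absent).max()),
        "estimate": est,
    }


def source_count_sweep(
    source_counts=(2, 4, 8),
    f: int = 100,
    n: int = 3200,
    T: int = 10,
    replicates: int = 5,
    seed: int = 0,
) -> dict:
    """Mean presence parameter of generating elements vs number of sources.

    More simultaneously present sources raise the overlap between the scene
    and non-generating elements, pulling the present elements' parameters
    away from 1.
    """
    means = []
    for k in source_counts:
        vals = []
        for r in range(replicates):
            out = large_dictionary_trial(
                n=n, f=f, n_sources=int(k), T=T, seed=derive_seed(seed, 500 + 37 * int(k) + r)
            )
            vals.append(float(np.mean(out["present_c"])))
        means.append(float(np.mean(vals)))
    return {"source_counts": tuple(int(k) for k in source_counts),
            "mean_present_c": np.array(means), "replicates": replicates}


def feature_count_sweep(
    f_values=(100, 400, 1600),
    n_over_f: int = 4,
    n_sources: int = 2,
    T: int = 10,
    replicates: int = 3,
    seed: int = 0,
    p0_diag: float = 1e4,
) -> dict:
    """SD of absent-element presence parameters as the feature count grows.

    With the dictionary-size-to-feature ratio fixed, random elements become
    closer to orthogonal as f grows and the absent-element parameters shrink
    roughly as 1/sqrt(f); the log-log regression slope is returned.

    The default prior is diffuse (large ``p0_diag``) so the measured spread
    reflects the estimator's own overlap-driven deviations; a strong prior
    would instead shrink absent-element parameters toward zero at the faster
    ridge-dominated rate (close to 1/f) and mask the law being probed.
    """
    sds = []
    for f in f_values:
        vals = []
        for r in range(replicates):
            out = large_dictionary_trial(
                n=int(n_over_f) * int(f), f=int(f), n_sources=n_sources, T=T,
                seed=derive_seed(seed, 900 + 13 * int(f) + r), p0_diag=p0_diag,
            )
            vals.append(out["absent_c_sd"])
        sds.append(float(np.mean(vals)))
    sds = np.array(sds)
    slope = float(np.polyfit(np.log(np.asarray(f_values, dtype=float)), np.log(sds), 1)[0])
    return {"f_values": tuple(int(f) for f in f_values), "absent_sd": sds,
            "slope": slope, "replicates": replicates}


def dictionary_size_sweep(
    n_values=(1000, 4000, 16000),
    f: int = 400,
    n_sources: int = 2,
    T: int = 10,
    replicates: int = 3,
    seed: int = 0,
) -> dict:
    """Present vs absent presence parameters as the dictionary grows.

    Larger dictionaries divert more of the reconstruction onto spurious
    elements, lowering the present elements' parameters, but identification
    stays perfect as long as present stays well above absent.
    """
    rows = []
    for n in n_values:
        pres, ab, correct = [], [], 0
        for r in range(replicates):
            out = large_dictionary_trial(
                n=int(n), f=f, n_sources=n_sources, T=T,
                seed=derive_seed(seed, 700 + 7 * int(n) + r),
            )
            pres.append(float(np.mean(out["present_c"])))
            ab.append(out["absent_c_max"])
            correct += out["truth"] == out["top"]
        rows.append({
            "n": int(n), "mean_present_c": float(np.mean(pres)),
            "max_absent_c": float(np.mean(ab)), "correct": correct,
        })
    return {"rows": rows, "replicates": replicates}


def unknown_source_trial(
    amplitude_sd: float,
    n: int = 1000,
    f: int = 300,
    T: int = 10,
    seed: int = 0,
    n_known: int = 2,
) -> dict:
    """Known sources plus one out-of-dictionary source of given loudness.

    With ``n_known=2`` this probes robustness: do the in-dictionary sources
    still carry the largest presence parameters despite the unknown
    perturbation?  With ``n_known=0`` the unknown source is presented alone
    and should appear only as low-level activation spread over many elements,
    never as a single large presence parameter.
    """
    d = make_random_dictionary(n, f, "uniform01", seed=derive_seed(seed, 60))
    rng = rng_from(seed, 61)
    truth = np.sort(rng.choice(n, size=n_known, replace=False)) if n_known else np.array([], dtype=int)
    scene = generate_scene(d, truth, T, seed=derive_seed(seed, 62),
                           noise_sd=1e-12 if n_known == 0 else 0.0)
    v = normalize_element(rng.random(f))
    perturbed = add_unknown_source(scene, v, amplitude_sd, seed=derive_seed(seed, 63))
    est = large_n_fit(perturbed, d)
    top = rank_detect(est.c, max(n_known, 1))
    absent = np.delete(est.c, truth) if n_known else est.c
    return {
        "truth": set(int(i) for i in truth),
        "top": set(int(i) for i in top),
        "present_min_c": float(est.c[truth].min()) if n_known else float("nan"),
        "absent_max_c": float(absent.max()),
        "absent_above_tenth_max": int(np.sum(np.abs(absent) > 0.1 * np.abs(est.c).max())),
    }
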