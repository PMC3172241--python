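import numpy as np
import pandas as pd
import pytest

from cpascene.circuit import (
    CircuitActivity,
    decompose_activity,
    fit_adaptation,
    response_metrics,
    spearman_with_ci,
)
from cpascene.dictionary import make_random_dictionary
from cpascene.recursive import init_state, run_icpa
from cpascene.scenes import generate_click_train


def small_click_run(seed=0, n=30, f=20, n_pulses=4, gap=5, lead=5, noise_sd=0.005):
    d = make_random_dictionary(n, f, "uniform01", seed=seed)
    train = generate_click_train(d, 0, n_pulses, gap=gap, lead_silence=lead,
                                 noise_sd=noise_sd, seed=seed)
    traj = run_icpa(train, d, init=init_state(n, c0=0.01, p0_diag=0.5))
    act = decompose_activity(traj, train.pulse_steps, train.lead_steps)
    return act, traj, train


class TestDecomposeActivity:
    def test_single_step_toy_matches_hand_computation(self, rng):
        d = make_random_dictionary(2, 3, seed=5)
        state = init_state(2, p0_diag=1.0)
        s = rng.standard_normal(3)
        new = run_icpa(s[np.newaxis, :], d, init=state)[0]
        act = decompose_activity([new], pulse_steps=[0], lead_steps=[])
        K = new.diagnostics.K
        e = new.diagnostics.e
        for h in range(2):
            for i in range(3):
                assert act.k_activity[0, h, i] == pytest.approx(abs(K[h, i]), abs=1e-14)
                assert act.d_activity[0, h, i] == pytest.approx(abs(K[h, i] * e[i]), abs=1e-14)

    def test_zero_error_step_silences_error_units_only(self, ortho_dict):
        # a perfectly predicted observation: error units mute, gain units do not
        c0 = np.zeros(ortho_dict.n)
        c0[1] = 1.0
        s = 0.8 * ortho_dict.matrix[1]
        traj = run_icpa(s[np.newaxis, :], ortho_dict, init=init_state(ortho_dict.n, c0=c0))
        act = decompose_activity(traj, pulse_steps=[0], lead_steps=[])
        assert np.max(act.d_activity) < 1e-12
        assert np.max(act.k_activity) > 0

    def test_missing_diagnostics_rejected(self):
        bare = init_state(3)
        with pytest.raises(ValueError, match="lacks diagnostics"):
            decompose_activity([bare], [0], [])


class TestResponseMetrics:
    def _activity(self, values):
        """CircuitActivity with identical K and D unit activity per step."""
        arr = np.array(values, dtype=float).reshape(-1, 1, 1)
        return CircuitActivity(arr, arr.copy(), pulse_steps=(1, 2, 3), lead_steps=(0,))

    def test_constant_activity_gives_unit_normalized_last(self):
        df = response_metrics(self._activity([2.0, 2.0, 2.0, 2.0]))
        assert np.allclose(df["normalized_last"], 1.0)

    def test_halving_activity_gives_half(self):
        df = response_metrics(self._activity([1.0, 4.0, 3.0, 2.0]))
        assert np.allclose(df["normalized_last"], 0.5)
        assert np.allclose(df["spontaneous"], 1.0)
        assert np.allclose(df["evoked_first"], 4.0)

    def test_near_zero_first_response_excluded_and_counted(self):
        df = response_metrics(self._activity([1.0, 0.0, 1.0, 1.0]))
        assert df["normalized_last"].isna().all()
        assert df.attrs["n_excluded"] == 2  # one K unit + one D unit

    def test_requires_two_pulses_and_lead_window(self):
        arr = np.ones((3, 1, 1))
        with pytest.raises(ValueError, match="2 pulses"):
            response_metrics(CircuitActivity(arr, arr, pulse_steps=(1,), lead_steps=(0,)))
        with pytest.raises(ValueError, match="spontaneous window"):
            response_metrics(CircuitActivity(arr, arr, pulse_steps=(1, 2), lead_steps=()))


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        assert spearman_with_ci(x, x**3)["rho"] == pytest.approx(1.0)
        assert spearman_with_ci(x, -x)["rho"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        x = np.array([3.1, 0.2, 5.5, 2.2, 4.0, 1.1])
        y = np.array([0.5, 0.1, 2.0, 2.5, 1.7, 0.3])
        rx = np.argsort(np.argsort(x))
        ry = np.argsort(np.argsort(y))
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_with_ci(x, y)["rho"] == pytest.approx(expected, abs=1e-12)

    def test_ci_brackets_rho_and_tightens_with_n(self, rng):
        x = rng.standard_normal(200)
        y = x + rng.standard_normal(200)
        out = spearman_with_ci(x, y)
        assert out["ci_low"] < out["rho"] < out["ci_high"]
        small = spearman_with_ci(x[:30], y[:30])
        assert (small["ci_high"] - small["ci_low"]) > (out["ci_high"] - out["ci_low"])

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="undefined correlation"):
            spearman_with_ci(np.ones(10), np.arange(10.0))


class TestFitAdaptation:
    def test_exact_exponential_recovered(self):
        k = np.arange(1, 10)
        r = 1.0 * np.exp(-k / 2.0) + 0.1
        out = fit_adaptation(r)
        assert out["amplitude"] == pytest.approx(1.0, abs=1e-6)
        assert out["decay_rate"] == pytest.approx(2.0, abs=1e-6)
        assert out["offset"] == pytest.approx(0.1, abs=1e-6)
        assert out["fit_error"] < 1e-8

    def test_constant_responses_fit_offset(self):
        out = fit_adaptation(np.full(9, 0.7))
        assert out["amplitude"] == pytest.approx(0.0, abs=1e-6)
        assert out["offset"] + out["amplitude"] * np.exp(-1 / out["decay_rate"]) == pytest.approx(
            0.7, abs=1e-3
        )

    def test_noisy_exponential_median_error_below_ten_percent(self):
        k = np.arange(1, 10)
        errs = []
        gen = np.random.default_rng(0)
        for _ in range(100):
            r = 1.0 * np.exp(-k / 2.0) + 0.1 + 0.01 * gen.standard_normal(9)
            out = fit_adaptation(r)
            errs.append(abs(out["decay_rate"] - 2.0) / 2.0)
        assert np.median(errs) < 0.10

    def test_too_few_pulses_rejected(self):
        with pytest.raises(ValueError):
            fit_adaptation([1.0, 0.5])


class TestClickTrainCircuit:
    """Scaled-down click-train run: the qualitative unit-class contrasts."""

    def test_error_units_quieter_than_gain_units_in_silence(self):
        act, _, _ = small_click_run(seed=1)
        lead = list(act.lead_steps)
        assert act.d_activity[lead].mean() < act.k_activity[lead].mean()

    def test_estimation_error_decays_over_train(self):
        act, traj, train = small_click_run(seed=2)
        norms = [np.linalg.norm(traj[t].diagnostics.e) for t in train.pulse_steps]
        assert norms[-1] < norms[0]

    def test_pulsed_element_wins_presence_parameter(self):
        _, traj, train = small_click_run(seed=3)
        assert int(np.argmax(traj[-1].c)) == train.active_indices[0]

    def test_error_population_adapts_more_than_gain_population(self):
        act, _, _ = small_click_run(seed=4)
        df = response_metrics(act)
        pooled = df.dropna(subset=["normalized_last"])
        med = pooled.groupby("population")["normalized_last"].median()
        assert med["D"] < med["K"]
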