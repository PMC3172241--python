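import numpy as np
import pytest

from cpascene.dictionary import make_random_dictionary
from cpascene.recursive import (
    batch_equivalent_fit,
    export_trajectory,
    init_state,
    large_n_fit,
    projection_matrix,
    run_icpa,
    update,
)
from cpascene.scenes import generate_scene
from tests.conftest import orthogonal_zero_mean_dictionary


def ridge_rls_oracle(obs, d, p0_diag, c0):
    """Independent closed form: augmented stacked least squares.

    minimizes sum_t ||s(t) - B(t) c||^2 + (1/p0)||c - c0||^2 via lstsq on the
    stacked design with sqrt(1/p0) prior rows appended.
    """
    T, f = obs.shape
    n = d.n
    P = obs @ d.matrix.T
    M = (P[:, None, :] * d.matrix.T[None, :, :]).reshape(T * f, n)
    w = 1.0 / np.sqrt(p0_diag)
    A = np.vstack([M, w * np.eye(n)])
    y = np.concatenate([obs.ravel(), w * np.full(n, c0)])
    return np.linalg.lstsq(A, y, rcond=None)[0]


class TestProjectionMatrix:
    def test_pure_element_gives_single_column(self, ortho_dict):
        B = projection_matrix(ortho_dict.matrix[1], ortho_dict)
        np.testing.assert_allclose(B[:, 1], ortho_dict.matrix[1], atol=1e-10)
        B[:, 1] = 0
        np.testing.assert_allclose(B, 0, atol=1e-10)

    def test_zero_observation_gives_zero_matrix(self, ortho_dict):
        B = projection_matrix(np.zeros(ortho_dict.f), ortho_dict)
        np.testing.assert_array_equal(B, 0)

    def test_matches_outer_product_oracle(self, rng):
        d = make_random_dictionary(5, 7, seed=2)
        s = rng.standard_normal(7)
        B = projection_matrix(s, d)
        for i in range(5):
            np.testing.assert_allclose(
                B[:, i], float(np.dot(s, d.matrix[i])) * d.matrix[i], atol=1e-12
            )


class TestUpdate:
    def test_no_update_when_estimate_already_matches(self, ortho_dict):
        # s = a * b_k with c_k = 1 predicts itself exactly: e = 0, delta_c = 0
        c0 = np.zeros(ortho_dict.n)
        c0[2] = 1.0
        state = init_state(ortho_dict.n, c0=c0, p0_diag=0.5)
        s = 1.3 * ortho_dict.matrix[2]
        new = update(state, s, ortho_dict)
        np.testing.assert_allclose(new.diagnostics.e, 0, atol=1e-12)
        np.testing.assert_allclose(new.c, c0, atol=1e-12)

    def test_gain_equals_new_P_times_Bt(self, rng):
        d = make_random_dictionary(8, 5, seed=4)
        state = init_state(8, p0_diag=2.0)
        s = rng.standard_normal(5)
        new = update(state, s, d)
        K_recomputed = new.P @ new.diagnostics.B.T
        np.testing.assert_allclose(new.diagnostics.K, K_recomputed, atol=1e-8)

    def test_uncertainty_never_grows(self, rng):
        d = make_random_dictionary(10, 6, seed=1)
        state = init_state(10, p0_diag=1.0)
        for _ in range(12):
            prev_P = state.P
            state = update(state, rng.standard_normal(6), d)
            growth = np.linalg.eigvalsh(state.P - prev_P).max()
            assert growth <= 1e-8

    def test_uncertainty_stays_positive_semidefinite(self, rng):
        d = make_random_dictionary(10, 6, seed=3)
        state = init_state(10, p0_diag=1.0)
        for _ in range(8):
            state = update(state, rng.standard_normal(6), d)
        assert np.linalg.eigvalsh(state.P).min() >= -1e-8
        np.testing.assert_allclose(state.P, state.P.T, atol=1e-10)

    def test_non_finite_observation_rejected(self, ortho_dict):
        state = init_state(ortho_dict.n)
        s = np.full(ortho_dict.f, np.nan)
        with pytest.raises(ValueError, match="invalid observation"):
            update(state, s, ortho_dict)


class TestInitState:
    def test_defaults(self):
        st = init_state(4)
        np.testing.assert_array_equal(st.c, 0)
        np.testing.assert_array_equal(st.P, np.eye(4))
        assert st.step == 0

    def test_nonpositive_uncertainty_rejected(self):
        with pytest.raises(ValueError, match="uncertainty must be positive"):
            init_state(3, p0_diag=0.0)


class TestEquivalence:
    """The recursion equals the regularized batch solution -- the identity
    linking the iterative and non-iterative estimators."""

    @pytest.mark.parametrize("seed", range(6))
    def test_final_c_matches_ridge_batch_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        f = int(rng.integers(3, 30))
        T = int(rng.integers(1, 20))
        p0 = float(rng.uniform(0.1, 5.0))
        c0 = float(rng.uniform(-0.2, 0.2))
        d = make_random_dictionary(n, f, seed=seed + 100)
        k = min(2, n)
        scene = generate_scene(d, tuple(range(k)), T, noise_sd=0.1, seed=seed + 200)
        final = run_icpa(scene, d, init=init_state(n, c0=c0, p0_diag=p0), keep="last")[0]
        expected = ridge_rls_oracle(scene.observations, d, p0, c0)
        scale = max(1.0, np.abs(expected).max())
        np.testing.assert_allclose(final.c, expected, atol=1e-6 * scale)

    def test_batch_equivalent_fit_matches_recursion(self):
        d = make_random_dictionary(20, 10, seed=7)
        scene = generate_scene(d, (0, 5), 8, noise_sd=0.05, seed=7)
        final = run_icpa(scene, d, init=init_state(20, c0=0.1, p0_diag=0.7), keep="last")[0]
        be = batch_equivalent_fit(scene, d, p0_diag=0.7, c0=0.1)
        np.testing.assert_allclose(be.c, final.c, rtol=1e-8, atol=1e-10)

    def test_large_n_fit_matches_recursion(self):
        d = make_random_dictionary(50, 20, seed=9)
        scene = generate_scene(d, (3, 17), 10, noise_sd=0.1, seed=9)
        final = run_icpa(scene, d, init=init_state(50, p0_diag=1.0), keep="last")[0]
        mf = large_n_fit(scene, d, p0_diag=1.0)
        scale = max(1.0, np.abs(final.c).max())
        np.testing.assert_allclose(mf.c, final.c, atol=1e-6 * scale)


class TestRunIcpa:
    def test_zero_scene_leaves_state_unchanged(self, ortho_dict):
        with pytest.warns(UserWarning):
            scene = generate_scene(ortho_dict, (), 5, noise_sd=0.0)
        traj = run_icpa(scene, ortho_dict, init=init_state(ortho_dict.n, p0_diag=2.0))
        assert len(traj) == 5
        np.testing.assert_array_equal(traj[-1].c, 0)
        np.testing.assert_array_equal(traj[-1].P, 2.0 * np.eye(ortho_dict.n))

    def test_keep_last_matches_full_trajectory(self):
        d = make_random_dictionary(8, 6, seed=2)
        scene = generate_scene(d, (0, 1), 6, noise_sd=0.1, seed=2)
        full = run_icpa(scene, d)
        last = run_icpa(scene, d, keep="last")
        assert len(last) == 1
        np.testing.assert_array_equal(full[-1].c, last[0].c)

    def test_two_random_sources_identified_after_ten_steps(self):
        # moderate-scale version of the large-dictionary identification runs
        d = make_random_dictionary(800, 400, seed=12)
        scene = generate_scene(d, (100, 600), 10, seed=12)
        final = run_icpa(scene, d, keep="last")[0]
        top2 = set(np.argsort(-final.c)[:2])
        assert top2 == {100, 600}

    def test_exact_recovery_limit_single_orthogonal_source(self):
        d = orthogonal_zero_mean_dictionary(4, 20, seed=3)
        scene = generate_scene(d, (1,), 15, seed=3)
        est = large_n_fit(scene, d, p0_diag=1e8)
        assert est.c[1] == pytest.approx(1.0, abs=1e-3)
        assert np.max(np.abs(np.delete(est.c, 1))) < 1e-3


def test_export_trajectory(tmp_path):
    d = make_random_dictionary(6, 5, seed=0)
    scene = generate_scene(d, (2,), 4, seed=0)
    traj = run_icpa(scene, d)
    path = tmp_path / "traj.tsv"
    export_trajectory(traj, d.labels, path, top_k=3)
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    assert list(df["step"]) == [1, 2, 3, 4]
    assert "top1_label" in df.columns
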