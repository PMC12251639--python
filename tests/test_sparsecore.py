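"""Oracle and property tests for the sparse-attention numerics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulsemil import sparsecore as sc


# ---------------------------------------------------------------- oracles
def sparsemax_projection(z: np.ndarray) -> np.ndarray:
    """Closed-form Euclidean projection onto the simplex (alpha = 2 oracle)."""
    z = np.asarray(z, dtype=float)
    u = np.sort(z)[::-1]
    css = np.cumsum(u)
    k = np.arange(1, z.size + 1)
    support = u + (1.0 - css) / k > 0
    rho = k[support][-1]
    tau = (css[support][-1] - 1.0) / rho
    return np.maximum(z - tau, 0.0)


def entmax_tau_grid(z: np.ndarray, alpha: float, n_grid: int = 4_000_001) -> np.ndarray:
    """Brute-force oracle: dense grid search over the threshold tau."""
    zt = (alpha - 1.0) * z
    taus = np.linspace(zt.max() - 1.0, zt.max(), n_grid)
    p = np.maximum(zt[None, :] - taus[:, None], 0.0) ** (1.0 / (alpha - 1.0))
    sums = p.sum(axis=1)
    best = np.argmin(np.abs(sums - 1.0))
    out = p[best]
    return out / out.sum()


class TestSoftmax:
    def test_symmetry(self):
        np.testing.assert_allclose(sc.softmax(np.zeros(2)), [0.5, 0.5])

    def test_shift_invariance(self):
        z = np.array([0.3, -1.2, 2.0])
        np.testing.assert_allclose(sc.softmax(z), sc.softmax(z + 7.5), atol=1e-12)

    def test_two_point_value(self):
        e = np.e
        np.testing.assert_allclose(
            sc.softmax(np.array([1.0, 0.0])), [e / (e + 1), 1 / (e + 1)], atol=5e-6
        )

    def test_rejects_empty_and_nonfinite(self):
        with pytest.raises(ValueError):
            sc.softmax(np.array([]))
        with pytest.raises(ValueError):
            sc.softmax(np.array([1.0, np.inf]))


class TestEntmax:
    def test_uniform_on_constant_input(self):
        for alpha in (1.2, 1.5, 2.0, 3.0):
            p = sc.entmax_bisect(np.full(5, 0.7), alpha)
            np.testing.assert_allclose(p, np.full(5, 0.2), atol=1e-9)

    def test_sparsemax_closed_form_two_point(self):
        p = sc.entmax_bisect(np.array([0.5, -0.5]), alpha=2.0)
        np.testing.assert_allclose(p, [1.0, 0.0], atol=1e-9)

    def test_shift_invariance(self):
        z = np.array([0.4, -0.1, 0.9, 0.0])
        for alpha in (1.3, 1.5, 2.0):
            np.testing.assert_allclose(
                sc.entmax_bisect(z, alpha),
                sc.entmax_bisect(z + 3.3, alpha),
                atol=1e-7,
            )

    @pytest.mark.parametrize("alpha", [1.25, 1.5, 1.75, 2.0])
    def test_against_sparsemax_and_grid_oracles(self, alpha):
        rng = np.random.default_rng(42)
        for _ in range(25):
            z = rng.normal(size=5)
            p = sc.entmax_bisect(z, alpha)
            if alpha == 2.0:
                oracle = sparsemax_projection(z)
            else:
                oracle = entmax_tau_grid(z, alpha, n_grid=400_001)
            np.testing.assert_allclose(p, oracle, atol=2e-5)

    def test_sparsemax_oracle_high_precision(self):
        """Against the closed-form simplex projection, 1e-6 tolerance."""
        rng = np.random.default_rng(7)
        z = rng.normal(size=(1000, 5))
        p = sc.entmax_bisect(z, 2.0, axis=-1)
        oracle = np.stack([sparsemax_projection(row) for row in z])
        assert np.max(np.abs(p - oracle)) < 1e-6

    def test_support_monotone_in_alpha(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            z = rng.normal(size=8)
            sizes = [
                int(np.sum(sc.entmax_bisect(z, a) > 1e-12))
                for a in (1.1, 1.3, 1.5, 1.8, 2.0)
            ]
            assert all(s2 <= s1 for s1, s2 in zip(sizes, sizes[1:]))

    def test_entropy_below_softmax(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=(1000, 6))
        h_ent = sc.shannon_entropy(sc.entmax_bisect(z, 1.5, axis=-1), axis=-1)
        h_soft = sc.shannon_entropy(sc.softmax(z, axis=-1), axis=-1)
        assert np.all(h_ent <= h_soft + 1e-9)

    def test_softmax_limit(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            z = rng.normal(size=6)
            p = sc.entmax_bisect(z, 1.0 + 1e-3)
            assert np.max(np.abs(p - sc.softmax(z))) < 1e-3

    def test_alpha_at_most_one_needs_flag(self):
        z = np.array([1.0, 0.0])
        with pytest.raises(ValueError):
            sc.entmax_bisect(z, 1.0)
        np.testing.assert_allclose(
            sc.entmax_bisect(z, 1.0, allow_softmax=True), sc.softmax(z)
        )

    def test_simplex_output(self):
        rng = np.random.default_rng(17)
        for alpha in (1.2, 1.5, 2.0):
            p = sc.entmax_bisect(rng.normal(size=(50, 7)), alpha, axis=-1)
            assert np.all(p >= 0)
            np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-9)


class TestEntmaxJvp:
    def test_zero_vector(self):
        z = np.array([0.2, -0.4, 1.0])
        p = sc.entmax_bisect(z, 1.5)
        np.testing.assert_allclose(sc.entmax_jvp(z, 1.5, p, np.zeros(3)), 0.0)

    @pytest.mark.parametrize("alpha", [1.5, 2.0])
    def test_finite_difference_agreement(self, alpha):
        rng = np.random.default_rng(11)
        eps = 1e-6
        for _ in range(20):
            # interior points: small scores keep the support full and smooth
            z = 0.2 * rng.normal(size=5)
            p = sc.entmax_bisect(z, alpha)
            if np.any(p < 1e-3):  # stay away from support boundaries
                continue
            v = rng.normal(size=5)
            jv = sc.entmax_jvp(z, alpha, p, v)
            fd = (
                sc.entmax_bisect(z + eps * v, alpha)
                - sc.entmax_bisect(z - eps * v, alpha)
            ) / (2 * eps)
            assert np.max(np.abs(jv - fd)) < 1e-4

    def test_softmax_limit_jacobian(self):
        rng = np.random.default_rng(13)
        z = 0.3 * rng.normal(size=6)
        v = rng.normal(size=6)
        alpha = 1.001
        p = sc.entmax_bisect(z, alpha)
        jv = sc.entmax_jvp(z, alpha, p, v)
        q = sc.softmax(z)
        softmax_jv = q * (v - np.sum(q * v))
        assert np.max(np.abs(jv - softmax_jv)) < 1e-3

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sc.entmax_jvp(None, 1.5, np.ones(3) / 3, np.zeros(4))


class TestEntropy:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (np.full(4, 0.25), np.log(4)),
            (np.array([1.0, 0.0, 0.0]), 0.0),
            (np.array([0.5, 0.25, 0.25]), 1.0397207708399179),
        ],
    )
    def test_closed_forms(self, p, expected):
        assert sc.shannon_entropy(p) == pytest.approx(expected, abs=1e-9)


class TestSigmaGamma:
    def test_neutral_state_is_identity(self):
        state = sc.ScaleState(running_sigma=1.0, gamma=1.0, epsilon=1e-12)
        raw = np.array([0.3, -1.0, 2.0])
        scaled, _ = sc.sigma_gamma_scale(raw, state, training=False)
        np.testing.assert_allclose(scaled, raw, rtol=1e-9)

    def test_scale_invariance_after_convergence(self):
        raw = np.array([0.5, -0.5, 1.5, -1.5])
        outs = []
        for k in (1.0, 10.0):
            state = sc.ScaleState()
            for _ in range(1500):
                scaled, state = sc.sigma_gamma_scale(k * raw, state, training=True)
            outs.append(scaled)
        np.testing.assert_allclose(outs[0], outs[1], rtol=0.01)

    def test_eval_mode_is_frozen(self):
        state = sc.ScaleState(running_sigma=2.0)
        raw = np.array([1.0, 2.0, 3.0])
        s1, st1 = sc.sigma_gamma_scale(raw, state, training=False)
        s2, st2 = sc.sigma_gamma_scale(raw, st1, training=False)
        np.testing.assert_array_equal(s1, s2)
        assert st1.running_sigma == st2.running_sigma == 2.0

    def test_zero_variance_batch_warns_and_keeps_sigma(self):
        state = sc.ScaleState(running_sigma=3.0)
        with pytest.warns(UserWarning):
            _, new = sc.sigma_gamma_scale(np.ones(4), state, training=True)
        assert new.running_sigma == 3.0

    def test_training_needs_two_scores(self):
        with pytest.raises(ValueError):
            sc.sigma_gamma_scale(np.array([1.0]), sc.ScaleState(), training=True)


class TestTopK:
    def test_ratio_examples(self):
        w = np.array([0.5, 0.3, 0.2, 0.0, 0.0])
        np.testing.assert_array_equal(sc.topk_support(w, 0.4), [0, 1])
        np.testing.assert_array_equal(sc.topk_support(w, 1.0), np.arange(5))

    def test_tie_break_by_smaller_index(self):
        np.testing.assert_array_equal(
            sc.topk_support(np.full(4, 0.25), 0.5), [0, 1]
        )

    def test_floor_of_one(self):
        assert sc.topk_support(np.array([0.6, 0.4]), 0.01).tolist() == [0]

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            sc.topk_support(np.array([1.0]), 0.0)


class TestSchedule:
    def test_alpha_g_schedule_endpoints_and_midpoint(self):
        sched = sc.LinearSchedule(30, 50, 1.5, 1.8)
        assert sc.schedule_value(sched, 30) == pytest.approx(1.5)
        assert sc.schedule_value(sched, 50) == pytest.approx(1.8)
        assert sc.schedule_value(sched, 40) == pytest.approx(1.65)

    def test_clamping(self):
        sched = sc.LinearSchedule(10, 20, 0.9, 0.3)
        assert sc.schedule_value(sched, 0) == 0.9
        assert sc.schedule_value(sched, 99) == 0.3

    def test_degenerate_schedule_rejected(self):
        with pytest.raises(ValueError):
            sc.LinearSchedule(5, 5, 0.0, 1.0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(-10, 10), min_size=2, max_size=8),
    st.floats(1.05, 3.0),
)
def test_entmax_always_simplex(zs, alpha):
    p = sc.entmax_bisect(np.array(zs), alpha)
    assert np.all(p >= 0)
    assert abs(p.sum() - 1.0) < 1e-9
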