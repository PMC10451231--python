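import numpy as np
import pytest
from scipy.linalg import expm

from dosekit import (
    ContinuousModel,
    DiscreteModel,
    build_continuous_model,
    discrete_transfer_function,
    interval_is_stable,
    make_interval,
    steady_state_gain,
    zoh_discretize,
)
from dosekit.core_model import RateConstants

from conftest import F_REF, G_REF, GAIN_REF


class TestZohDiscretize:
    def test_reproduces_reference_matrices_to_4dp(self, disc_model):
        np.testing.assert_allclose(disc_model.F, F_REF, atol=5e-5)
        np.testing.assert_allclose(disc_model.g, G_REF, atol=5e-5)
        assert disc_model.discretization_method == "direct"

    def test_scalar_closed_form(self):
        model = ContinuousModel.from_matrices(
            -np.eye(3), [1, 0, 0], [0, 0, 1], permissive=True
        )
        for T in (0.5, 2.0, 7.3):
            disc = zoh_discretize(model, T)
            np.testing.assert_allclose(disc.F, np.exp(-T) * np.eye(3), rtol=1e-12)
            np.testing.assert_allclose(disc.g, [1 - np.exp(-T), 0, 0], rtol=1e-12)

    def test_small_T_taylor_expansion(self, cont_model):
        T = 1e-3
        disc = zoh_discretize(cont_model, T)
        np.testing.assert_allclose(disc.F, np.eye(3) + cont_model.A * T, atol=1e-6)
        np.testing.assert_allclose(disc.g, cont_model.b * T, atol=1e-6)

    def test_singular_A_uses_augmented_path(self):
        A = np.array([[0.0, 0.0], [1.0, -1.0]])  # singular, Metzler
        model = ContinuousModel.from_matrices(A, [1, 0], [0, 1], permissive=True)
        disc = zoh_discretize(model, 2.0)
        assert disc.discretization_method == "augmented"
        # oracle: augmented exponential of the full (A, b) block
        aug = np.zeros((3, 3))
        aug[:2, :2] = A
        aug[:2, 2] = [1, 0]
        M = expm(aug * 2.0)
        np.testing.assert_allclose(disc.F, M[:2, :2], rtol=1e-12)
        np.testing.assert_allclose(disc.g, M[:2, 2], rtol=1e-12)

    def test_expm_agrees_with_eigendecomposition(self, cont_model):
        # triangular A with distinct diagonal: eigendecomposition is exact
        T = 6.0
        w, V = np.linalg.eig(cont_model.A)
        F_eig = (V @ np.diag(np.exp(w * T)) @ np.linalg.inv(V)).real
        np.testing.assert_allclose(expm(cont_model.A * T), F_eig, atol=1e-10)

    def test_nonpositive_period_rejected(self, cont_model):
        with pytest.raises(ValueError, match="positive"):
            zoh_discretize(cont_model, 0.0)

    @pytest.mark.parametrize("T", [0.1, 1.0, 6.0, 24.0, 100.0])
    def test_compartmental_discretization_nonnegative_schur(self, cont_model, T):
        disc = zoh_discretize(cont_model, T)
        assert np.all(disc.F >= 0)
        assert disc.spectral_radius() < 1


class TestSteadyStateGain:
    def test_reference_value(self, disc_model):
        assert steady_state_gain(disc_model) == pytest.approx(GAIN_REF, abs=5e-5)

    def test_zero_F_identity_case(self):
        model = DiscreteModel(np.zeros((3, 3)), [1.0, 2.0, 3.0], [0, 0, 1], T=6.0)
        assert steady_state_gain(model) == pytest.approx(3.0)

    def test_geometric_series_oracle(self, disc_model):
        total, Fj = 0.0, np.eye(3)
        for _ in range(201):
            total += disc_model.c @ Fj @ disc_model.g
            Fj = Fj @ disc_model.F
        assert steady_state_gain(disc_model) == pytest.approx(total, abs=1e-10)

    def test_unstable_F_raises(self):
        model = DiscreteModel(1.05 * np.eye(3), [1.0, 0, 0], [0, 0, 1], T=6.0)
        with pytest.raises(ValueError, match="no finite steady state"):
            steady_state_gain(model)


class TestMakeInterval:
    def test_reference_corner_entries(self, interval):
        assert interval.F_hi[0, 0] == pytest.approx(0.4252, abs=5e-5)
        assert interval.g_hi[0] == pytest.approx(4.2598, abs=5e-5)
        assert interval.F_lo[0, 0] == pytest.approx(0.3479, abs=5e-5)
        assert interval.g_lo[0] == pytest.approx(3.4853, abs=5e-5)

    def test_zero_delta_degenerate(self, disc_model):
        iv = make_interval(disc_model, 0.0)
        np.testing.assert_array_equal(iv.F_lo, iv.F_hi)
        np.testing.assert_array_equal(iv.g_lo, iv.g_hi)

    @pytest.mark.parametrize("delta", [1.0, 1.5, -0.1])
    def test_delta_out_of_range_rejected(self, disc_model, delta):
        with pytest.raises(ValueError):
            make_interval(disc_model, delta)

    def test_gain_monotone_across_interval(self, disc_model, interval):
        gain_lo = steady_state_gain(
            DiscreteModel(interval.F_lo, interval.g_lo, disc_model.c, 6.0)
        )
        gain_hi = steady_state_gain(
            DiscreteModel(interval.F_hi, interval.g_hi, disc_model.c, 6.0)
        )
        assert gain_lo < steady_state_gain(disc_model) < gain_hi


class TestIntervalStability:
    def test_reference_interval_is_stable(self, interval):
        stable, certificate = interval_is_stable(interval)
        assert stable
        assert "monotone" in certificate

    def test_zero_delta_stable(self, disc_model):
        stable, _ = interval_is_stable(make_interval(disc_model, 0.0))
        assert stable

    def test_diagonal_entry_above_one_unstable(self, interval):
        F_hi = interval.F_hi.copy()
        F_hi[0, 0] = 1.05
        from dosekit.discretization import IntervalModel

        bumped = IntervalModel(
            F_lo=interval.F_lo,
            F_hi=F_hi,
            g_lo=interval.g_lo,
            g_hi=interval.g_hi,
            delta=interval.delta,
            base=interval.base,
        )
        stable, _ = interval_is_stable(bumped)
        assert not stable

    def test_negative_lower_corner_vertex_fallback(self, interval):
        from dosekit.discretization import IntervalModel

        F_lo = interval.F_lo.copy()
        F_lo[2, 0] = -0.01
        bumped = IntervalModel(
            F_lo=F_lo,
            F_hi=interval.F_hi,
            g_lo=interval.g_lo,
            g_hi=interval.g_hi,
            delta=interval.delta,
            base=interval.base,
        )
        stable, certificate = interval_is_stable(bumped)
        assert stable
        assert "vertex" in certificate


class TestDiscreteTransferFunction:
    def test_first_impulse_sample_is_cg(self, disc_model):
        tf = discrete_transfer_function(disc_model)
        # strictly proper: numerator degree n-1, leading coefficient c^T g
        assert tf.num.size == 3
        assert tf.num[0] == pytest.approx(0.2704, abs=5e-5)

    def test_zero_F_single_delay(self):
        model = DiscreteModel(np.zeros((3, 3)), [1.0, 0, 2.0], [0, 0, 1], T=6.0)
        tf = discrete_transfer_function(model)
        # G(z) = c^T g / z: one pure-delay impulse-response sample
        np.testing.assert_allclose(tf(5.0), 2.0 / 5.0, rtol=1e-12)
        np.testing.assert_allclose(tf.num[0], 2.0)

    def test_poles_are_eigenvalues_of_F(self, disc_model):
        tf = discrete_transfer_function(disc_model)
        np.testing.assert_allclose(
            np.sort(tf.poles().real),
            np.sort(np.linalg.eigvals(disc_model.F).real),
            atol=1e-10,
        )

    def test_markov_parameter_convolution(self, disc_model):
        # numerator = denominator (*) impulse response, truncated
        tf = discrete_transfer_function(disc_model)
        h = []  # h[j] = c^T F^j g, the response j+1 steps after a unit dose
        Fj = np.eye(3)
        for _ in range(6):
            h.append(disc_model.c @ Fj @ disc_model.g)
            Fj = Fj @ disc_model.F
        conv = np.convolve(tf.den, h)[: len(tf.num)]
        np.testing.assert_allclose(conv, tf.num, atol=1e-12)


def test_interval_on_secondary_continuous_parameterization():
    """Perturbing the continuous rates and then discretizing is a different
    uncertainty model than scaling (F, g): the two produce different corners."""
    rates = RateConstants(0.0370, 0.1214, 1.2725, 0.2171)
    disc = zoh_discretize(build_continuous_model(rates), 6.0)
    disc_hi = zoh_discretize(build_continuous_model(rates.scaled(1.1)), 6.0)
    scaled_hi = 1.1 * disc.F
    assert not np.allclose(disc_hi.F, scaled_hi, atol=1e-4)
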