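import numpy as np
import pytest

from lpunwrap import (
    LpUnwrapConfig,
    PhaseImage,
    congruence_correct,
    distinction,
    floodfill_unwrap,
    lp_unwrap,
    wrap,
)
from lpunwrap.metrics import rms_error_vs_truth

TWO_PI = 2 * np.pi


def assert_congruent(phi_final, psi, tol=1e-9):
    k = (phi_final.values - psi.values) / TWO_PI
    assert np.abs(k - np.rint(k)).max() <= tol


class TestDistinction:
    def test_identical_and_2pi_shift(self, smooth_wrapped):
        _, psi = smooth_wrapped
        np.testing.assert_allclose(
            distinction(psi, PhaseImage(psi.values.copy(), False)), 0.0, atol=1e-12
        )
        shifted = PhaseImage(psi.values + TWO_PI, is_wrapped=False)
        np.testing.assert_allclose(distinction(psi, shifted), 0.0, atol=1e-9)

    def test_constant_offset(self, smooth_wrapped):
        _, psi = smooth_wrapped
        phi = PhaseImage(psi.values - 0.3, is_wrapped=False)
        np.testing.assert_allclose(distinction(psi, phi), 0.3, atol=1e-12)

    def test_shape_mismatch(self, smooth_wrapped):
        _, psi = smooth_wrapped
        with pytest.raises(ValueError):
            distinction(psi, PhaseImage(np.zeros((3, 3)), False))


class TestFloodFill:
    def test_identity_on_wrap_free_field(self, smooth_surface_factory):
        surf = smooth_surface_factory(12, 11, amp=2.0)
        np.testing.assert_array_equal(floodfill_unwrap(surf), surf)

    def test_line_ramp_integration(self):
        ramp = 1.5 * np.arange(8)[None, :] * np.ones((2, 1))
        e = wrap(ramp)
        out = floodfill_unwrap(e, check_residues=False)
        start_col = 4 - 1  # one-based round(8/2) = 4
        expected = ramp - ramp[0, start_col] + e[0, start_col]
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_differs_from_input_by_2pi_multiples(self, smooth_surface_factory):
        surf = smooth_surface_factory(16, 16, amp=9.0)
        e = wrap(surf)
        out = floodfill_unwrap(e)
        k = (out - e) / TWO_PI
        np.testing.assert_allclose(k, np.rint(k), atol=1e-9)
        assert np.abs(np.diff(out, axis=0)).max() <= np.pi
        assert np.abs(np.diff(out, axis=1)).max() <= np.pi

    def test_order_independence_on_residue_free_fields(self, smooth_surface_factory):
        for _ in range(5):
            surf = smooth_surface_factory(14, 13, amp=8.0)
            e = wrap(surf)
            fifo = floodfill_unwrap(e, discipline="fifo")
            lifo = floodfill_unwrap(e, discipline="lifo")
            np.testing.assert_array_equal(fifo, lifo)

    def test_rejects_residue_bearing_field(self):
        e = np.array([[0, np.pi / 2], [-np.pi / 2, np.pi]])
        with pytest.raises(ValueError, match="residue"):
            floodfill_unwrap(e)


class TestCongruenceCorrect:
    def test_zero_field_is_identity(self, smooth_wrapped):
        truth, psi = smooth_wrapped
        phi = PhaseImage(truth.values.copy(), is_wrapped=False)
        out = congruence_correct(phi, np.zeros(phi.shape))
        np.testing.assert_array_equal(out.values, phi.values)

    def test_restores_congruence(self, smooth_wrapped):
        _, psi = smooth_wrapped
        phi = PhaseImage(psi.values + 0.3, is_wrapped=False)
        e_unwrapped = floodfill_unwrap(distinction(psi, phi))
        out = congruence_correct(phi, e_unwrapped)
        assert_congruent(out, psi)


class TestLpUnwrap:
    def test_recovers_smooth_ramp(self):
        m, n = 40, 32
        ramp = 0.9 * np.arange(m)[:, None] + 0.4 * np.arange(n)[None, :]
        psi = PhaseImage(wrap(ramp), is_wrapped=True)
        res = lp_unwrap(psi)
        assert res.converged
        assert rms_error_vs_truth(res.phi_final, PhaseImage(ramp, False)) < 1e-9
        assert res.history[-1].weighted_l0 == 0.0
        assert_congruent(res.phi_final, psi)

    def test_constant_image_trivial(self):
        psi = PhaseImage(np.full((8, 8), 1.1), is_wrapped=True)
        res = lp_unwrap(psi)
        assert res.converged and res.iterations_run == 1
        np.testing.assert_allclose(
            res.phi_final.values, res.phi_final.values[0, 0], atol=1e-12
        )

    def test_requires_wrapped_input(self):
        with pytest.raises(ValueError):
            lp_unwrap(PhaseImage(np.zeros((4, 4)), is_wrapped=False))

    def test_exact_on_default_shear_phantom(self, default_phantom):
        _, truth, wrapped = default_phantom
        res = lp_unwrap(wrapped)
        assert res.converged
        assert rms_error_vs_truth(res.phi_final, truth) < 1e-6
        assert_congruent(res.phi_final, wrapped)

    def test_idempotent_on_own_output(self, default_phantom):
        _, _, wrapped = default_phantom
        first = lp_unwrap(wrapped)
        again = lp_unwrap(
            PhaseImage(wrap(first.phi_final.values), is_wrapped=True)
        )
        diff = again.phi_final.values - first.phi_final.values
        np.testing.assert_allclose(diff, diff[0, 0], atol=1e-6)
        k0 = diff[0, 0] / TWO_PI
        assert abs(k0 - round(k0)) < 1e-6

    def test_p2_unit_weights_match_dense_least_squares(self):
        from lpunwrap.linear_system import dense_oracle_assemble
        from lpunwrap.phase_core import wrapped_gradients
        from lpunwrap.weighting import DataWeights, UserWeights

        m, n = 10, 9
        ramp = 0.5 * np.arange(m)[:, None] + 0.25 * np.arange(n)[None, :]
        psi = PhaseImage(wrap(ramp), is_wrapped=True)
        uw = UserWeights(
            w=np.ones((m, n)), wx=np.ones((m - 1, n)), wy=np.ones((m, n - 1))
        )
        res = lp_unwrap(psi, LpUnwrapConfig(p=2.0), user_w=uw)
        grad = wrapped_gradients(psi)
        q, s = dense_oracle_assemble(
            grad, DataWeights(R=uw.wx, C=uw.wy, p=2.0, alpha=0.01)
        )
        phi = np.zeros(m * n)
        phi[1:] = np.linalg.solve(q[1:, 1:], s[1:])
        dense = phi.reshape((m, n), order="F")
        a = res.phi_final.values - res.phi_final.values.mean()
        b = dense - dense.mean()
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_determinism(self, default_phantom):
        _, _, wrapped = default_phantom
        r1 = lp_unwrap(wrapped)
        r2 = lp_unwrap(wrapped)
        np.testing.assert_array_equal(r1.phi_final.values, r2.phi_final.values)
        assert [h.residues for h in r1.history] == [h.residues for h in r2.history]
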