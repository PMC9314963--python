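import numpy as np
import pytest

from relsens import (
    SequenceParams,
    SimulationConfig,
    TissueState,
    decompose_error,
    ernst_angle,
    figure1_surface,
    kappa_derivative,
    simulate_error_grid,
    spgr_signal_small_angle,
)

ALPHA_C = np.deg2rad(6.0)
TR_C = 6.5e-3


class TestKappaDerivative:
    def test_unity_when_transmit_unchanged(self, rng):
        f = rng.uniform(0.5, 1.5, 100)
        r1 = rng.uniform(0.5, 1.4, 100)
        np.testing.assert_allclose(
            kappa_derivative(f, f, ALPHA_C, TR_C, r1), 1.0, atol=1e-14
        )

    def test_unity_on_ernst_hyperbola(self, rng):
        # fT1 * fT2 = (alpha_E / alpha_c)^2 is the second exact-cancellation branch
        for _ in range(100):
            r1 = rng.uniform(0.5, 1.4)
            fT1 = rng.uniform(0.5, 1.5)
            fT2 = ernst_angle(TR_C, r1) ** 2 / ALPHA_C**2 / fT1
            assert kappa_derivative(fT1, fT2, ALPHA_C, TR_C, r1) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_matches_forward_signal_ratio(self):
        # independent oracle: kappa with Delta = 1 is the ratio of two
        # calibration-signal evaluations with unit receive fields
        fT1, fT2, r1 = 1.2, 0.9, 0.84
        seq = SequenceParams(6.0, TR_C)
        x1 = spgr_signal_small_angle(seq, TissueState(r1), fT=fT1)
        x2 = spgr_signal_small_angle(seq, TissueState(r1), fT=fT2)
        assert kappa_derivative(fT1, fT2, ALPHA_C, TR_C, r1) == pytest.approx(
            x1 / x2, rel=1e-12
        )

    def test_reciprocity(self, rng):
        for _ in range(50):
            fT1, fT2 = rng.uniform(0.5, 1.5, 2)
            r1 = rng.uniform(0.5, 1.4)
            fwd = kappa_derivative(fT1, fT2, ALPHA_C, TR_C, r1)
            rev = kappa_derivative(fT2, fT1, ALPHA_C, TR_C, r1)
            assert fwd * rev == pytest.approx(1.0, rel=1e-12)


def small_config(n=9, with_unity=True):
    def axis(lo, hi):
        ax = np.linspace(lo, hi, n)
        if with_unity:
            ax = np.unique(np.append(ax, 1.0))
        return ax

    return SimulationConfig(
        ft1_axis=np.linspace(0.5, 1.5, n),
        r1_axis=np.linspace(0.5, 1.4, n),
        rel_transmit_axis=axis(0.85, 1.18),
        rel_receive_axis=axis(0.84, 1.18),
    )


@pytest.fixture(scope="module")
def grid():
    return simulate_error_grid(small_config())


class TestErrorGrid:

    def test_no_field_change_means_no_error(self, grid):
        c = grid.config
        it = int(np.argmin(np.abs(c.rel_transmit_axis - 1.0)))
        ik = int(np.argmin(np.abs(c.rel_receive_axis - 1.0)))
        for err in (grid.err_none, grid.err_tx_only, grid.err_rx_only, grid.err_both):
            np.testing.assert_allclose(err[:, :, it, ik], 0.0, atol=1e-9)

    def test_both_corrections_exact_when_transmit_unchanged(self, grid):
        # kappa equals Delta on the fT1 == fT2 slice, so receive + transmit
        # correction removes the error entirely even for Delta != 1
        c = grid.config
        it = int(np.argmin(np.abs(c.rel_transmit_axis - 1.0)))
        np.testing.assert_allclose(grid.err_both[:, :, it, :], 0.0, atol=1e-9)

    def test_receive_correction_exact_on_ernst_branch(self):
        # pick lattice points lying exactly on fT1*fT2 = (alpha_E/alpha_c)^2
        r1 = 0.84
        fT1 = np.linspace(0.9, 1.1, 5)
        fT2 = ernst_angle(TR_C, r1) ** 2 / ALPHA_C**2 / fT1
        cfg = SimulationConfig(
            ft1_axis=fT1[:1],
            r1_axis=np.array([r1]),
            rel_transmit_axis=np.array([fT1[0] / fT2[0]]),
            rel_receive_axis=np.array([0.9, 1.0, 1.1]),
        )
        grid = simulate_error_grid(cfg)
        # kappa equals Delta here, so the fully corrected estimate is exact;
        # the receive-only estimate still carries the shared-transmit error
        np.testing.assert_allclose(grid.err_both, 0.0, atol=1e-9)
        assert np.abs(grid.err_rx_only).max() > 1e-3

    def test_combined_correction_beats_none(self, grid):
        assert np.median(np.abs(grid.err_both)) <= np.median(np.abs(grid.err_none))

    def test_single_point_matches_scalar_reimplementation(self):
        # independent scalar re-derivation of the whole pipeline at one point
        fT1, r1, rel_t, kappa = 1.3, 0.7, 1.1, 0.9
        cfg = SimulationConfig(
            ft1_axis=np.array([fT1]), r1_axis=np.array([r1]),
            rel_transmit_axis=np.array([rel_t]), rel_receive_axis=np.array([kappa]),
        )
        grid = simulate_error_grid(cfg)

        fT2 = fT1 / rel_t
        a1, a2, tr = np.deg2rad(6.0), np.deg2rad(26.0), 19.5e-3
        g = (fT1 * (fT2**2 * ALPHA_C**2 + 2 * TR_C * r1)) / (
            fT2 * (fT1**2 * ALPHA_C**2 + 2 * TR_C * r1)
        )
        delta = kappa / g

        def sig(a, s):
            return s * r1 * a * tr / (a * a / 2 + r1 * tr)

        i1, i2 = sig(fT1 * a1, delta), sig(fT2 * a2, 1.0)

        def estimate(j1, a1e, a2e):
            return 0.5 * (i2 * a2e / tr - j1 * a1e / tr) / (j1 / a1e - i2 / a2e)

        exp_none = fT1**2 * estimate(i1, a1, a2)
        exp_both = estimate(i1 / kappa, fT1 * a1, fT2 * a2)
        assert grid.err_none.item() == pytest.approx((exp_none - r1) / r1 * 100, rel=1e-10)
        assert grid.err_both.item() == pytest.approx((exp_both - r1) / r1 * 100, rel=1e-10)


class TestDecomposition:
    def test_shares_sum_to_hundred(self):
        grid = simulate_error_grid(small_config(7))
        dec = decompose_error(grid)
        assert dec.median_tx_pct + dec.median_rx_pct == pytest.approx(100.0)
        assert dec.median_tx_pct_abs + dec.median_rx_pct_abs == pytest.approx(100.0)

    def test_pure_receive_grid_attributes_everything_to_receive(self):
        # with no transmit change, kappa is exact and receive-only correction
        # removes all error: the transmit share is zero wherever defined
        cfg = SimulationConfig(
            ft1_axis=np.linspace(0.8, 1.2, 5),
            r1_axis=np.linspace(0.5, 1.4, 5),
            rel_transmit_axis=np.array([1.0]),
            rel_receive_axis=np.linspace(0.84, 1.18, 5),
        )
        dec = decompose_error(simulate_error_grid(cfg))
        assert dec.median_rx_pct == pytest.approx(100.0, abs=1e-6)

    def test_medians_stable_under_grid_refinement(self):
        coarse = decompose_error(simulate_error_grid(small_config(21, with_unity=False)))
        fine = decompose_error(simulate_error_grid(SimulationConfig()))
        assert abs(coarse.median_tx_pct - fine.median_tx_pct) < 1.0
        assert abs(coarse.median_rx_pct - fine.median_rx_pct) < 1.0


class TestFigure1:
    def test_diagonal_is_unity(self):
        f1, f2, surf = figure1_surface()
        np.testing.assert_allclose(np.diag(surf), 1.0, atol=1e-14)

    def test_reciprocal_symmetry(self):
        f1, f2, surf = figure1_surface()
        np.testing.assert_allclose(surf * surf.T, 1.0, rtol=1e-12)

    def test_unity_on_hyperbola(self):
        f1 = np.linspace(0.8, 1.2, 7)
        r1 = 0.84
        f2 = ernst_angle(TR_C, r1) ** 2 / ALPHA_C**2 / f1
        _, _, surf = figure1_surface(f1, f2, r1_hz=r1)
        np.testing.assert_allclose(np.diag(surf), 1.0, atol=1e-12)
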