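import numpy as np
import pytest

from relsens import (
    PDW_SEQUENCE,
    RelativeSensitivity,
    RigidTransform,
    SequenceParams,
    T1W_SEQUENCE,
    TissueState,
    VFAInput,
    compute_r1_map,
    extrapolate_te0,
    mae,
    r1_shared_transmit,
    r1_two_point,
    spgr_signal_small_angle,
)
from relsens.phantom import PhantomSpec, make_phantom
from relsens.vfa import R1Map

from conftest import grid_volume


def _echo_input(intensity_te0, r2s, seq=PDW_SEQUENCE, shape=(4, 4, 4)):
    echoes = [
        grid_volume(shape, data=np.full(shape, intensity_te0 * np.exp(-te * r2s)))
        for te in seq.te_s
    ]
    return VFAInput(echoes, seq)


class TestTE0Extrapolation:
    def test_monoexponential_intercept_recovered(self):
        vfa = _echo_input(100.0, 30.0)
        out, valid = extrapolate_te0(vfa)
        assert valid.all()
        np.testing.assert_allclose(out.data, 100.0, rtol=1e-6)

    def test_constant_echoes(self):
        vfa = _echo_input(42.0, 0.0)
        out, _ = extrapolate_te0(vfa)
        np.testing.assert_allclose(out.data, 42.0, rtol=1e-9)

    def test_single_echo_passthrough(self):
        echo = grid_volume((4, 4, 4), data=np.full((4, 4, 4), 7.0))
        vfa = VFAInput([echo], SequenceParams(6.0, 19.5e-3, (2.56e-3,)))
        with pytest.warns(UserWarning, match="single echo"):
            out, valid = extrapolate_te0(vfa)
        assert valid.all()
        np.testing.assert_array_equal(out.data, 7.0)

    def test_nonpositive_voxels_fall_back_to_first_echo(self):
        vfa = _echo_input(100.0, 30.0)
        vfa.echoes[3].data[0, 0, 0] = -1.0
        out, valid = extrapolate_te0(vfa)
        assert not valid[0, 0, 0]
        assert out.data[0, 0, 0] == vfa.echoes[0].data[0, 0, 0]
        assert valid[1:].all()


class TestTwoPointEstimator:
    def _signals(self, r1, fT1, fT2, s1, s2):
        i1 = spgr_signal_small_angle(PDW_SEQUENCE, TissueState(r1), fT=fT1, s=s1)
        i2 = spgr_signal_small_angle(T1W_SEQUENCE, TissueState(r1), fT=fT2, s=s2)
        return i1, i2

    def test_exact_on_small_angle_signals(self, rng):
        # algebraic inverse of the rational forward model: with the true
        # relative sensitivity and transmit fields supplied, recovery is
        # exact to numerical precision
        for _ in range(500):
            r1 = rng.uniform(0.5, 1.4)
            fT1, fT2 = rng.uniform(0.5, 1.5), rng.uniform(0.5, 1.5)
            s1, s2 = rng.uniform(0.5, 1.5), rng.uniform(0.5, 1.5)
            i1, i2 = self._signals(r1, fT1, fT2, s1, s2)
            est = r1_two_point(i1, i2, PDW_SEQUENCE, T1W_SEQUENCE, fT1, fT2, delta=s1 / s2)
            assert abs(est / r1 - 1) < 1e-9

    def test_unity_delta_reduces_to_uncorrected(self, rng):
        i1, i2 = rng.uniform(1, 2, 2)
        a = r1_two_point(i1, i2, PDW_SEQUENCE, T1W_SEQUENCE, 1.0, 1.0, delta=1.0)
        b = r1_two_point(i1, i2, PDW_SEQUENCE, T1W_SEQUENCE, 1.0, 1.0)
        assert a == b

    def test_shared_transmit_identity(self, rng):
        # equal per-position fields in the general estimator must coincide
        # exactly with the factored shared-transmit form
        for _ in range(50):
            i1, i2 = rng.uniform(0.01, 0.1, 2)
            fT = rng.uniform(0.5, 1.5)
            delta = rng.uniform(0.8, 1.2)
            a = r1_two_point(i1, i2, PDW_SEQUENCE, T1W_SEQUENCE, fT, fT, delta)
            b = r1_shared_transmit(i1, i2, PDW_SEQUENCE, T1W_SEQUENCE, fT, delta)
            assert a == pytest.approx(b, rel=1e-12)

    def test_common_mode_receive_invariance(self):
        i1, i2 = self._signals(0.84, 1.0, 1.0, 1.0, 1.0)
        a = r1_two_point(i1, i2, PDW_SEQUENCE, T1W_SEQUENCE)
        b = r1_two_point(3.7 * i1, 3.7 * i2, PDW_SEQUENCE, T1W_SEQUENCE)
        assert a == pytest.approx(b, rel=1e-12)

    def test_uncorrected_bias_flips_sign_with_delta(self):
        i1, i2 = self._signals(0.84, 1.0, 1.0, 1.2, 1.0)  # s1/s2 = 1.2
        biased_hi = r1_two_point(i1, i2, PDW_SEQUENCE, T1W_SEQUENCE)  # delta assumed 1
        i1, i2 = self._signals(0.84, 1.0, 1.0, 1.0 / 1.2, 1.0)
        biased_lo = r1_two_point(i1, i2, PDW_SEQUENCE, T1W_SEQUENCE)
        assert (biased_hi - 0.84) * (biased_lo - 0.84) < 0


@pytest.fixture(scope="module")
def clean_phantom():
    # no motion, identical fields, no noise, rational forward model:
    # the estimator inverts the signals exactly
    return make_phantom(PhantomSpec(
        shape=(32, 32, 32), snr=None, seed=3,
        receive_rel_range=(1.0, 1.0), transmit_rel_range=(1.0, 1.0),
        vfa_signal_model="small_angle",
    ))


class TestComputeR1Map:

    def test_exact_recovery_without_motion(self, clean_phantom):
        b = clean_phantom
        # truth transmit field on the acquisition grid: tests the estimator
        # itself, not B1-map resampling
        pdw = VFAInput(b.pdw_echoes, b.spec.pdw_seq, b1_map=b.transmit_fields[0])
        t1w = VFAInput(b.t1w_echoes, b.spec.t1w_seq)
        result = compute_r1_map(pdw, t1w)
        truth = R1Map(r1=b.r1, mask=b.brain_mask)
        assert mae(result, truth, b.brain_mask).mae_pct < 0.1

    def test_oracle_delta_removes_motion_bias(self):
        motion = RigidTransform((3.0, -4.0, 2.0), (3.0, -2.0, 4.0))
        spec = PhantomSpec(shape=(32, 32, 32), motion=motion, snr=None, seed=3,
                           vfa_signal_model="small_angle")
        b = make_phantom(spec)
        from relsens import resample_rigid

        grid = b.pdw_echoes[0]
        inv = motion.inverse()
        t1w_reg = [resample_rigid(e, inv, grid, outside="zero") for e in b.t1w_echoes]
        b1_t1w = resample_rigid(b.transmit_fields[1], inv, grid, outside="zero")
        b1_t1w.data[b1_t1w.data == 0] = 1.0
        pdw = VFAInput(b.pdw_echoes, spec.pdw_seq, b1_map=b.transmit_fields[0])
        t1w = VFAInput(t1w_reg, spec.t1w_seq, b1_map=b1_t1w)
        truth = R1Map(r1=b.r1, mask=b.brain_mask)
        from scipy import ndimage

        mask = grid.with_data(
            ndimage.binary_erosion(b.brain_mask.data > 0.5, iterations=2).astype(float)
        )
        oracle = RelativeSensitivity(field=b.true_delta)
        corrected = compute_r1_map(pdw, t1w, delta=oracle, b1_mode="per_contrast")
        uncorrected = compute_r1_map(pdw, t1w)
        mae_corr = mae(corrected, truth, mask).mae_pct
        mae_unc = mae(uncorrected, truth, mask).mae_pct
        # oracle fields reduce the error to the trilinear-interpolation
        # floor of the moved anatomy (O(h^2) at 2 mm voxels), far below the
        # field-induced bias
        assert mae_corr < 2.5
        assert mae_unc > 2 * mae_corr

    def test_per_contrast_requires_both_b1_maps(self, clean_phantom):
        b = clean_phantom
        pdw = VFAInput(b.pdw_echoes, b.spec.pdw_seq, b1_map=b.b1[0])
        t1w = VFAInput(b.t1w_echoes, b.spec.t1w_seq)
        with pytest.raises(ValueError, match="per_contrast"):
            compute_r1_map(pdw, t1w, b1_mode="per_contrast")

    def test_nonphysical_voxels_masked(self):
        shape = (4, 4, 4)
        i1 = grid_volume(shape, data=np.full(shape, 0.05))
        i2 = grid_volume(shape, data=np.full(shape, 0.04))
        i2.data[0, 0, 0] = 0.2  # denominator flips: non-physical estimate
        pdw = VFAInput([i1], SequenceParams(6.0, 19.5e-3, (2.4e-3,)))
        t1w = VFAInput([i2], SequenceParams(26.0, 19.5e-3, (2.4e-3,)))
        with pytest.warns(UserWarning):
            result = compute_r1_map(pdw, t1w)
        assert result.mask.data[0, 0, 0] == 0
        assert np.isnan(result.r1.data[0, 0, 0])
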