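import numpy as np
import pytest

from srcconn.headmodel import SolutionSpace, build_leadfield, make_grid
from srcconn.inverse import (apply_inverse, localize_point_source, roi_band_power,
                             roi_band_power_chunked, roi_timeseries,
                             roi_timeseries_direct, sloreta_operator,
                             standardized_power, voxel_relative_band_power,
                             voxel_relative_band_power_fast)
from srcconn.recording import EEGRecording, MONTAGE_1020, common_average_reference


def _phi(leadfield, v, q):
    phi = leadfield.voxel_gain(v) @ q
    return phi - phi.mean()


class TestZeroLocalization:
    @pytest.mark.parametrize("n_voxels", [50, 500])
    def test_every_voxel_localized_exactly_synthetic(self, n_voxels, rng):
        coords = make_grid(10.0, None, 72.0)[:n_voxels]
        space = SolutionSpace(coords, 10.0)
        lf = build_leadfield(MONTAGE_1020, space, model="synthetic", seed=1)
        op = sloreta_operator(lf, alpha=0.0)
        for v in range(n_voxels):
            phi = _phi(lf, v, rng.standard_normal(3))
            assert localize_point_source(op, phi) == v

    def test_sample_of_three_shell_voxels(self, leadfield_test, rng):
        op = sloreta_operator(leadfield_test, alpha=0.0)
        for v in rng.choice(leadfield_test.n_voxels, 25, replace=False):
            phi = _phi(leadfield_test, int(v), rng.standard_normal(3))
            assert localize_point_source(op, phi) == v

    def test_two_planted_sources_top2(self, leadfield_synth, rng):
        # two sources with independent time courses and equal scalp power:
        # the exhaustive scan of time-averaged standardized power must rank
        # the planted voxels first
        op = sloreta_operator(leadfield_synth, alpha=0.0)
        v1, v2 = 3, 207
        patterns = []
        for v in (v1, v2):
            l = _phi(leadfield_synth, v, rng.standard_normal(3))
            patterns.append(l / np.linalg.norm(l))
        T = 2000
        phi = (np.outer(patterns[0], rng.standard_normal(T))
               + np.outer(patterns[1], rng.standard_normal(T)))
        J = (op.T @ phi).reshape(-1, 3, T)
        p = np.einsum("vit,vij,vjt->v", J, op.block_pinv(), J) / T
        top2 = set(int(i) for i in np.argsort(p)[-2:])
        assert top2 == {v1, v2}


class TestOperatorAlgebra:
    def test_zero_input_zero_output(self, operator_test):
        p = standardized_power(operator_test, np.zeros(19))
        assert np.all(p == 0)

    def test_quadratic_scaling(self, operator_test, rng):
        phi = rng.standard_normal(19)
        phi -= phi.mean()
        p1 = standardized_power(operator_test, phi)
        p3 = standardized_power(operator_test, 3.0 * phi)
        assert np.allclose(p3, 9.0 * p1)

    def test_apply_inverse_linear(self, operator_test, rng):
        a = rng.standard_normal((19, 40))
        b = rng.standard_normal((19, 40))
        def car(x):
            return common_average_reference(EEGRecording(x, 128.0))
        ja = apply_inverse(operator_test, car(a)).j
        jb = apply_inverse(operator_test, car(b)).j
        jab = apply_inverse(operator_test, car(2 * a + 3 * b)).j
        assert np.allclose(jab, 2 * ja + 3 * jb, atol=1e-10)

    def test_single_sample_shape(self, operator_test, rng):
        rec = common_average_reference(EEGRecording(rng.standard_normal((19, 1)), 128.0))
        cd = apply_inverse(operator_test, rec)
        assert cd.j.shape == (operator_test.n_voxels, 3, 1)

    def test_montage_mismatch_rejected(self, operator_test, rng):
        labels = ("Fz",) * 0 + tuple(f"E{i}" for i in range(19))
        rec = EEGRecording(rng.standard_normal((19, 5)), 128.0, labels,
                           reference="common_average")
        with pytest.raises(ValueError, match="montage"):
            apply_inverse(operator_test, rec)

    def test_resolution_blocks_positive_definite(self, operator_test):
        w = np.linalg.eigvalsh(operator_test.resolution_blocks)
        assert w.min() > 0


@pytest.fixture(scope="module")
def current(operator_test):
    rng = np.random.default_rng(5)
    rec = common_average_reference(
        EEGRecording(20 * rng.standard_normal((19, 128 * 20)), 128.0))
    return apply_inverse(operator_test, rec), rec


class TestROIBandPower:

    def test_fractions_sum_to_one(self, current, space_test):
        cd, _ = current
        rel = voxel_relative_band_power(cd, bands=("theta",))
        assert np.allclose(rel["theta"].sum(), 1.0, atol=1e-9)

    def test_scale_invariance(self, current, space_test):
        cd, rec = current
        a = roi_band_power(cd, space_test)
        cd2 = type(cd)(j=cd.j * 2.0, fs=cd.fs)
        b = roi_band_power(cd2, space_test)
        for roi in a.values:
            for band in a.values[roi]:
                assert a.values[roi][band] == pytest.approx(b.values[roi][band], abs=1e-9)

    def test_chunked_and_fast_paths_agree_with_direct(self, current, operator_test,
                                                      space_test):
        cd, rec = current
        direct = roi_band_power(cd, space_test)
        chunked = roi_band_power_chunked(operator_test, rec, space_test,
                                         chunk_voxels=100)
        fast = voxel_relative_band_power_fast(operator_test, rec)
        for roi in direct.values:
            for band in direct.values[roi]:
                assert chunked.values[roi][band] == pytest.approx(
                    direct.values[roi][band], abs=1e-9)
                idx = space_test.roi_index(roi)
                assert float(np.log(fast[band][idx])) == pytest.approx(
                    direct.values[roi][band], abs=1e-9)

    def test_silent_recording_rejected(self, operator_test, space_test):
        rec = EEGRecording(np.zeros((19, 256)), 128.0, reference="common_average")
        with pytest.raises(ValueError, match="silent"):
            roi_band_power_chunked(operator_test, rec, space_test)


class TestROITimeseries:
    def test_indexing_matches_current_blocks(self, operator_test, space_test, rng):
        rec = common_average_reference(EEGRecording(rng.standard_normal((19, 64)), 128.0))
        cd = apply_inverse(operator_test, rec)
        ts = roi_timeseries(cd, space_test)
        direct = roi_timeseries_direct(operator_test, rec, space_test)
        for roi, idx in space_test.roi_map.items():
            assert np.array_equal(ts[roi], cd.j[idx])
            assert np.allclose(direct[roi], cd.j[idx], atol=1e-12)

    def test_squared_magnitude_rotation_invariant(self, rng):
        x = rng.standard_normal((3, 200))
        from scipy.stats import special_ortho_group
        R = special_ortho_group.rvs(3, random_state=1)
        assert np.allclose((x**2).sum(axis=0), ((R @ x) ** 2).sum(axis=0))
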