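"""Activation volumes: upsampling, longitudinal folding, and counting."""

import numpy as np
import pytest

from microstim import (SurrogateModel, compute_vta, fold_longitudinal,
                       surrogate_grid, union_vta, upsample_field, volume_ratio)
from microstim.vta import BoundaryClippedWarning

from conftest import make_random_field


def brute_force_vta(field, amplitude, target_step=1.0):
    """Independent oracle: materialize the 1 µm lattice by direct trilinear
    evaluation and count points at or below the amplitude."""
    v = field.values
    nx, ny, nz = v.shape
    sub = (field.step / target_step).astype(int)
    fx = np.arange((nx - 1) * sub[0] + 1) / sub[0]
    fy = np.arange((ny - 1) * sub[1] + 1) / sub[1]
    if field.z_period is not None:
        fz = np.arange(nz * sub[2]) / sub[2]
        vz = np.concatenate([v, v[:, :, :1]], axis=2)   # wrap
    else:
        fz = np.arange((nz - 1) * sub[2] + 1) / sub[2]
        vz = v
    count = 0
    for zf in fz:
        k0 = min(int(np.floor(zf)), vz.shape[2] - 2)
        tz = zf - k0
        plane = (1 - tz) * vz[:, :, k0] + tz * vz[:, :, k0 + 1]
        for xf in fx:
            i0 = min(int(np.floor(xf)), nx - 2) if nx > 1 else 0
            tx = xf - i0
            line = (1 - tx) * plane[i0] + tx * plane[min(i0 + 1, nx - 1)]
            for yf in fy:
                j0 = min(int(np.floor(yf)), ny - 2) if ny > 1 else 0
                ty = yf - j0
                val = (1 - ty) * line[j0] + ty * line[min(j0 + 1, ny - 1)]
                if val <= amplitude:
                    count += 1
    return count * target_step ** 3


class TestUpsample:
    def test_constant_field_stays_constant(self):
        f = make_random_field(0, shape=(3, 3, 3), step=(10.0, 10.0, 10.0))
        f.values[:] = 7.5
        fine = upsample_field(f, 1.0)
        assert fine.values.shape == (21, 21, 21)
        assert np.all(fine.values == 7.5)

    def test_knots_reproduced_and_midpoints_linear(self):
        f = make_random_field(1, shape=(4, 3, 5), step=(10.0, 10.0, 10.0))
        fine = upsample_field(f, 5.0)
        np.testing.assert_allclose(fine.values[::2, ::2, ::2], f.values)
        # midpoint of 4 and 6 µA neighbors is 5 µA
        f.values[0, 0, 0] = 4.0
        f.values[1, 0, 0] = 6.0
        fine = upsample_field(f, 5.0)
        assert fine.values[1, 0, 0] == pytest.approx(5.0)


class TestFolding:
    def test_fold_within_one_period_is_identity(self):
        # knots cover [0, L): nothing aliases, folding changes no value
        f = make_random_field(2, shape=(3, 3, 4), step=(20.0, 20.0, 25.0))
        folded = fold_longitudinal(f, 100.0)
        np.testing.assert_array_equal(folded.values, f.values)
        assert folded.z_period == 100.0

    def test_fold_min_rule(self):
        # two knot planes one period apart: folded value is the minimum
        f = make_random_field(3, shape=(2, 2, 9), step=(20.0, 20.0, 25.0))
        L = 100.0   # 4 cells per period; knots k and k+4 alias
        f.values[0, 0, 1] = 8.0
        f.values[0, 0, 5] = 6.0
        folded = fold_longitudinal(f, L)
        assert folded.values.shape[2] == 4
        assert folded.values[0, 0, 1] == 6.0

    def test_threshold_then_fold_commutes_with_fold_then_threshold(self):
        # folding booleans (recruited at a) with OR == folding values with
        # min then thresholding, at the knot level
        f = make_random_field(4, shape=(3, 2, 12), step=(20.0, 20.0, 25.0),
                              nan_frac=0.1)
        L, nper = 100.0, 4
        a = 12.0
        folded = fold_longitudinal(f, L)
        with np.errstate(invalid="ignore"):
            rec_folded = folded.values <= a
            rec = f.values <= a
        rec_or = np.zeros_like(rec_folded)
        for k in range(f.values.shape[2]):
            rec_or[:, :, k % nper] |= rec[:, :, k]
        np.testing.assert_array_equal(rec_folded, rec_or)

    def test_fold_then_vta_equals_restricted_vta(self):
        # when nothing is recruited outside the first period, folding does
        # not change the volume (up to the shared end plane z = 0 ≡ L)
        f = make_random_field(5, shape=(3, 3, 9), step=(20.0, 20.0, 25.0))
        f.values[:, :, 4] = f.values[:, :, 0]   # periodic seam
        f.values[:, :, 5:] = 50.0               # nothing beyond one period
        folded = fold_longitudinal(f, 100.0)
        restricted = make_random_field(5, shape=(3, 3, 5), step=(20.0, 20.0, 25.0))
        restricted.values = f.values[:, :, :5].copy()
        a = 10.0
        assert compute_vta(folded, a, L=100.0) == pytest.approx(
            compute_vta(restricted, a, L=100.0), rel=0.02)

    def test_misaligned_step_rejected(self):
        f = make_random_field(6, shape=(2, 2, 5), step=(20.0, 20.0, 30.0))
        with pytest.raises(ValueError, match="divide"):
            fold_longitudinal(f, 100.0)


class TestVtaCounting:
    def test_below_global_minimum_is_empty(self, iso_surrogate):
        f = surrogate_grid(iso_surrogate, (-100, -100, -100), (11, 11, 11), 20.0)
        assert compute_vta(f, 0.5) == 0.0

    def test_ellipsoid_closed_form(self):
        """Iso-threshold surface with semi-axes (100, 100, 200) µm: counted
        volume within 1% of (4/3)π·100·100·200."""
        m = SurrogateModel(k=1e-4, offset=1.0, weights=(1.0, 1.0, 0.25))
        f = surrogate_grid(m, (-140.0, -140.0, -260.0), (29, 29, 53), 10.0)
        vol = compute_vta(f, 2.0)
        expected = 4.0 / 3.0 * np.pi * 100.0 * 100.0 * 200.0
        assert vol == pytest.approx(expected, rel=0.01)

    def test_monotone_in_amplitude(self):
        f = make_random_field(7, shape=(5, 5, 5), step=(20.0, 20.0, 20.0))
        vols = [compute_vta(f, a) for a in (5.0, 10.0, 20.0)]
        assert vols[0] <= vols[1] <= vols[2]

    @pytest.mark.parametrize("seed,nan_frac,z_period", [
        (10, 0.0, None), (11, 0.2, None), (12, 0.0, 50.0), (13, 0.15, 50.0),
    ])
    def test_counting_matches_brute_force_upsampling(self, seed, nan_frac, z_period):
        """The closed-form per-cell count equals brute-force materialized
        upsampling exactly, including not-recruited (NaN) cells and
        periodic longitudinal windows."""
        f = make_random_field(seed, shape=(4, 3, 5), step=(10.0, 15.0, 10.0),
                              nan_frac=nan_frac, z_period=z_period)
        rng = np.random.default_rng(seed + 100)
        for a in rng.uniform(2.0, 28.0, size=3):
            vol = compute_vta(f, a, L=z_period if z_period else 1000.0)
            assert vol == brute_force_vta(f, a)

    def test_boundary_clipping_warns(self, iso_surrogate):
        f = surrogate_grid(iso_surrogate, (-60, -60, -60), (7, 7, 7), 20.0)
        with pytest.warns(BoundaryClippedWarning):
            compute_vta(f, 5.0)    # radius 200 µm ≫ 60 µm domain


class TestUnionAndRatio:
    def test_identical_fields_union_is_single_vta(self, iso_surrogate):
        f = surrogate_grid(iso_surrogate, (-120, -120, -120), (13, 13, 13), 20.0)
        assert union_vta([f, f], 2.0) == compute_vta(f, 2.0)

    def test_disjoint_volumes_add(self):
        m = SurrogateModel(k=1e-4, offset=1.0,
                           electrodes=((0, 0, 0), (600.0, 0.0, 0.0)))
        f1 = surrogate_grid(m, (-120, -120, -120), (43, 13, 13), 20.0, "single:0")
        f2 = surrogate_grid(m, (-120, -120, -120), (43, 13, 13), 20.0, "single:1")
        a = 2.0   # radius 100 µm around each electrode: disjoint
        u = union_vta([f1, f2], a)
        assert u == pytest.approx(compute_vta(f1, a) + compute_vta(f2, a), rel=1e-12)

    def test_union_bounds(self):
        m = SurrogateModel(k=1e-4, offset=1.0,
                           electrodes=((0, 0, 0), (120.0, 0.0, 0.0)))
        f1 = surrogate_grid(m, (-140, -140, -140), (27, 15, 15), 20.0, "single:0")
        f2 = surrogate_grid(m, (-140, -140, -140), (27, 15, 15), 20.0, "single:1")
        a = 2.0
        v1, v2 = compute_vta(f1, a), compute_vta(f2, a)
        u = union_vta([f1, f2], a)
        assert max(v1, v2) <= u <= v1 + v2

    def test_ratio_one_when_sync_equals_async(self, iso_surrogate):
        f = surrogate_grid(iso_surrogate, (-120, -120, -120), (13, 13, 13), 20.0)
        curve = volume_ratio(f, [f], [1.5, 2.0])
        np.testing.assert_allclose(curve.ratios, 1.0)

    def test_ratio_undefined_below_recruitment(self, iso_surrogate):
        f = surrogate_grid(iso_surrogate, (-120, -120, -120), (13, 13, 13), 20.0)
        curve = volume_ratio(f, [f], [0.5, 2.0])
        assert np.isnan(curve.ratios[0]) and curve.ratios[1] == 1.0

    def test_scaling_identity(self):
        """Doubling every threshold and evaluating at doubled amplitude
        reproduces the original ratio exactly."""
        m = SurrogateModel(k=2e-4, offset=2.0,
                           electrodes=((0, 0, 0), (0, 0, 0)))
        fs = surrogate_grid(m, (-160, -160, -160), (17, 17, 17), 20.0, "sync")
        f1 = surrogate_grid(m, (-160, -160, -160), (17, 17, 17), 20.0, "single:0")
        c1 = volume_ratio(fs, [f1], [4.0])
        fs2, f12 = fs, f1
        fs2.values = fs.values * 2
        f12.values = f1.values * 2
        c2 = volume_ratio(fs2, [f12], [8.0])
        assert c1.ratios[0] == c2.ratios[0]
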