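"""Renormalization, cDVH construction and DER computation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vasculodose.dosimetry import (
    CDVHCurve, RenormalizationError, cdvh, colorwash, compartment_mask,
    der_report, dose_at_volume, renormalize,
)
from vasculodose.phantom import BLOOD, GOLD, TISSUE, VoxelPhantom
from vasculodose.transport import DoseGrid


def grid_from(arr, cell_total=True):
    arr = np.asarray(arr, dtype=np.float32)
    return DoseGrid(
        dose=arr, rel_uncertainty=np.zeros_like(arr),
        cell_dose=arr[..., None], cell_rel_unc=np.zeros_like(arr)[..., None],
        cell_total_dose=arr.astype(float) if cell_total else None,
        meta={"normalization_factor": 1.0},
    )


class TestRenormalize:
    def test_min_two_prescription_ten_gives_factor_five(self):
        g = grid_from(np.linspace(2.0, 8.0, 27).reshape(3, 3, 3))
        factor, out = renormalize(g, 10.0)
        assert factor == pytest.approx(5.0)
        assert out.cell_total_dose.min() == pytest.approx(10.0)

    def test_identity_when_min_equals_prescription(self):
        g = grid_from(np.full((2, 2, 2), 10.0))
        factor, out = renormalize(g, 10.0)
        assert factor == 1.0
        np.testing.assert_array_equal(out.dose, g.dose)

    def test_minimum_is_exactly_prescription(self):
        rng = np.random.default_rng(0)
        g = grid_from(rng.uniform(0.5, 3.0, (4, 4, 4)))
        _, out = renormalize(g, 10.0)
        assert out.cell_total_dose.min() == pytest.approx(10.0, rel=1e-12)

    def test_zero_minimum_fails(self):
        arr = np.ones((3, 3, 3))
        arr[0, 0, 0] = 0.0
        with pytest.raises(RenormalizationError, match="histories"):
            renormalize(grid_from(arr), 10.0)


class TestCDVH:
    def test_uniform_region_is_step_function(self):
        g = np.full((4, 4, 4), 10.0)
        curve = cdvh(g, np.ones_like(g, dtype=bool), bins=12, dose_max=12.0)
        below = curve.dose_gy <= 10.0
        np.testing.assert_allclose(curve.volume_fraction[below], 1.0)
        np.testing.assert_allclose(curve.volume_fraction[~below], 0.0)

    def test_four_voxel_grid_fraction(self):
        g = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)
        curve = cdvh(g, np.ones_like(g, dtype=bool), bins=8, dose_max=4.0)
        i = np.flatnonzero(np.isclose(curve.dose_gy, 2.5))[0]
        assert curve.volume_fraction[i] == pytest.approx(0.5)

    def test_empty_mask_rejected(self):
        g = np.ones((2, 2, 2))
        with pytest.raises(ValueError, match="empty"):
            cdvh(g, np.zeros_like(g, dtype=bool))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_monotone_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.exponential(5.0, (5, 5, 5))
        curve = cdvh(g, np.ones_like(g, dtype=bool), bins=64)
        assert (np.diff(curve.volume_fraction) <= 1e-12).all()
        assert curve.volume_fraction[0] == 1.0

    def test_integral_equals_mean_dose(self):
        """The area under the cumulative curve is the mean dose."""
        rng = np.random.default_rng(3)
        g = rng.uniform(0.0, 20.0, (8, 8, 8))
        curve = cdvh(g, np.ones_like(g, dtype=bool), bins=4096)
        integral = np.trapezoid(curve.volume_fraction, curve.dose_gy)
        assert integral == pytest.approx(g.mean(), rel=2e-3)


class TestDoseAtVolume:
    def test_step_curve(self):
        g = np.full((3, 3, 3), 10.0)
        curve = cdvh(g, np.ones_like(g, dtype=bool), bins=10, dose_max=10.0)
        assert dose_at_volume(curve, 0.5) == pytest.approx(10.0)

    def test_four_voxel_median(self):
        """D_50 of {1,2,3,4}: exactly half the volume receives >= 3."""
        g = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)
        curve = cdvh(g, np.ones_like(g, dtype=bool), bins=4, dose_max=4.0)
        assert dose_at_volume(curve, 0.5) == pytest.approx(3.0)

    def test_small_volume_limit_is_max_dose(self):
        g = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)
        curve = cdvh(g, np.ones_like(g, dtype=bool), bins=4, dose_max=4.0)
        assert dose_at_volume(curve, 1e-9) == pytest.approx(4.0)

    def test_volume_bounds_rejected(self):
        curve = CDVHCurve(np.array([0.0, 1.0]), np.array([1.0, 0.0]))
        for v in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                dose_at_volume(curve, v)


def _phantom_1d(labels):
    return VoxelPhantom(labels=np.asarray(labels, dtype=np.uint8).reshape(-1, 1, 1))


class TestDERReport:
    def test_identical_grids_give_unity(self):
        ph = _phantom_1d([TISSUE] * 8)
        g = grid_from(np.linspace(1, 9, 8).reshape(8, 1, 1))
        rep = der_report(g, g, ph)
        assert rep.average_der["TISSUE"] == pytest.approx(1.0)
        for v in rep.der["TISSUE"]:
            assert v == pytest.approx(1.0)

    def test_doubled_grid_gives_two(self):
        ph = _phantom_1d([TISSUE] * 8)
        base = np.linspace(1, 9, 8).reshape(8, 1, 1)
        rep = der_report(grid_from(2 * base), grid_from(base), ph)
        for v in rep.der["TISSUE"]:
            assert v == pytest.approx(2.0, rel=1e-6)

    def test_toy_median_ratio(self):
        """with={2,4,6,8}, without={1,2,3,4}: DER at V=50% equals 2."""
        ph = _phantom_1d([TISSUE] * 4)
        w = grid_from(np.array([2.0, 4.0, 6.0, 8.0]).reshape(4, 1, 1))
        wo = grid_from(np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1))
        rep = der_report(w, wo, ph, bins=8)
        i = rep.volumes.index(0.5)
        assert rep.der["TISSUE"][i] == pytest.approx(2.0)

    def test_invariant_under_common_rescaling(self):
        rng = np.random.default_rng(5)
        ph = _phantom_1d([TISSUE] * 64)
        a = rng.uniform(1, 5, (64, 1, 1))
        b = rng.uniform(1, 5, (64, 1, 1))
        r1 = der_report(grid_from(a), grid_from(b), ph)
        r2 = der_report(grid_from(3.7 * a), grid_from(3.7 * b), ph)
        np.testing.assert_allclose(r1.der["TISSUE"], r2.der["TISSUE"], rtol=1e-6)

    def test_average_der_is_mean_of_three(self):
        ph = _phantom_1d([TISSUE] * 16)
        rng = np.random.default_rng(8)
        w = grid_from(rng.uniform(2, 6, (16, 1, 1)))
        wo = grid_from(rng.uniform(1, 3, (16, 1, 1)))
        rep = der_report(w, wo, ph)
        assert rep.average_der["TISSUE"] == pytest.approx(
            np.mean(rep.der["TISSUE"]))

    def test_gold_voxels_excluded_from_masks(self):
        labels = np.array([TISSUE, TISSUE, GOLD, BLOOD]).reshape(4, 1, 1)
        ph = VoxelPhantom(labels=labels.astype(np.uint8), metadata={
            "gold_voxel_indices": np.array([2]),
            "gold_host_labels": np.array([TISSUE], dtype=np.uint8),
        })
        m = compartment_mask(ph, TISSUE)
        assert m.sum() == 2
        m_inc = compartment_mask(ph, TISSUE, include_gold_hosts=True)
        assert m_inc.sum() == 3


class TestColorwash:
    def test_smoke_writes_file(self, tmp_path):
        labels = np.zeros((8, 8, 8), dtype=np.uint8)
        labels[3:5, 3:5, :] = BLOOD
        ph = VoxelPhantom(labels=labels)
        g = grid_from(np.random.default_rng(0).uniform(1, 2, (8, 8, 8)))
        out = colorwash(g, ph, slice_index=4, path=tmp_path / "slice.png")
        assert out.exists() and out.stat().st_size > 0

    def test_uniform_grid_renders(self, tmp_path):
        ph = VoxelPhantom(labels=np.zeros((4, 4, 4), dtype=np.uint8))
        g = grid_from(np.zeros((4, 4, 4)))
        out = colorwash(g, ph, slice_index=2, path=tmp_path / "flat.png")
        assert out.exists()
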