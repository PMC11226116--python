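"""Vascular-tree generation and voxelization."""

import numpy as np
import pytest

from vasculodose.materials import EnergySpectrum, StoppingTable
from vasculodose.phantom import (
    BLOOD, GOLD, TISSUE, WALL,
    GenerationConfig, VascularTargetError, VesselSegment, VoxelPhantom,
    equilibrium_padding, generate_tree, vascular_fraction, voxelize,
    voxelize_chunked,
)
from conftest import make_tree


def brute_force_labels(tree, n, voxel_um):
    """Independent per-voxel classification: nearest-distance to every
    segment, no bounding boxes, priority BLOOD > WALL > TISSUE."""
    labels = np.zeros((n, n, n), dtype=np.uint8)
    for ix in range(n):
        for iy in range(n):
            for iz in range(n):
                p = (np.array([ix, iy, iz]) + 0.5) * voxel_um
                best = TISSUE
                for seg in tree.segments:
                    a, b = seg.start_point, seg.end_point
                    u = b - a
                    t = np.clip(np.dot(p - a, u) / np.dot(u, u), 0.0, 1.0)
                    d = np.linalg.norm(p - (a + t * u))
                    if d <= seg.inner_radius:
                        best = BLOOD
                        break
                    if d <= seg.outer_radius:
                        best = WALL
                labels[ix, iy, iz] = best
    return labels


class TestGenerateTree:
    def test_zero_target_gives_root_only(self):
        cfg = GenerationConfig(target_vascular_fraction=0.0)
        tree = generate_tree(seed=5, params=cfg)
        assert tree.segments == []

    def test_fixed_seed_reproducible(self):
        t1 = generate_tree(seed=42)
        t2 = generate_tree(seed=42)
        assert len(t1.segments) == len(t2.segments)
        for a, b in zip(t1.segments, t2.segments):
            np.testing.assert_array_equal(a.start_point, b.start_point)
            np.testing.assert_array_equal(a.end_point, b.end_point)
            assert a.inner_radius == b.inner_radius

    @pytest.mark.parametrize("seed", [1, 7])
    def test_terminates_at_target_fraction(self, seed):
        """Voxelized vascular fraction lands in [target, target + one
        segment's worth of overshoot]."""
        cfg = GenerationConfig()
        tree = generate_tree(seed=seed, params=cfg)
        phantom = voxelize(tree)
        frac = vascular_fraction(phantom)
        cube_vol = cfg.cube_side**3
        max_seg_vol = np.pi * (cfg.root_radius + cfg.wall_thickness) ** 2 \
            * cfg.step_length
        # venous return adds one more minimum-radius segment
        max_seg_vol += np.pi * (cfg.min_radius + cfg.wall_thickness) ** 2 \
            * cfg.cube_side
        assert cfg.target_vascular_fraction <= frac
        assert frac <= cfg.target_vascular_fraction + max_seg_vol / cube_vol

    def test_radii_within_bounds(self):
        cfg = GenerationConfig()
        tree = generate_tree(seed=11, params=cfg)
        radii = np.array([s.inner_radius for s in tree.segments])
        assert (radii >= cfg.min_radius).all()
        assert (radii <= cfg.root_radius).all()

    def test_tree_connectivity(self):
        """Every non-root segment starts at its parent's end point."""
        tree = generate_tree(seed=2)
        for seg in tree.segments:
            if seg.parent_index is not None:
                np.testing.assert_allclose(
                    seg.start_point, tree.segments[seg.parent_index].end_point)

    def test_endpoints_inside_cube(self):
        tree = generate_tree(seed=9)
        for seg in tree.segments:
            for p in (seg.start_point, seg.end_point):
                assert (p >= 0).all() and (p <= tree.cube_side).all()

    def test_entry_off_surface_rejected(self):
        with pytest.raises(ValueError):
            generate_tree(seed=1, entry=np.array([50.0, 50.0, 50.0]))

    def test_entry_equal_exit_rejected(self):
        p = np.array([0.0, 50.0, 50.0])
        with pytest.raises(ValueError):
            generate_tree(seed=1, entry=p, exit=p)

    def test_unreachable_target_fails_with_diagnostic(self):
        cfg = GenerationConfig(target_vascular_fraction=0.49, max_segments=40)
        with pytest.raises(VascularTargetError, match="unreachable"):
            generate_tree(seed=1, params=cfg)


class TestVoxelize:
    def test_empty_tree_is_all_tissue(self):
        tree = make_tree([], cube_side=10.0)
        phantom = voxelize(tree)
        assert (phantom.labels == TISSUE).all()

    def test_single_segment_cross_section(self, straight_segment_tree):
        """Mid-segment profile: blood disc of the lumen radius surrounded
        by a wall annulus of the wall thickness (4 voxels at 500 nm)."""
        phantom = voxelize(straight_segment_tree)
        n = phantom.labels.shape[0]
        sl = phantom.labels[n // 2]  # perpendicular plane at x = 10 um
        c = (np.arange(n) + 0.5) * 0.5
        yy, zz = np.meshgrid(c - 10.0, c - 10.0, indexing="ij")
        r = np.hypot(yy, zz)
        np.testing.assert_array_equal(sl == BLOOD, r <= 2.0)
        np.testing.assert_array_equal(sl == WALL, (r > 2.0) & (r <= 4.0))

    def test_wall_shell_radial_extent(self, straight_segment_tree):
        """Measured wall extent equals the 2 um wall thickness to within
        one voxel diagonal."""
        phantom = voxelize(straight_segment_tree)
        n = phantom.labels.shape[0]
        sl = phantom.labels[n // 2]
        c = (np.arange(n) + 0.5) * 0.5
        yy, zz = np.meshgrid(c - 10.0, c - 10.0, indexing="ij")
        r = np.hypot(yy, zz)
        wall_r = r[sl == WALL]
        diag = 0.5 * np.sqrt(3.0)
        assert wall_r.max() - wall_r.min() == pytest.approx(2.0, abs=diag)

    @pytest.mark.parametrize("seed", [0, 4])
    def test_matches_brute_force_oracle(self, seed):
        """Rasterization equals exhaustive per-voxel classification on a
        small grid with random oblique segments."""
        rng = np.random.default_rng(seed)
        segs = []
        for i in range(3):
            a = rng.uniform(0, 16, 3)
            b = rng.uniform(0, 16, 3)
            segs.append(VesselSegment(a, b, inner_radius=rng.uniform(1.5, 3.0)))
        tree = make_tree(segs, cube_side=16.0)
        phantom = voxelize(tree)  # 32^3 at 500 nm
        oracle = brute_force_labels(tree, 32, 0.5)
        np.testing.assert_array_equal(phantom.labels, oracle)

    def test_label_partition(self, vascular_phantom):
        counts = vascular_phantom.label_counts()
        assert sum(counts.values()) == vascular_phantom.labels.size

    def test_memory_budget_error(self, straight_segment_tree):
        from vasculodose.phantom import MemoryBudgetError
        with pytest.raises(MemoryBudgetError, match="chunked"):
            voxelize(straight_segment_tree, memory_budget_bytes=1000)

    def test_chunked_matches_in_memory(self, straight_segment_tree, tmp_path):
        phantom = voxelize(straight_segment_tree)
        path = tmp_path / "labels.raw"
        shape = voxelize_chunked(straight_segment_tree, 500.0, path, slab_voxels=7)
        chunked = np.fromfile(path, dtype=np.uint8).reshape(shape)
        np.testing.assert_array_equal(chunked, phantom.labels)


class TestVascularFraction:
    def test_all_tissue_is_zero(self):
        phantom = VoxelPhantom(labels=np.zeros((10, 10, 10), dtype=np.uint8))
        assert vascular_fraction(phantom) == 0.0

    def test_hand_built_grid(self):
        labels = np.zeros((10, 10, 10), dtype=np.uint8)
        labels[:3, :3, :3] = BLOOD
        phantom = VoxelPhantom(labels=labels)
        assert vascular_fraction(phantom) == pytest.approx(0.027)

    def test_gold_counts_toward_host_compartment(self):
        labels = np.zeros((10, 10, 10), dtype=np.uint8)
        labels[0, 0, :5] = BLOOD
        labels[0, 0, 0] = GOLD
        phantom = VoxelPhantom(labels=labels, metadata={
            "gold_voxel_indices": np.array([0]),
            "gold_host_labels": np.array([BLOOD], dtype=np.uint8),
        })
        assert vascular_fraction(phantom) == pytest.approx(5 / 1000)


class TestEquilibriumPadding:
    def test_mono_100kev_covers_csda_range(self):
        spectrum = EnergySpectrum(np.array([100.0]), np.array([1.0]))
        stopping = StoppingTable.load()
        pad = equilibrium_padding(spectrum, stopping)
        assert pad >= stopping.csda_range_um("soft_tissue_ICRU44", 100.0)[0]

    def test_degenerate_spectrum_rejected(self):
        with pytest.raises(ValueError):
            EnergySpectrum(np.array([0.0]), np.array([1.0]))

    def test_monotone_in_max_energy(self):
        stopping = StoppingTable.load()
        pads = [
            equilibrium_padding(EnergySpectrum(np.array([e]), np.array([1.0])),
                                stopping)
            for e in (50.0, 100.0, 300.0, 1000.0)
        ]
        assert all(a < b for a, b in zip(pads, pads[1:]))

    def test_energy_outside_table_rejected(self):
        from vasculodose.materials import TableRangeError
        spectrum = EnergySpectrum(np.array([50000.0]), np.array([1.0]))
        with pytest.raises(TableRangeError):
            equilibrium_padding(spectrum)


class TestVesselSegment:
    def test_zero_length_rejected(self):
        p = np.array([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            VesselSegment(p, p.copy(), inner_radius=2.0)

    def test_default_wall_thickness(self):
        seg = VesselSegment(np.zeros(3), np.ones(3), inner_radius=2.0)
        assert seg.wall_thickness == 2.0
        assert seg.outer_radius == 4.0
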