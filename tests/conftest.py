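import numpy as np
import pytest

from vasculodose.phantom import (
    GenerationConfig, VesselSegment, VesselTree, VoxelPhantom, generate_tree,
    voxelize,
)


def make_tree(segments, cube_side=20.0, seed=0):
    """Assemble a VesselTree from raw segments for geometry tests."""
    entry = segments[0].start_point if segments else np.array([0.0, cube_side / 2,
                                                              cube_side / 2])
    exit_ = segments[-1].end_point if segments else np.array([cube_side,
                                                              cube_side / 2,
                                                              cube_side / 2])
    return VesselTree(segments=segments, arterial_entry=entry, venous_exit=exit_,
                      rng_seed=seed, cube_side=cube_side,
                      config=GenerationConfig(cube_side=cube_side))


@pytest.fixture
def straight_segment_tree():
    """One axis-aligned vessel through the middle of a 20 um cube."""
    seg = VesselSegment(np.array([0.0, 10.0, 10.0]), np.array([20.0, 10.0, 10.0]),
                        inner_radius=2.0)
    return make_tree([seg])


@pytest.fixture(scope="session")
def desk_config():
    """Reduced-scale generation config used by the transport tests."""
    return GenerationConfig(cube_side=50.0, root_radius=5.0)


@pytest.fixture(scope="session")
def vascular_phantom(desk_config):
    """A (50 um)^3 vascular phantom shared across the heavier tests."""
    tree = generate_tree(seed=3, params=desk_config)
    return voxelize(tree)


@pytest.fixture
def uniform_tissue_phantom():
    """Homogeneous soft-tissue cube, 40^3 voxels of 500 nm (20 um side)."""
    return VoxelPhantom(labels=np.zeros((40, 40, 40), dtype=np.uint8))
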