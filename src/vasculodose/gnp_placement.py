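"""Gold-nanoparticle cluster loading of a voxel phantom.

Clusters are whole 500 nm voxels of bulk gold (19.3 g/cm^3): the cluster
size observed for internalized nanoparticles matches the phantom
resolution, so one cluster occupies exactly one voxel.  The number of
clusters realizing a mass concentration C (mg gold per g of phantom) is

    N = round(C * M_phantom / m_voxel),   m_voxel = rho_Au * d^3,

with M_phantom the pre-placement phantom mass.  Clusters are placed
uniformly at random without replacement in one of three compartments:
circulating in the blood, attached to the inner vessel walls (lumen-side
voxels facing the wall), or uniformly spread in the tumor tissue.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .phantom import BLOOD, GOLD, TISSUE, WALL, VoxelPhantom


class PlacementMode(enum.Enum):
    BLOOD = "blood"
    WALL_ATTACHED = "wall"
    TISSUE_UNIFORM = "tissue"


class PlacementError(RuntimeError):
    """Not enough eligible voxels to realize the requested concentration."""


@dataclass
class GNPPlacementSpec:
    """Concentration, compartment and RNG seed for cluster placement."""

    concentration_mg_g: float = 10.0
    mode: PlacementMode = PlacementMode.BLOOD
    cluster_size_nm: float = 500.0
    gold_density: float = 19.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.mode, str):
            self.mode = PlacementMode(self.mode)
        if self.concentration_mg_g < 0:
            raise ValueError("concentration must be non-negative")


def eligible_voxels(phantom: VoxelPhantom, mode: PlacementMode) -> np.ndarray:
    """Flat indices of voxels a cluster may occupy in the given mode."""
    labels = phantom.labels
    if mode is PlacementMode.BLOOD:
        mask = labels == BLOOD
    elif mode is PlacementMode.TISSUE_UNIFORM:
        mask = labels == TISSUE
    else:  # lumen voxels touching the wall through a face
        blood = labels == BLOOD
        wall = labels == WALL
        touches = np.zeros_like(blood)
        pad = np.pad(wall, 1, mode="constant")
        touches |= pad[:-2, 1:-1, 1:-1] | pad[2:, 1:-1, 1:-1]
        touches |= pad[1:-1, :-2, 1:-1] | pad[1:-1, 2:, 1:-1]
        touches |= pad[1:-1, 1:-1, :-2] | pad[1:-1, 1:-1, 2:]
        mask = blood & touches
    return np.flatnonzero(mask.ravel())


def cluster_count(phantom: VoxelPhantom, spec: GNPPlacementSpec) -> int:
    """Number of single-voxel gold clusters realizing the concentration."""
    if (phantom.labels == GOLD).any():
        raise ValueError("phantom already contains GOLD voxels")
    if abs(spec.cluster_size_nm - phantom.voxel_size_nm) > 1e-9:
        raise ValueError("cluster size must equal the phantom voxel size")
    gold_voxel_mass = spec.gold_density * phantom.voxel_volume_cm3
    n = int(round(spec.concentration_mg_g * 1e-3 * phantom.mass_g() / gold_voxel_mass))
    eligible = eligible_voxels(phantom, spec.mode)
    if n > eligible.size:
        raise PlacementError(
            f"{n} clusters requested but only {eligible.size} eligible voxels "
            f"in mode {spec.mode.value} (shortfall {n - eligible.size})")
    return n


def place(phantom: VoxelPhantom, spec: GNPPlacementSpec) -> VoxelPhantom:
    """Return a new phantom with N cluster voxels relabeled GOLD.

    Sampling is uniform without replacement over the mode's eligible
    voxels; the original label of every GOLD voxel is recorded in the
    metadata (``gold_voxel_indices`` / ``gold_host_labels``).
    """
    n = cluster_count(phantom, spec)
    labels = phantom.labels.copy()
    meta = dict(phantom.metadata)
    if n > 0:
        eligible = eligible_voxels(phantom, spec.mode)
        rng = np.random.default_rng(spec.rng_seed)
        chosen = rng.choice(eligible, size=n, replace=False)
        chosen.sort()
        hosts = labels.ravel()[chosen].copy()
        labels.ravel()[chosen] = GOLD
        meta["gold_voxel_indices"] = chosen
        meta["gold_host_labels"] = hosts
    else:
        meta["gold_voxel_indices"] = np.empty(0, dtype=np.int64)
        meta["gold_host_labels"] = np.empty(0, dtype=np.uint8)
    meta["gnp_spec"] = {
        "concentration_mg_g": spec.concentration_mg_g,
        "mode": spec.mode.value,
        "cluster_size_nm": spec.cluster_size_nm,
        "gold_density": spec.gold_density,
        "rng_seed": spec.rng_seed,
    }
    out = VoxelPhantom(labels=labels, voxel_size_nm=phantom.voxel_size_nm,
                       densities_by_label=dict(phantom.densities_by_label),
                       metadata=meta)
    out.densities_by_label[GOLD] = spec.gold_density
    return out


def realized_concentration(phantom: VoxelPhantom) -> float:
    """Gold mass per pre-placement phantom mass, mg/g."""
    n_gold = int((phantom.labels == GOLD).sum())
    gold_mass = n_gold * phantom.densities_by_label[GOLD] * phantom.voxel_volume_cm3
    return gold_mass / phantom.mass_g(pre_placement=True) * 1e3
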