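"""Random tumor-vasculature phantom: tree growth and voxelization.

A rapidly-exploring random tree (RRT) is grown inside a cube between an
arterial entry point and a venous exit point on the cube surface.  Each
tree edge is a pair of concentric finite cylinders: the lumen (blood) of
radius r and a vessel wall extending a fixed 2 um beyond it.  Growth
stops once the vascular volume (lumen + wall, overlaps counted once on a
tracking grid) reaches the target fraction of the cube, 3% by default.

The voxelized phantom labels each voxel TISSUE, WALL, BLOOD or (after
nanoparticle loading) GOLD on a regular grid, 500 nm resolution by
default, with half-open voxel extents [i*d, (i+1)*d).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .materials import MATERIALS, EnergySpectrum, StoppingTable

TISSUE, WALL, BLOOD, GOLD = 0, 1, 2, 3
LABEL_NAMES = {TISSUE: "TISSUE", WALL: "WALL", BLOOD: "BLOOD", GOLD: "GOLD"}
#: material assigned to each label; vessel walls are modeled as soft tissue
LABEL_MATERIALS = {
    TISSUE: "soft_tissue_ICRU44",
    WALL: "soft_tissue_ICRU44",
    BLOOD: "blood_ICRU44",
    GOLD: "gold",
}
DEFAULT_DENSITIES = {lab: MATERIALS[m].density for lab, m in LABEL_MATERIALS.items()}


class VascularTargetError(RuntimeError):
    """The requested vascular fraction cannot be reached."""


class MemoryBudgetError(MemoryError):
    """Voxel grid would exceed the configured memory budget."""


@dataclass
class VesselSegment:
    """A tapering vessel segment: lumen cylinder plus concentric wall."""

    start_point: np.ndarray  # um
    end_point: np.ndarray    # um
    inner_radius: float      # um
    wall_thickness: float = 2.0
    parent_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.start_point = np.asarray(self.start_point, dtype=float)
        self.end_point = np.asarray(self.end_point, dtype=float)
        if self.length <= 0:
            raise ValueError("segment length must be positive")
        if self.inner_radius <= 0:
            raise ValueError("inner radius must be positive")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end_point - self.start_point))

    @property
    def outer_radius(self) -> float:
        return self.inner_radius + self.wall_thickness


@dataclass
class GenerationConfig:
    """Parameters of the vascular-tree generator.

    The desk-scale default is a (100 um)^3 cube; the root radius is scaled
    to 6 um so that a single segment cannot overshoot the 3% vascular
    target by more than a small fraction of it (the 2-20 um radius span of
    the millimeter-scale geometry is available via ``root_radius=20``).
    ``taper_rate`` is the radius loss per micrometer of added vessel; the
    default 0.04 spreads the taper over the tree, while 0.5 reproduces the
    literal one-half-micrometer-per-micrometer rule.
    """

    cube_side: float = 100.0          # um
    root_radius: float = 6.0          # um
    min_radius: float = 2.0           # um
    wall_thickness: float = 2.0       # um
    taper_rate: float = 0.04          # um radius lost per um length
    step_length: float = 20.0         # um
    target_vascular_fraction: float = 0.03
    tracking_voxel_um: float = 0.5    # termination-tracking grid resolution
    max_segments: int = 50000
    stall_limit: int = 500            # consecutive zero-gain segments allowed


@dataclass
class VesselTree:
    """Geometric vessel tree prior to voxelization."""

    segments: list[VesselSegment]
    arterial_entry: np.ndarray
    venous_exit: np.ndarray
    rng_seed: int
    cube_side: float
    config: GenerationConfig = field(default_factory=GenerationConfig)


@dataclass
class VoxelPhantom:
    """Labeled voxel grid with per-label densities and provenance."""

    labels: np.ndarray               # uint8, shape (n, n, n)
    voxel_size_nm: float = 500.0
    densities_by_label: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_DENSITIES))
    metadata: dict = field(default_factory=dict)

    @property
    def voxel_size_um(self) -> float:
        return self.voxel_size_nm * 1e-3

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def cube_side_um(self) -> float:
        return self.labels.shape[0] * self.voxel_size_um

    @property
    def voxel_volume_cm3(self) -> float:
        return (self.voxel_size_nm * 1e-7) ** 3

    def label_counts(self) -> dict[int, int]:
        counts = np.bincount(self.labels.ravel(), minlength=4)
        return {lab: int(counts[lab]) for lab in (TISSUE, WALL, BLOOD, GOLD)}

    def mass_g(self, pre_placement: bool = False) -> float:
        """Total phantom mass; with ``pre_placement`` gold voxels are
        counted at the density of the compartment they replaced."""
        counts = self.label_counts()
        mass = sum(counts[lab] * self.densities_by_label[lab] * self.voxel_volume_cm3
                   for lab in (TISSUE, WALL, BLOOD))
        if counts[GOLD]:
            if pre_placement:
                hosts = self.metadata.get("gold_host_labels")
                if hosts is None:
                    raise ValueError("phantom has GOLD voxels but no host-label record")
                host_counts = np.bincount(np.asarray(hosts), minlength=4)
                mass += sum(int(host_counts[lab]) * self.densities_by_label[lab]
                            * self.voxel_volume_cm3 for lab in (TISSUE, WALL, BLOOD))
            else:
                mass += counts[GOLD] * self.densities_by_label[GOLD] * self.voxel_volume_cm3
        return mass


def _on_surface(point: np.ndarray, side: float, tol: float = 1e-9) -> bool:
    p = np.asarray(point, dtype=float)
    if (p < -tol).any() or (p > side + tol).any():
        return False
    return bool(np.any(np.abs(p) <= tol) or np.any(np.abs(p - side) <= tol))


def _paint_segment(
    occ: np.ndarray, seg_a: np.ndarray, seg_b: np.ndarray, radius: float,
    voxel_um: float, value: int = 1, overwrite: bool = False,
) -> int:
    """Mark voxels whose centers lie within ``radius`` of the segment.

    Distance is point-to-segment (rounded end caps, which also fills the
    junctions between parent and child).  Returns the number of voxels
    newly set.  Without ``overwrite`` only zero voxels are claimed.
    """
    shape = np.array(occ.shape)
    lo = np.floor((np.minimum(seg_a, seg_b) - radius) / voxel_um - 0.5).astype(int)
    hi = np.ceil((np.maximum(seg_a, seg_b) + radius) / voxel_um + 0.5).astype(int)
    lo = np.clip(lo, 0, shape)
    hi = np.clip(hi, 0, shape)
    if (hi <= lo).any():
        return 0
    ax = (np.arange(lo[0], hi[0]) + 0.5) * voxel_um
    ay = (np.arange(lo[1], hi[1]) + 0.5) * voxel_um
    az = (np.arange(lo[2], hi[2]) + 0.5) * voxel_um
    px = ax[:, None, None]
    py = ay[None, :, None]
    pz = az[None, None, :]
    u = seg_b - seg_a
    ll = float(u @ u)
    t = ((px - seg_a[0]) * u[0] + (py - seg_a[1]) * u[1] + (pz - seg_a[2]) * u[2]) / ll
    t = np.clip(t, 0.0, 1.0)
    dx = px - (seg_a[0] + t * u[0])
    dy = py - (seg_a[1] + t * u[1])
    dz = pz - (seg_a[2] + t * u[2])
    inside = dx * dx + dy * dy + dz * dz <= radius * radius
    view = occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    if overwrite:
        changed = inside & (view != value)
    else:
        changed = inside & (view == 0)
    view[changed] = value
    return int(changed.sum())


def generate_tree(
    seed: int,
    entry: np.ndarray | None = None,
    exit: np.ndarray | None = None,
    params: GenerationConfig | None = None,
) -> VesselTree:
    """Grow a random vascular tree until the target volume fraction is met.

    The RRT expansion rule: draw a uniform random point in the cube, find
    the nearest existing vertex, and extend toward the point by
    ``step_length`` (clipped at the cube faces).  The child radius tapers
    from the parent vertex radius by ``taper_rate`` per micrometer of
    segment length, floored at ``min_radius``.  Growth terminates as soon
    as the tracked vascular volume (lumen + wall, overlaps counted once)
    reaches ``target_vascular_fraction``; the vertex nearest the venous
    exit is then connected to it by a minimum-radius segment.
    """
    cfg = params or GenerationConfig()
    side = cfg.cube_side
    if entry is None:
        entry = np.array([0.0, side / 2, side / 2])
    if exit is None:
        exit = np.array([side, side / 2, side / 2])
    entry = np.asarray(entry, dtype=float)
    exit = np.asarray(exit, dtype=float)
    if not _on_surface(entry, side) or not _on_surface(exit, side):
        raise ValueError("entry and exit points must lie on the cube surface")
    if np.allclose(entry, exit):
        raise ValueError("entry and exit points must differ")
    if not 0.0 <= cfg.target_vascular_fraction < 0.5:
        raise VascularTargetError(
            f"target fraction {cfg.target_vascular_fraction} not attainable "
            "(must be in [0, 0.5) for a cylinder tree in a cube)")

    rng = np.random.default_rng(seed)
    n_track = max(int(round(side / cfg.tracking_voxel_um)), 1)
    occ = np.zeros((n_track, n_track, n_track), dtype=np.uint8)
    n_total = occ.size
    target_count = cfg.target_vascular_fraction * n_total

    vertices = [entry.copy()]
    vertex_radius = [cfg.root_radius]
    segments: list[VesselSegment] = []
    occupied = 0
    stall = 0

    while occupied < target_count:
        if len(segments) >= cfg.max_segments:
            raise VascularTargetError(
                f"vascular fraction {occupied / n_total:.4f} after "
                f"{len(segments)} segments; target "
                f"{cfg.target_vascular_fraction} unreachable with "
                f"min_radius={cfg.min_radius} in a {side} um cube")
        sample = rng.uniform(0.0, side, size=3)
        varr = np.asarray(vertices)
        d2 = np.sum((varr - sample) ** 2, axis=1)
        near = int(np.argmin(d2))
        origin = varr[near]
        delta = sample - origin
        dist = float(np.linalg.norm(delta))
        if dist < 1e-9:
            continue
        step = min(cfg.step_length, dist)
        end = origin + delta / dist * step
        end = np.clip(end, 0.0, side)
        seg_len = float(np.linalg.norm(end - origin))
        if seg_len < cfg.tracking_voxel_um:
            continue
        radius = max(cfg.min_radius, vertex_radius[near] - cfg.taper_rate * seg_len)
        parent = near - 1 if near > 0 else None
        seg = VesselSegment(origin.copy(), end, radius,
                            wall_thickness=cfg.wall_thickness, parent_index=parent)
        gained = _paint_segment(occ, origin, end, radius + cfg.wall_thickness,
                                cfg.tracking_voxel_um)
        segments.append(seg)
        vertices.append(end)
        vertex_radius.append(radius)
        occupied += gained
        stall = stall + 1 if gained == 0 else 0
        if stall >= cfg.stall_limit:
            raise VascularTargetError(
                f"no vascular volume gained over {stall} consecutive segments "
                f"at fraction {occupied / n_total:.4f}; target "
                f"{cfg.target_vascular_fraction} unreachable")

    if segments:
        varr = np.asarray(vertices)
        d2 = np.sum((varr - exit) ** 2, axis=1)
        near = int(np.argmin(d2))
        if d2[near] > 1e-12:
            parent = near - 1 if near > 0 else None
            segments.append(VesselSegment(
                varr[near].copy(), exit.copy(), cfg.min_radius,
                wall_thickness=cfg.wall_thickness, parent_index=parent))

    return VesselTree(segments=segments, arterial_entry=entry, venous_exit=exit,
                      rng_seed=int(seed), cube_side=side, config=cfg)


def voxelize(
    tree: VesselTree,
    voxel_size_nm: float = 500.0,
    memory_budget_bytes: int = 2**31,
) -> VoxelPhantom:
    """Rasterize a vessel tree into a labeled voxel phantom.

    A voxel is BLOOD if its center lies within the inner radius of any
    segment axis, else WALL if within inner radius + wall thickness, else
    TISSUE (priority BLOOD > WALL > TISSUE at junction overlaps).
    """
    voxel_um = voxel_size_nm * 1e-3
    n_f = tree.cube_side / voxel_um
    n = int(round(n_f))
    if abs(n_f - n) > 1e-6:
        raise ValueError("voxel size must divide the cube side")
    if n**3 > memory_budget_bytes:
        raise MemoryBudgetError(
            f"{n}^3 voxel grid exceeds the {memory_budget_bytes} byte budget; "
            "use voxelize_chunked or a coarser voxel size")
    labels = np.zeros((n, n, n), dtype=np.uint8)
    for seg in tree.segments:
        _paint_segment(labels, seg.start_point, seg.end_point,
                       seg.outer_radius, voxel_um, value=WALL)
    for seg in tree.segments:
        _paint_segment(labels, seg.start_point, seg.end_point,
                       seg.inner_radius, voxel_um, value=BLOOD, overwrite=True)
    meta = {
        "seed": tree.rng_seed,
        "generation": asdict(tree.config),
        "arterial_entry": tree.arterial_entry.tolist(),
        "venous_exit": tree.venous_exit.tolist(),
        "n_segments": len(tree.segments),
    }
    return VoxelPhantom(labels=labels, voxel_size_nm=voxel_size_nm, metadata=meta)


def voxelize_chunked(
    tree: VesselTree, voxel_size_nm: float, out_path, slab_voxels: int = 64
):
    """Voxelize slab-by-slab along x, streaming raw uint8 labels to disk.

    Intended for full-scale grids that do not fit the in-memory budget;
    returns the grid shape written.
    """
    voxel_um = voxel_size_nm * 1e-3
    n = int(round(tree.cube_side / voxel_um))
    with open(out_path, "wb") as fh:
        for x0 in range(0, n, slab_voxels):
            nx = min(slab_voxels, n - x0)
            slab = np.zeros((nx, n, n), dtype=np.uint8)
            shift = np.array([x0 * voxel_um, 0.0, 0.0])
            for seg in tree.segments:
                _paint_segment(slab, seg.start_point - shift, seg.end_point - shift,
                               seg.outer_radius, voxel_um, value=WALL)
            for seg in tree.segments:
                _paint_segment(slab, seg.start_point - shift, seg.end_point - shift,
                               seg.inner_radius, voxel_um, value=BLOOD, overwrite=True)
            fh.write(slab.tobytes())
    return (n, n, n)


def vascular_fraction(phantom: VoxelPhantom) -> float:
    """(BLOOD + WALL voxels) / total voxels; GOLD voxels count toward the
    compartment they replaced."""
    counts = phantom.label_counts()
    vascular = counts[BLOOD] + counts[WALL]
    hosts = phantom.metadata.get("gold_host_labels")
    if counts[GOLD]:
        if hosts is None:
            raise ValueError("GOLD voxels present but host labels not recorded")
        hc = np.bincount(np.asarray(hosts), minlength=4)
        vascular += int(hc[BLOOD]) + int(hc[WALL])
    return vascular / phantom.labels.size


def equilibrium_padding(
    spectrum: EnergySpectrum,
    stopping: StoppingTable | None = None,
    material: str = "soft_tissue_ICRU44",
    safety: float = 1.0,
) -> float:
    """Soft-tissue shell thickness (um) establishing electronic equilibrium.

    The CSDA range, in the surrounding medium, of the most energetic
    secondary electron the spectrum can produce (bounded by the maximum
    photon energy), times an optional safety factor.
    """
    stopping = stopping or StoppingTable.load()
    e_max = spectrum.max_energy
    if e_max <= 0:
        raise ValueError("degenerate spectrum with no positive-energy fluence")
    return float(stopping.csda_range_um(material, e_max)[0]) * safety
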