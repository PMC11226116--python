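"""Dose renormalization, cumulative DVHs and dose-enhancement ratios.

The reference (no-GNP) dose grid is scaled so that its minimum dose
inside the cube equals the prescription (10 Gy by default, a typical
hypofractionated/SBRT fraction); the same factor is then applied to the
GNP-loaded grid from the same beam.  Cumulative dose-volume histograms
are built per compartment (blood, vessel wall, tumor tissue; gold voxels
are excluded from the compartment masks by default) and the dose
enhancement ratio DER(V) = D_V(with GNP) / D_V(without) is evaluated at
fixed volume fractions V = 25, 50, 75%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import BLOOD, GOLD, TISSUE, WALL, LABEL_NAMES, VoxelPhantom
from .transport import DoseGrid

COMPARTMENTS = (BLOOD, WALL, TISSUE)
DEFAULT_VOLUMES = (0.25, 0.5, 0.75)


class RenormalizationError(RuntimeError):
    """Reference grid has non-positive minimum dose (undersampled run)."""


@dataclass
class CDVHCurve:
    """Cumulative dose-volume histogram of one compartment."""

    dose_gy: np.ndarray          # monotone increasing dose axis
    volume_fraction: np.ndarray  # non-increasing, starts at 1
    compartment: str = ""

    def __post_init__(self) -> None:
        self.dose_gy = np.asarray(self.dose_gy, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)


@dataclass
class DERReport:
    """Dose-enhancement ratios and average doses per compartment."""

    volumes: tuple[float, ...]
    d_with: dict[str, list[float]]
    d_without: dict[str, list[float]]
    der: dict[str, list[float]]
    average_der: dict[str, float]
    mean_dose_with: dict[str, float]
    mean_dose_without: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "volumes": list(self.volumes),
            "d_with_gy": self.d_with,
            "d_without_gy": self.d_without,
            "der": self.der,
            "average_der": self.average_der,
            "mean_dose_with_gy": self.mean_dose_with,
            "mean_dose_without_gy": self.mean_dose_without,
        }


def renormalize(reference: DoseGrid, prescription_gy: float = 10.0
                ) -> tuple[float, DoseGrid]:
    """Scale the reference grid so its minimum cube dose equals the
    prescription; returns (factor, scaled grid).

    The minimum is taken over the mass-weighted tally-cell dose (the dose
    matrix at the engine's statistical resolution); per-(cell, label)
    slivers holding a few voxels of one compartment would otherwise pin
    the minimum to counting noise.
    """
    if reference.cell_total_dose is not None:
        dmin = float(reference.cell_total_dose.min())
    else:
        dmin = float(reference.dose.min())
    if dmin <= 0.0:
        raise RenormalizationError(
            "reference grid has zero-dose regions; run more histories "
            "or coarsen the tally before renormalizing")
    factor = prescription_gy / dmin
    return factor, reference.scaled(factor)


def compartment_mask(phantom: VoxelPhantom, label: int,
                     include_gold_hosts: bool = False) -> np.ndarray:
    """Boolean voxel mask of one compartment.

    GOLD voxels are excluded unless ``include_gold_hosts``, in which case
    each gold voxel counts toward the compartment it replaced.
    """
    mask = phantom.labels == label
    if include_gold_hosts:
        idx = phantom.metadata.get("gold_voxel_indices")
        hosts = phantom.metadata.get("gold_host_labels")
        if idx is not None and len(idx):
            sel = np.asarray(idx)[np.asarray(hosts) == label]
            flat = mask.ravel()
            flat[sel] = True
            mask = flat.reshape(phantom.labels.shape)
    return mask


def cdvh(dose: DoseGrid | np.ndarray, mask: np.ndarray, bins: int = 1024,
         dose_max: float | None = None, compartment: str = "") -> CDVHCurve:
    """Cumulative DVH: volume fraction receiving at least each dose level."""
    arr = dose.dose if isinstance(dose, DoseGrid) else np.asarray(dose)
    vals = np.sort(arr[mask].ravel())
    if vals.size == 0:
        raise ValueError("empty compartment mask")
    dmax = float(dose_max if dose_max is not None else vals[-1])
    axis = np.linspace(0.0, dmax if dmax > 0 else 1.0, bins + 1)
    frac = (vals.size - np.searchsorted(vals, axis, side="left")) / vals.size
    return CDVHCurve(dose_gy=axis, volume_fraction=frac, compartment=compartment)


def dose_at_volume(curve: CDVHCurve, volume: float) -> float:
    """Largest dose received by at least the given volume fraction,
    linearly interpolated between histogram points."""
    if not 0.0 < volume < 1.0:
        raise ValueError("volume fraction must be in (0, 1)")
    frac = curve.volume_fraction
    dose = curve.dose_gy
    idx = np.flatnonzero(frac >= volume)
    if idx.size == 0:
        return float(dose[0])
    i = idx[-1]
    if i == len(dose) - 1 or frac[i] == volume:
        return float(dose[i])
    f0, f1 = frac[i], frac[i + 1]
    if f0 == f1:
        return float(dose[i + 1])
    t = (f0 - volume) / (f0 - f1)
    return float(dose[i] + t * (dose[i + 1] - dose[i]))


def dose_at_volume_exact(dose_values: np.ndarray, volume: float) -> float:
    """D_V from raw voxel doses: the largest dose d such that the volume
    fraction with dose >= d is at least V (exact sort/count, no binning)."""
    if not 0.0 < volume < 1.0:
        raise ValueError("volume fraction must be in (0, 1)")
    vals = np.sort(np.asarray(dose_values).ravel())
    n = vals.size
    if n == 0:
        raise ValueError("empty dose set")
    k = int(np.floor(n * (1.0 - volume) + 1e-12))
    return float(vals[min(k, n - 1)])


def der_report(
    with_gnp: DoseGrid,
    without_gnp: DoseGrid,
    phantom: VoxelPhantom,
    volumes: tuple[float, ...] = DEFAULT_VOLUMES,
    bins: int = 1024,
    include_gold_hosts: bool = False,
) -> DERReport:
    """Per-compartment DER at the given volume fractions plus mean doses.

    Both grids must carry the same normalization factor and geometry; the
    DVH dose axes are shared between the with/without curves so that
    DER(V) is well defined.
    """
    d_with: dict[str, list[float]] = {}
    d_without: dict[str, list[float]] = {}
    ders: dict[str, list[float]] = {}
    avg: dict[str, float] = {}
    mean_w: dict[str, float] = {}
    mean_wo: dict[str, float] = {}
    for lab in COMPARTMENTS:
        name = LABEL_NAMES[lab]
        mask = compartment_mask(phantom, lab, include_gold_hosts)
        if not mask.any():
            continue
        dw = [dose_at_volume_exact(with_gnp.dose[mask], v) for v in volumes]
        dwo = [dose_at_volume_exact(without_gnp.dose[mask], v) for v in volumes]
        d_with[name] = dw
        d_without[name] = dwo
        ders[name] = [w / wo if wo > 0 else float("nan") for w, wo in zip(dw, dwo)]
        avg[name] = float(np.mean(ders[name]))
        mean_w[name] = float(with_gnp.dose[mask].mean())
        mean_wo[name] = float(without_gnp.dose[mask].mean())
    return DERReport(volumes=tuple(volumes), d_with=d_with, d_without=d_without,
                     der=ders, average_der=avg,
                     mean_dose_with=mean_w, mean_dose_without=mean_wo)


def colorwash(dose: DoseGrid, phantom: VoxelPhantom, slice_index: int,
              path, axis: int = 2, dpi: int = 120):
    """Render a cross-sectional dose color wash over the phantom labels."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dose_sl = np.take(dose.dose, slice_index, axis=axis)
    lab_sl = np.take(phantom.labels, slice_index, axis=axis)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(dose_sl.T, origin="lower", cmap="jet")
    ax.contour(lab_sl.T, levels=[0.5, 1.5, 2.5], colors="white",
               linewidths=0.4, origin="lower")
    fig.colorbar(im, ax=ax, label="dose (Gy)")
    ax.set_title(f"slice {slice_index}")
    ax.set_xlabel("x (voxels)")
    ax.set_ylabel("y (voxels)")
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path
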