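"""Material compositions, photon interaction coefficients, electron
stopping/range data and source spectra.

All numeric data are packaged plain-text fixtures under
``vasculodose/data`` (regenerable with ``scripts/make_physics_tables.py``);
this module loads them and provides edge-aware log-log interpolation and
the elemental mixture rule.

Compositions are ICRU Report 44 soft tissue and whole blood (mass
fractions), both at 1.06 g/cm^3; gold is elemental at 19.3 g/cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

PROCESSES = ("photoelectric", "incoherent", "coherent", "pair")

#: gold K shell: edge energy, mean K x-ray energy, fluorescence yield
AU_K_EDGE_KEV = 80.7249
AU_K_XRAY_KEV = 68.8
AU_K_FLUOR_YIELD = 0.96


class TableRangeError(ValueError):
    """Requested energy lies outside a fixture table's grid."""


@dataclass(frozen=True)
class MaterialSpec:
    """A homogeneous material: elemental mass fractions and bulk density."""

    name: str
    mass_fractions: dict[str, float]
    density: float  # g/cm^3
    mean_excitation_ev: float

    def __post_init__(self) -> None:
        total = sum(self.mass_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mass fractions of {self.name} sum to {total}, not 1")


SOFT_TISSUE = MaterialSpec(
    "soft_tissue_ICRU44",
    {"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.708, "Na": 0.002,
     "P": 0.003, "S": 0.003, "Cl": 0.002, "K": 0.003},
    density=1.06, mean_excitation_ev=75.0,
)
BLOOD = MaterialSpec(
    "blood_ICRU44",
    {"H": 0.102, "C": 0.110, "N": 0.033, "O": 0.745, "Na": 0.001,
     "P": 0.001, "S": 0.002, "Cl": 0.003, "K": 0.002, "Fe": 0.001},
    density=1.06, mean_excitation_ev=75.2,
)
GOLD = MaterialSpec("gold", {"Au": 1.0}, density=19.3, mean_excitation_ev=790.0)

MATERIALS = {m.name: m for m in (SOFT_TISSUE, BLOOD, GOLD)}

#: stopping-table file stem per material name
_STOPPING_STEM = {
    "soft_tissue_ICRU44": "soft_tissue",
    "blood_ICRU44": "blood",
    "gold": "gold",
}


def _data_path(*parts: str) -> Path:
    return Path(str(resources.files("vasculodose").joinpath("data"))).joinpath(*parts)


def _interp_edge_aware(e: np.ndarray, grid: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Log-log interpolation on a grid that may contain duplicated knots.

    Duplicated energies mark absorption edges (below-edge row first).
    Queries are right-continuous at knots, so interpolation never crosses
    an edge, and a query at a tabulated energy returns the tabulated value
    exactly.  Zero values (e.g. pair production below threshold) fall back
    to linear interpolation.
    """
    e = np.atleast_1d(np.asarray(e, dtype=float))
    if (e < grid[0]).any() or (e > grid[-1]).any():
        raise TableRangeError(
            f"energy outside table range [{grid[0]}, {grid[-1]}] keV"
        )
    hi = np.searchsorted(grid, e, side="right")
    exact = hi > 0
    out = np.empty_like(e)
    # exact-knot hits: right-continuous value
    is_knot = exact & (grid[np.clip(hi - 1, 0, None)] == e)
    out[is_knot] = values[hi[is_knot] - 1]
    # interior points
    mid = ~is_knot
    lo = hi[mid] - 1
    hi_m = np.clip(hi[mid], None, len(grid) - 1)
    x0, x1 = grid[lo], grid[hi_m]
    y0, y1 = values[lo], values[hi_m]
    t = np.log(e[mid] / x0) / np.log(x1 / x0)
    pos = (y0 > 0) & (y1 > 0)
    res = np.where(
        pos,
        np.exp(np.log(np.where(y0 > 0, y0, 1.0)) * (1 - t)
               + np.log(np.where(y1 > 0, y1, 1.0)) * t),
        y0 * (1 - t) + y1 * t,
    )
    out[mid] = res
    return out


@dataclass
class AttenuationTable:
    """Per-element, per-process photon mass attenuation coefficients."""

    energies: dict[str, np.ndarray] = field(default_factory=dict)
    coefficients: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def load(cls) -> "AttenuationTable":
        table = cls()
        for path in sorted(_data_path("elements").glob("*.csv")):
            df = pd.read_csv(path, comment="#")
            sym = path.stem
            table.energies[sym] = df["energy_keV"].to_numpy()
            table.coefficients[sym] = {
                "photoelectric": df["photoelectric_cm2_g"].to_numpy(),
                "incoherent": df["incoherent_cm2_g"].to_numpy(),
                "coherent": df["coherent_cm2_g"].to_numpy(),
                "pair": df["pair_cm2_g"].to_numpy(),
            }
        return table

    def element_mu(self, symbol: str, energy_kev, process: str) -> np.ndarray:
        """Elemental mass attenuation coefficient, cm^2/g."""
        return _interp_edge_aware(
            energy_kev, self.energies[symbol], self.coefficients[symbol][process]
        )


def mixture_mu(
    material: MaterialSpec, table: AttenuationTable, energy_kev
) -> dict[str, np.ndarray]:
    """Mass attenuation coefficients of a mixture, cm^2/g per process.

    Mass-fraction-weighted sum of elemental coefficients (Bragg additivity)
    with a ``total`` entry appended.
    """
    e = np.atleast_1d(np.asarray(energy_kev, dtype=float))
    out = {p: np.zeros_like(e) for p in PROCESSES}
    for sym, w in material.mass_fractions.items():
        for p in PROCESSES:
            out[p] += w * table.element_mu(sym, e, p)
    out["total"] = sum(out[p] for p in PROCESSES)
    return out


@dataclass
class StoppingTable:
    """Electron collision stopping power and CSDA range per material."""

    energies: dict[str, np.ndarray] = field(default_factory=dict)
    stopping: dict[str, np.ndarray] = field(default_factory=dict)  # MeV cm^2/g
    csda: dict[str, np.ndarray] = field(default_factory=dict)      # g/cm^2

    @classmethod
    def load(cls) -> "StoppingTable":
        table = cls()
        for name, stem in _STOPPING_STEM.items():
            df = pd.read_csv(_data_path("stopping", f"{stem}.csv"), comment="#")
            table.energies[name] = df["energy_keV"].to_numpy()
            table.stopping[name] = df["stopping_MeV_cm2_g"].to_numpy()
            table.csda[name] = df["csda_range_g_cm2"].to_numpy()
        return table

    def stopping_power(self, material: str, energy_kev) -> np.ndarray:
        return _interp_edge_aware(energy_kev, self.energies[material], self.stopping[material])

    def csda_range(self, material: str, energy_kev) -> np.ndarray:
        """CSDA range in g/cm^2."""
        return _interp_edge_aware(energy_kev, self.energies[material], self.csda[material])

    def csda_range_um(self, material: str, energy_kev) -> np.ndarray:
        """CSDA range in micrometers at the material's bulk density."""
        rho = MATERIALS[material].density
        return self.csda_range(material, energy_kev) / rho * 1e4


@dataclass
class EnergySpectrum:
    """Tabulated photon fluence spectrum (discrete bins, weights sum to 1)."""

    energies_kev: np.ndarray
    weights: np.ndarray
    label: str = "custom"

    def __post_init__(self) -> None:
        self.energies_kev = np.asarray(self.energies_kev, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("spectrum weights must be non-negative")
        total = self.weights.sum()
        if total <= 0 or (self.energies_kev <= 0).any():
            raise ValueError("spectrum must have positive energies and total weight")
        self.weights = self.weights / total

    @classmethod
    def from_csv(cls, path: str | Path, label: str | None = None) -> "EnergySpectrum":
        df = pd.read_csv(path, comment="#")
        return cls(df["energy_keV"].to_numpy(), df["weight"].to_numpy(),
                   label=label or Path(path).stem)

    @classmethod
    def builtin(cls, name: str) -> "EnergySpectrum":
        """Load a packaged spectrum: mono_100kev, kvp_220, or mv6_fff."""
        return cls.from_csv(_data_path("spectra", f"{name}.csv"), label=name)

    @property
    def max_energy(self) -> float:
        return float(self.energies_kev[self.weights > 0].max())

    @property
    def mean_energy(self) -> float:
        return float(np.sum(self.energies_kev * self.weights))

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.weights)

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Draw bin energies with probability equal to their weights."""
        idx = np.searchsorted(self.cdf(), rng.random(size), side="right")
        return self.energies_kev[np.clip(idx, 0, len(self.energies_kev) - 1)]


def sample_energy(spectrum: EnergySpectrum, rng: np.random.Generator) -> float:
    """Draw one photon energy (keV) from the spectrum."""
    return float(spectrum.sample(rng, 1)[0])
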