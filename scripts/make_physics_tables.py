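"""Regenerate the packaged plain-text physics fixtures.

Writes, under ``src/vasculodose/data/``:

* ``elements/<Sym>.csv``   -- per-process photon mass attenuation
  coefficients (cm^2/g) on a log energy grid 1 keV - 10 MeV with duplicated
  knots at absorption edges (below-edge row first, above-edge row second);
* ``stopping/<material>.csv`` -- electron collision stopping power
  (MeV cm^2/g) and CSDA range (g/cm^2);
* ``spectra/*.csv``        -- the three source spectra.

Models (synthetic tabulations, not copies of any published table):
photoelectric from Cromer-Liberman f'' (sigma = 2 r_e lambda f''),
incoherent = Z x Klein-Nishina, coherent from a Thomas-Fermi screened
form factor, pair production from Born Bethe-Heitler, stopping from the
Bethe formula. See ``vasculodose.physics`` and ``docs/methods.md``.

Run from the repository root:  python scripts/make_physics_tables.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import gemmi  # noqa: E402

from vasculodose.physics import (  # noqa: E402
    AVOGADRO,
    HC_KEV_CM,
    R_E_CM,
    bethe_collision_stopping,
    coherent_sigma,
    csda_range,
    klein_nishina_total,
    pair_sigma,
)

DATA = Path(__file__).resolve().parents[1] / "src" / "vasculodose" / "data"

# symbol -> (Z, atomic weight, absorption edges >= 1 keV, descending not required)
ELEMENTS = {
    "H": (1, 1.008, []),
    "C": (6, 12.011, []),
    "N": (7, 14.007, []),
    "O": (8, 15.999, []),
    "Na": (11, 22.990, [1.0721]),
    "P": (15, 30.974, [2.1455]),
    "S": (16, 32.06, [2.472]),
    "Cl": (17, 35.45, [2.8224]),
    "K": (19, 39.098, [3.6074]),
    "Fe": (26, 55.845, [7.112]),
    "Au": (79, 196.967, [2.206, 2.291, 2.743, 3.148, 3.425, 11.9187, 13.7336, 14.3528, 80.7249]),
}

E_MIN, E_MAX, N_GRID = 1.0, 10000.0, 90

# material -> (composition {symbol: mass fraction}, density g/cm3, I in eV)
MATERIALS = {
    "soft_tissue": (
        {"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.708, "Na": 0.002,
         "P": 0.003, "S": 0.003, "Cl": 0.002, "K": 0.003},
        1.06, 75.0,
    ),
    "blood": (
        {"H": 0.102, "C": 0.110, "N": 0.033, "O": 0.745, "Na": 0.001,
         "P": 0.001, "S": 0.002, "Cl": 0.003, "K": 0.002, "Fe": 0.001},
        1.06, 75.2,
    ),
    "gold": ({"Au": 1.0}, 19.3, 790.0),
}


def photoelectric_mass(z: int, a: float, e_kev: float) -> float:
    """tau/rho from the imaginary anomalous scattering factor, cm^2/g."""
    _, fpp = gemmi.cromer_liberman(z=z, energy=e_kev * 1000.0)
    lam = HC_KEV_CM / e_kev
    return max(2.0 * R_E_CM * lam * fpp, 0.0) * AVOGADRO / a


def element_grid(edges: list[float]) -> tuple[np.ndarray, np.ndarray]:
    """Energy knots (keV) and per-knot evaluation energies.

    Each edge contributes two rows at the identical tabulated energy; the
    first is evaluated just below the edge, the second just above, so
    interpolation never bridges the discontinuity.
    """
    base = np.geomspace(E_MIN, E_MAX, N_GRID)
    knots = [(e, e) for e in base]
    for edge in edges:
        if E_MIN < edge < E_MAX:
            knots.append((edge, edge * (1.0 - 1e-6)))
            knots.append((edge, edge * (1.0 + 1e-6)))
    knots.sort(key=lambda p: (p[0], p[1]))
    tab = np.array([p[0] for p in knots])
    ev = np.array([p[1] for p in knots])
    return tab, ev


def write_elements() -> None:
    out = DATA / "elements"
    out.mkdir(parents=True, exist_ok=True)
    for sym, (z, a, edges) in ELEMENTS.items():
        tab, ev = element_grid(edges)
        rows = []
        for e_tab, e_ev in zip(tab, ev):
            pe = photoelectric_mass(z, a, e_ev)
            inc = z * klein_nishina_total(e_ev) * AVOGADRO / a
            coh = coherent_sigma(z, e_ev) * AVOGADRO / a
            pair = pair_sigma(z, e_ev) * AVOGADRO / a
            rows.append((e_tab, pe, inc, coh, pair))
        path = out / f"{sym}.csv"
        with path.open("w") as fh:
            fh.write(f"# synthetic photon mass attenuation table, element {sym} (Z={z}, A={a})\n")
            fh.write("# generated by scripts/make_physics_tables.py; see module docstring for models\n")
            fh.write("energy_keV,photoelectric_cm2_g,incoherent_cm2_g,coherent_cm2_g,pair_cm2_g\n")
            for r in rows:
                fh.write("%.7g,%.6e,%.6e,%.6e,%.6e\n" % r)
        print("wrote", path)


def write_stopping() -> None:
    out = DATA / "stopping"
    out.mkdir(parents=True, exist_ok=True)
    e = np.geomspace(1.0, 10000.0, 160)
    for name, (comp, _rho, i_ev) in MATERIALS.items():
        z_over_a = sum(w * ELEMENTS[s][0] / ELEMENTS[s][1] for s, w in comp.items())
        s = bethe_collision_stopping(e, z_over_a, i_ev)
        r = csda_range(e, s)
        path = out / f"{name}.csv"
        with path.open("w") as fh:
            fh.write(f"# synthetic electron stopping/range table, material {name}\n")
            fh.write(f"# Bethe collision stopping, Z/A={z_over_a:.5f}, I={i_ev} eV, no density effect\n")
            fh.write("energy_keV,stopping_MeV_cm2_g,csda_range_g_cm2\n")
            for ei, si, ri in zip(e, s, r):
                fh.write("%.7g,%.6e,%.6e\n" % (ei, si, ri))
        print("wrote", path)


def _mu_rho(sym_z_a: tuple[int, float], e: np.ndarray) -> np.ndarray:
    z, a = sym_z_a
    return np.array(
        [photoelectric_mass(z, a, ei) + z * klein_nishina_total(ei) * AVOGADRO / a
         + coherent_sigma(z, ei) * AVOGADRO / a for ei in e]
    )


def write_spectra() -> None:
    out = DATA / "spectra"
    out.mkdir(parents=True, exist_ok=True)

    # monoenergetic 100 keV
    with (out / "mono_100kev.csv").open("w") as fh:
        fh.write("# monoenergetic 100 keV photon source\nenergy_keV,weight\n100.0,1.0\n")

    # 220 kVp tungsten-anode tube: Kramers continuum filtered by 2 mm Al +
    # 0.3 mm Cu, plus W K characteristic lines (synthetic representative
    # spectrum; replace via a user CSV for a measured tube)
    e = np.arange(12.0, 221.0, 2.0)
    kramers = np.clip(220.0 / e - 1.0, 0.0, None)
    mu_al = _mu_rho((13, 26.982), e) * 2.699
    mu_cu = _mu_rho((29, 63.546), e) * 8.96
    flu = kramers * np.exp(-mu_al * 0.2 - mu_cu * 0.03)
    flu /= flu.sum()
    lines = {58.0: 0.025, 59.3: 0.045, 67.2: 0.020}
    flu *= 1.0 - sum(lines.values())
    e_list = list(e)
    w_list = list(flu)
    for le, lw in lines.items():
        e_list.append(le)
        w_list.append(lw)
    order = np.argsort(e_list)
    with (out / "kvp_220.csv").open("w") as fh:
        fh.write("# synthetic 220 kVp tungsten-anode spectrum, 2 mm Al + 0.3 mm Cu filtration\n")
        fh.write("# Kramers continuum + W K lines; representative, not a measured tube\n")
        fh.write("energy_keV,weight\n")
        for i in order:
            if w_list[i] > 1e-12:
                fh.write("%.4g,%.6e\n" % (e_list[i], w_list[i]))

    # 6 MV FFF linac: analytic bremsstrahlung-shaped histogram,
    # fluence ~ E * exp(-E/650 keV) truncated at 6 MeV (mean ~1.3 MeV)
    e = np.arange(75.0, 6001.0, 50.0)
    flu = e * np.exp(-e / 650.0)
    flu /= flu.sum()
    with (out / "mv6_fff.csv").open("w") as fh:
        fh.write("# synthetic 6 MV flattening-filter-free linac spectrum\n")
        fh.write("# analytic representative shape (mean ~1.3 MeV), not a measured beam\n")
        fh.write("energy_keV,weight\n")
        for ei, wi in zip(e, flu):
            if wi > 1e-12:
                fh.write("%.6g,%.6e\n" % (ei, wi))
    print("wrote spectra")


if __name__ == "__main__":
    write_elements()
    write_stopping()
    write_spectra()
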