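"""Closed-form photon and electron interaction models.

These are the compact analytic parametrizations from which the packaged
plain-text cross-section fixtures are generated (see
``scripts/make_physics_tables.py``) and against which the transport engine
is cross-checked:

* incoherent scattering -- Klein-Nishina on free electrons (one per Z);
* coherent scattering  -- Thomson differential cross section modulated by
  a Thomas-Fermi screened hydrogenic atomic form factor;
* pair production      -- Born-approximation Bethe-Heitler (no screening),
  clamped to zero below and near the 1022 keV threshold;
* electron collision stopping power -- relativistic Bethe formula without
  density-effect correction, integrated to CSDA range.

Photoelectric absorption is not modeled in closed form here; the fixture
generator derives it from Cromer-Liberman anomalous-scattering factors
(sigma = 2 r_e lambda f'') which carry the full edge structure.

Units: energies keV, cross sections cm^2 (per atom or per electron as
stated), mass coefficients cm^2/g, stopping power MeV cm^2/g.
"""

from __future__ import annotations

import numpy as np

# physical constants
ELECTRON_REST_KEV = 510.99895
R_E_CM = 2.8179403262e-13          # classical electron radius
AVOGADRO = 6.02214076e23
FINE_STRUCTURE = 7.2973525693e-3
BOHR_RADIUS_CM = 5.29177210903e-9
HC_KEV_CM = 12.398419843320026e-8  # h*c in keV*cm
THOMSON_CM2 = 6.6524587321e-25     # Thomson cross section per electron
MEV_TO_J = 1.602176634e-13


def klein_nishina_total(energy_kev: float | np.ndarray) -> float | np.ndarray:
    """Total Klein-Nishina cross section per free electron, cm^2."""
    k = np.asarray(energy_kev, dtype=float) / ELECTRON_REST_KEV
    t1 = (1.0 + k) / k**2 * (2.0 * (1.0 + k) / (1.0 + 2.0 * k) - np.log1p(2.0 * k) / k)
    t2 = np.log1p(2.0 * k) / (2.0 * k)
    t3 = -(1.0 + 3.0 * k) / (1.0 + 2.0 * k) ** 2
    sigma = 2.0 * np.pi * R_E_CM**2 * (t1 + t2 + t3)
    return sigma if np.ndim(energy_kev) else float(sigma)


def klein_nishina_mean_recoil_fraction(energy_kev: float, n_quad: int = 4096) -> float:
    """Mean fraction of the photon energy given to the Compton recoil electron.

    Numeric quadrature of the Klein-Nishina energy-differential cross
    section; serves as an independent oracle for the transport sampler.
    """
    k = energy_kev / ELECTRON_REST_KEV
    # integrate over scattered-photon fraction x = E'/E in [1/(1+2k), 1]
    x_lo = 1.0 / (1.0 + 2.0 * k)
    x = np.linspace(x_lo, 1.0, n_quad)
    # dsigma/dx ~ (1/x^2)*(x + 1/x + cos^2 - 1) with cos from Compton relation
    cost = 1.0 - (1.0 / x - 1.0) / k
    ds = (x + 1.0 / x - 1.0 + cost**2) / x**0 * (x / x)  # KN kernel below
    ds = (x + 1.0 / x + cost**2 - 1.0)
    w = np.trapezoid(ds, x)
    mean_x = np.trapezoid(x * ds, x) / w
    return 1.0 - mean_x


def coherent_sigma(z: int, energy_kev: float, n_quad: int = 2048) -> float:
    """Coherent (Rayleigh) cross section per atom, cm^2.

    Thomson angular distribution weighted by the square of a screened
    hydrogenic form factor F(q) = Z / (1 + (a q / 2)^2)^2 with the
    Thomas-Fermi screening length a = 0.885 a0 Z^(-1/3).
    """
    a = 0.885 * BOHR_RADIUS_CM * z ** (-1.0 / 3.0)
    kwave = 2.0 * np.pi * energy_kev / HC_KEV_CM  # 1/cm
    mu = np.linspace(-1.0, 1.0, n_quad)  # cos(theta)
    q = 2.0 * kwave * np.sqrt((1.0 - mu) / 2.0)
    ff = z / (1.0 + (a * q / 2.0) ** 2) ** 2
    integrand = 0.5 * R_E_CM**2 * (1.0 + mu**2) * ff**2
    return float(2.0 * np.pi * np.trapezoid(integrand, mu))


def pair_sigma(z: int, energy_kev: float) -> float:
    """Pair-production cross section per atom (nuclear field), cm^2.

    Born-approximation Bethe-Heitler without screening; adequate between
    threshold and ~10 MeV. Negative values of the asymptotic expression
    near threshold are clamped to zero.
    """
    if energy_kev <= 2.0 * ELECTRON_REST_KEV:
        return 0.0
    k = energy_kev / ELECTRON_REST_KEV
    val = FINE_STRUCTURE * R_E_CM**2 * z**2 * (28.0 / 9.0 * np.log(2.0 * k) - 218.0 / 27.0)
    return float(max(val, 0.0))


def bethe_collision_stopping(
    energy_kev: float | np.ndarray, z_over_a: float, mean_excitation_ev: float
) -> float | np.ndarray:
    """Electron collision mass stopping power, MeV cm^2/g (Bethe, no delta).

    Below the energy where the Bethe logarithm turns over the value is
    continued with a T^-0.8 power law to keep the table positive and
    monotone at the sub-keV tail.
    """
    t = np.atleast_1d(np.asarray(energy_kev, dtype=float)) / ELECTRON_REST_KEV
    i_ratio = mean_excitation_ev * 1e-3 / ELECTRON_REST_KEV  # I / (m c^2)
    beta2 = 1.0 - 1.0 / (1.0 + t) ** 2
    arg = t**2 * (t + 2.0) / (2.0 * i_ratio**2)
    fminus = 1.0 - beta2 + (t**2 / 8.0 - (2.0 * t + 1.0) * np.log(2.0)) / (t + 1.0) ** 2
    lterm = np.log(np.maximum(arg, 1.0 + 1e-12)) + fminus
    s = 0.153536 * z_over_a / beta2 * lterm
    # power-law continuation below the validity floor
    valid = (arg > np.e) & (s > 0)
    if not valid.all():
        idx = np.argmax(valid)
        t_floor = t[idx]
        s_floor = s[idx]
        bad = ~valid
        s[bad] = s_floor * (t[bad] / t_floor) ** (-0.8)
    out = s
    return out if np.ndim(energy_kev) else float(out[0])


def csda_range(energies_kev: np.ndarray, stopping_mev_cm2_g: np.ndarray) -> np.ndarray:
    """CSDA range in g/cm^2 by trapezoidal integration of 1/S over energy.

    The range at the first grid point is seeded with T0/S(T0).
    """
    e_mev = np.asarray(energies_kev, dtype=float) * 1e-3
    inv_s = 1.0 / np.asarray(stopping_mev_cm2_g, dtype=float)
    r = np.empty_like(e_mev)
    r[0] = e_mev[0] * inv_s[0]
    increments = np.diff(e_mev) * 0.5 * (inv_s[1:] + inv_s[:-1])
    r[1:] = r[0] + np.cumsum(increments)
    return r
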