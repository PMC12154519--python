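"""Photon attenuation data for the materials in the camera model.

Mass attenuation coefficients (total, with coherent scattering) are stored on a
coarse energy grid taken from the standard NIST compilations and interpolated
log-log, which is accurate to a few percent between grid points in the
60-700 keV range relevant to Lu-177 imaging.  The tables are deliberately
small: the transport engine only ever needs water (phantom bodies), tungsten
(shield and aperture) and the scintillator (GAGG by default, CsI(Na) as an
alternative).

All public functions accept scalar or array energies in keV.  Linear
attenuation coefficients are returned per millimetre, the length unit used
throughout the package.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "MATERIALS",
    "mass_attenuation",
    "linear_attenuation_mm",
    "register_material",
]

# energy grid in keV shared by all tables
_ENERGIES = np.array([60.0, 80.0, 100.0, 150.0, 200.0, 300.0, 400.0, 500.0, 662.0])

# mass attenuation mu/rho in cm^2/g on the grid above, and density in g/cm^3.
# Tungsten's K edge (69.5 keV) sits between the first two grid points; the
# 60 keV entry is below-edge and only the >=73 keV imaging window matters here.
_TABLES: dict[str, dict] = {
    "water": {
        "density": 1.0,
        "mu_rho": np.array(
            [0.2059, 0.1837, 0.1707, 0.1505, 0.1370, 0.1186, 0.1061, 0.0969, 0.0857]
        ),
    },
    "tungsten": {
        "density": 19.3,
        "mu_rho": np.array(
            [3.713, 7.810, 4.438, 1.581, 0.7844, 0.3238, 0.1925, 0.1378, 0.0950]
        ),
    },
    # Gd3Al2Ga3O12 ceramic scintillator
    "gagg": {
        "density": 6.63,
        "mu_rho": np.array(
            [1.37, 2.76, 1.61, 0.623, 0.344, 0.181, 0.133, 0.110, 0.090]
        ),
    },
    "csi": {
        "density": 4.51,
        "mu_rho": np.array(
            [1.50, 3.03, 1.76, 0.676, 0.368, 0.190, 0.137, 0.112, 0.091]
        ),
    },
}

MATERIALS = tuple(sorted(_TABLES))


def register_material(name: str, energies_kev, mu_rho_cm2_g, density_g_cm3: float) -> None:
    """Register (or override) a material table.

    Intended for config-driven overrides; energies must be strictly increasing
    and all values positive.
    """
    e = np.asarray(energies_kev, dtype=float)
    m = np.asarray(mu_rho_cm2_g, dtype=float)
    if e.ndim != 1 or e.size < 2 or np.any(np.diff(e) <= 0):
        raise ValueError("energies must be a strictly increasing 1-D grid")
    if m.shape != e.shape or np.any(m <= 0):
        raise ValueError("mu/rho values must be positive and match the energy grid")
    if density_g_cm3 <= 0:
        raise ValueError("density must be positive")
    _TABLES[name.lower()] = {"density": float(density_g_cm3), "mu_rho": m, "energies": e}


def _table(material: str) -> dict:
    try:
        return _TABLES[material.lower()]
    except KeyError:
        raise KeyError(
            f"unknown material {material!r}; known: {sorted(_TABLES)}"
        ) from None


def mass_attenuation(material: str, energy_kev):
    """Total mass attenuation coefficient mu/rho in cm^2/g, log-log interpolated."""
    tab = _table(material)
    e_grid = tab.get("energies", _ENERGIES)
    e = np.asarray(energy_kev, dtype=float)
    if np.any(e <= 0):
        raise ValueError("energy must be positive")
    if np.any(e < e_grid[0] - 1e-9) or np.any(e > e_grid[-1] + 1e-9):
        raise ValueError(
            f"energy {np.min(e)}-{np.max(e)} keV outside the tabulated "
            f"{e_grid[0]}-{e_grid[-1]} keV range for {material!r}"
        )
    out = np.exp(np.interp(np.log(e), np.log(e_grid), np.log(tab["mu_rho"])))
    return float(out) if np.isscalar(energy_kev) else out


def linear_attenuation_mm(material: str, energy_kev):
    """Linear attenuation coefficient in mm^-1 at the given energy."""
    tab = _table(material)
    return mass_attenuation(material, energy_kev) * tab["density"] / 10.0


def density(material: str) -> float:
    return _table(material)["density"]
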