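"""Tabulated mass attenuation and transmission for marker materials.

Ships a small plain-text table of the total mass attenuation coefficient of
gold (the standard fiducial-marker material) over 6000-7000 eV, interpolated
log-log. Used to quantify how strongly a non-edge element's contrast is
suppressed in a dual-energy difference map.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

_TABLES = {"Au": "au_mass_attenuation.tsv"}


def mass_attenuation(material: str, energy_eV: float | np.ndarray) -> np.ndarray:
    """Total mass attenuation coefficient mu/rho in cm^2/g (log-log interp)."""
    if material not in _TABLES:
        raise KeyError(f"no attenuation table for {material!r}")
    path = resources.files("txmkit.data") / _TABLES[material]
    table = np.loadtxt(str(path))
    e_tab, mu_tab = table[:, 0], table[:, 1]
    e = np.asarray(energy_eV, dtype=float)
    if np.any(e < e_tab[0]) or np.any(e > e_tab[-1]):
        raise ValueError(
            f"energy outside tabulated range [{e_tab[0]}, {e_tab[-1]}] eV"
        )
    return np.exp(np.interp(np.log(e), np.log(e_tab), np.log(mu_tab)))


def transmission(
    material: str,
    thickness_um: float,
    density_g_cm3: float,
    energy_eV: float | np.ndarray,
) -> np.ndarray:
    """Beer-Lambert transmission of a uniform slab at the given energies."""
    mu_rho = mass_attenuation(material, energy_eV)
    t_cm = thickness_um * 1e-4
    return np.exp(-mu_rho * density_g_cm3 * t_cm)
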