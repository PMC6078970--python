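"""Physical constants and small composition-arithmetic helpers.

Concentrations are molar (M) throughout the package; lengths entering
diffusion formulas are in meters, scattering lengths in arbitrary but
mutually consistent absolute-intensity units.
"""

from __future__ import annotations

import math

from scipy.constants import Avogadro as N_A  # noqa: F401  (re-exported)
from scipy.constants import R, k as K_B  # noqa: F401

#: Reference room temperature (K) used for k_B*T0 unit conversions.
T0 = 298.0

#: Molarity of a 1 g/L solution of CCMV coat-protein dimers (M).
SUBUNIT_MOLARITY_PER_GRAM_PER_LITRE = 24.6e-6

#: Molar ratio per unit subunit-to-genome mass ratio for CCMV
#: (molar ratio 150 at mass ratio 6).
CCMV_MOLAR_PER_MASS_RATIO = 25.0

#: Molar mass of a styrene-sulfonic-acid repeat unit (g/mol), acid form.
STYRENE_SULFONATE_REPEAT_MASS = 184.2


def mass_conc_to_molar(
    grams_per_litre: float,
    molarity_per_gram_per_litre: float = SUBUNIT_MOLARITY_PER_GRAM_PER_LITRE,
) -> float:
    """Convert a mass concentration (g/L) to molarity (M).

    The default conversion factor is the CCMV coat-protein dimer one.
    """
    if grams_per_litre < 0:
        raise ValueError("mass concentration must be non-negative")
    return grams_per_litre * molarity_per_gram_per_litre


def capsid_dimer_count(t_number: int = 3) -> int:
    """Number of dimeric subunits in a T-numbered icosahedral capsid.

    Caspar-Klug counting gives 60*T monomers, i.e. 30*T dimers.
    """
    if t_number < 1:
        raise ValueError("triangulation number must be >= 1")
    monomers = 60 * t_number
    if monomers % 2:
        raise ValueError("odd monomer count cannot be grouped into dimers")
    return monomers // 2


def polyelectrolyte_charge_count(
    chain_mass: float,
    repeat_mass: float = STYRENE_SULFONATE_REPEAT_MASS,
    charge_fraction: float = 0.95,
    round_to: int | None = 100,
) -> float:
    """Average number of charged groups on a polyelectrolyte chain.

    Parameters
    ----------
    chain_mass : float
        Molar mass of the full chain (g/mol).
    repeat_mass : float
        Molar mass of one (charge-bearing) repeat unit (g/mol).
    charge_fraction : float
        Fraction of repeat units actually carrying a charge
        (degree of sulfonation for PSS).
    round_to : int, optional
        Round the result to the nearest multiple; ``None`` disables rounding.
    """
    if chain_mass <= 0 or repeat_mass <= 0:
        raise ValueError("masses must be positive")
    if not 0 <= charge_fraction <= 1:
        raise ValueError("charge fraction must lie in [0, 1]")
    charges = chain_mass / repeat_mass * charge_fraction
    if round_to:
        charges = round(charges / round_to) * round_to
    return float(charges)


def celsius_to_kelvin(t_celsius: float) -> float:
    return t_celsius + 273.15


def joule_per_mol_to_kbt0(energy: float, t0: float = T0) -> float:
    """Convert a molar energy (J/mol) to units of k_B*T0."""
    return energy / (R * t0)


def kbt0_to_joule_per_mol(energy_kbt0: float, t0: float = T0) -> float:
    return energy_kbt0 * R * t0


def sphere_radius_from_rg(rg: float) -> float:
    """Radius of a homogeneous sphere with the given radius of gyration."""
    return math.sqrt(5.0 / 3.0) * rg
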