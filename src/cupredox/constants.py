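"""Physical constants and unit conversions used throughout the package.

All lengths are in angstrom, charges in elementary charges (e), energies in
kcal/mol unless noted. Potentials inside the solver are dimensionless (kT/e).
"""

from __future__ import annotations

import math

from scipy import constants as _sc

#: Coulomb constant in kcal*A/(mol*e^2): energy of two unit charges 1 A apart in vacuum.
COULOMB_KCAL_A: float = 332.0637

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE: float = 298.15

#: Gas constant in kcal/(mol*K).
R_KCAL: float = _sc.R / (_sc.calorie * 1000.0)

#: mV of electrode potential per kcal/mol for a one-electron couple
#: (1 kcal/mol / F expressed in mV).
MV_PER_KCAL: float = 43.364

#: Solvent probe radius for the molecular (solvent-excluded) surface, A.
DEFAULT_PROBE_RADIUS: float = 1.4

#: Interior (protein) and exterior (solvent) dielectric constants.
DEFAULT_EPS_IN: float = 4.0
DEFAULT_EPS_OUT: float = 78.0

#: Ion-exclusion (Stern) layer thickness, A.
DEFAULT_STERN_LAYER: float = 2.0

#: Default ionic strength, mol/L (1:1 salt).
DEFAULT_IONIC_STRENGTH: float = 0.15


def kT_kcal(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy kT in kcal/mol at the given temperature."""
    return R_KCAL * temperature


def debye_length(
    ionic_strength: float,
    eps_solvent: float = DEFAULT_EPS_OUT,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Debye screening length in A for a 1:1 electrolyte.

    ``kappa^-1 = sqrt(eps0*eps_r*kB*T / (2*e^2*I*NA))`` with the ionic
    strength ``I`` in mol/L.  Returns ``inf`` for zero ionic strength.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    if ionic_strength == 0:
        return math.inf
    i_si = ionic_strength * 1000.0 * _sc.N_A  # ions / m^3
    lam2 = (_sc.epsilon_0 * eps_solvent * _sc.k * temperature) / (
        2.0 * _sc.e**2 * i_si
    )
    return math.sqrt(lam2) * 1e10
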