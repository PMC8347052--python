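"""Physical constants, titratable-class definitions and default model pKas.

All energies are in kcal/mol, distances in Å, charges in elementary units.
"""

from __future__ import annotations

import math

#: ln(10); Wyman-linkage prefactor is LN10 * kT ("2.3 kT" in shorthand).
LN10 = math.log(10.0)

#: Coulomb constant e^2/(4 pi eps0) in kcal·Å/mol for unit charges.
COULOMB_KCAL_A = 332.0636

#: Gas constant in kcal/(mol·K).
R_KCAL = 1.9872041e-3

#: Default absolute temperature (K) and the corresponding kT (kcal/mol).
DEFAULT_T = 298.15
DEFAULT_KT = R_KCAL * DEFAULT_T  # ~0.5925 kcal/mol


def kt_from_temperature(temperature: float) -> float:
    """kT in kcal/mol at the given absolute temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature


def debye_kappa(ionic_strength: float, dielectric: float,
                temperature: float = DEFAULT_T) -> float:
    """Inverse Debye length in Å^-1 for a uniform-dielectric medium.

    kappa^2 = 8 pi e^2 N_A I / (eps eps0 kB T); with the Coulomb constant in
    kcal·Å/mol this reduces to kappa^2 = 8 pi * COULOMB * I_molar * 1e-27 *
    N_A / (eps * kT). At eps=78.5, T=298.15 K, I=0.15 M this gives the
    familiar ~0.127 Å^-1 (Debye length ~7.9 Å).
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be non-negative")
    if ionic_strength == 0:
        return 0.0
    kt = kt_from_temperature(temperature)
    avogadro = 6.02214076e23
    # mol/L -> charges per Å^3: * N_A * 1e-27
    rho = ionic_strength * avogadro * 1e-27
    kappa_sq = 8.0 * math.pi * COULOMB_KCAL_A * rho / (dielectric * kt)
    return math.sqrt(kappa_sq)


# --- titratable classes -------------------------------------------------

ACID = "acid"
BASE = "base"

#: class label -> (polarity, default model pKa)
TITRATABLE_CLASSES: dict[str, tuple[str, float]] = {
    "ASP": (ACID, 3.8),
    "GLU": (ACID, 4.5),
    "HIS": (BASE, 6.5),
    "CYS": (ACID, 9.0),
    "TYR": (ACID, 10.0),
    "LYS": (BASE, 10.5),
    "ARG": (BASE, 12.5),
    "NTERM": (BASE, 8.0),
    "CTERM": (ACID, 3.6),
}

DEFAULT_MODEL_PKA: dict[str, float] = {
    cls: pka for cls, (_, pka) in TITRATABLE_CLASSES.items()
}

#: residue-class groups used for the free-energy decomposition
CLASS_GROUPS: dict[str, frozenset[str]] = {
    "acidic": frozenset({"ASP", "GLU", "CYS", "TYR", "CTERM"}),
    "his": frozenset({"HIS"}),
    "basic": frozenset({"LYS", "ARG", "NTERM"}),
}

#: atoms whose midpoint defines the charge center of each side-chain class
CHARGE_CENTER_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "ARG": ("CZ",),
    "CYS": ("SG",),
    "TYR": ("OH",),
}

#: minimum inter-charge distance (Å); shorter distances are clamped so the
#: screened-Coulomb coupling stays finite on imperfect geometries
CLASH_FLOOR_A = 2.0

#: default uniform dielectric and ionic strength for the coupling matrix
DEFAULT_DIELECTRIC = 20.0
DEFAULT_IONIC_STRENGTH = 0.15

#: exact-enumeration site cap (2^N microstates)
ENUMERATION_CAP = 16
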