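"""Closed-form 1:1 ligand-depletion binding mathematics and shared unit plumbing.

All fitting modules in this package reduce to the same equilibrium: a fixed,
observed species U (the isotope-labeled or fluorophore-labeled subunit) binds
a titrated ligand L with dissociation constant ``Kd``.  Because U is not in
vast excess over L (or vice versa) in membrane-protein titrations, the free
ligand concentration cannot be approximated by the total, and the bound
fraction is the root of a quadratic in the complex concentration::

    f_b = [(Kd + L0 + U0) - sqrt((Kd + L0 + U0)^2 - 4*U0*L0)] / (2*U0)

For species confined to a membrane mimetic the natural concentration unit is
mole percent relative to the long-chain lipid (mol%); soluble ligands such as
the talin F3 domain are handled in µM.  Units are carried explicitly and
mixing them is a hard error.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Unit",
    "BindingParameters",
    "ConcentrationPair",
    "ShiftPerturbation",
    "UnitMismatchError",
    "bound_fraction",
    "predicted_response",
    "hybrid_shift",
    "mol_percent",
    "bicelle_lipid_molarity",
]


class Unit(str, enum.Enum):
    """Concentration unit tag. Exactly one of mol% or µM."""

    MOL_PERCENT = "mol%"
    MICROMOLAR = "µM"

    @classmethod
    def coerce(cls, value: "Unit | str") -> "Unit":
        if isinstance(value, cls):
            return value
        aliases = {"mol%": cls.MOL_PERCENT, "molpercent": cls.MOL_PERCENT,
                   "µM": cls.MICROMOLAR, "uM": cls.MICROMOLAR, "um": cls.MICROMOLAR}
        try:
            return aliases[str(value)]
        except KeyError:
            raise ValueError(
                f"unknown concentration unit {value!r}; expected 'mol%' or 'µM'"
            ) from None


class UnitMismatchError(ValueError):
    """Raised when quantities with different concentration units are combined."""


def _check_units(a: Unit, b: Unit) -> None:
    if a is not b:
        raise UnitMismatchError(f"concentration units differ: {a.value} vs {b.value}")


@dataclass(frozen=True)
class BindingParameters:
    """Dissociation constant plus saturation response of one reporter.

    ``delta_max`` is in ppm for chemical-shift reporters, dimensionless for
    normalized intensities, and in anisotropy units for fluorescence.
    """

    kd: float
    delta_max: float = 1.0
    unit: Unit = Unit.MOL_PERCENT

    def __post_init__(self):
        object.__setattr__(self, "unit", Unit.coerce(self.unit))
        if not (self.kd >= 0):
            raise ValueError(f"kd must be >= 0, got {self.kd}")
        if not math.isfinite(self.delta_max):
            raise ValueError("delta_max must be finite")


@dataclass(frozen=True)
class ConcentrationPair:
    """Fixed observed-species concentration u0 and titrant concentration l0."""

    u0: float
    l0: float
    unit: Unit = Unit.MOL_PERCENT

    def __post_init__(self):
        object.__setattr__(self, "unit", Unit.coerce(self.unit))
        if not (self.u0 > 0):
            raise ValueError(f"u0 must be > 0, got {self.u0}")
        if self.l0 < 0:
            raise ValueError(f"l0 must be >= 0, got {self.l0}")


@dataclass(frozen=True)
class ShiftPerturbation:
    """Amide 1H/15N chemical shift changes with hybrid-shift weights.

    Default weights w_h = 1 and w_n = 0.154 reflect the ~6.5-fold smaller
    dispersion of 15N shifts (in ppm) relative to 1H for backbone amides.
    """

    delta_h: float
    delta_n: float
    w_h: float = 1.0
    w_n: float = 0.154

    def __post_init__(self):
        if self.w_h <= 0 or self.w_n <= 0:
            raise ValueError("hybrid shift weights must be positive")


def bound_fraction_raw(kd, u0, l0):
    """Vectorized bound fraction of the observed species, no unit checks.

    Uses the algebraically equivalent form 2*l0 / (b + sqrt(b^2 - 4*u0*l0))
    with b = kd + u0 + l0, which avoids catastrophic cancellation when the
    bound fraction is small.  The discriminant is clipped at zero against
    roundoff.
    """
    kd = np.asarray(kd, dtype=float)
    u0 = np.asarray(u0, dtype=float)
    l0 = np.asarray(l0, dtype=float)
    if np.any(u0 <= 0):
        raise ValueError("u0 must be > 0")
    if np.any(l0 < 0) or np.any(kd < 0):
        raise ValueError("kd and l0 must be >= 0")
    b = kd + u0 + l0
    disc = np.maximum(b * b - 4.0 * u0 * l0, 0.0)
    denom = b + np.sqrt(disc)
    with np.errstate(invalid="ignore"):
        fb = np.where(denom > 0, 2.0 * l0 / denom, 0.0)
    return np.clip(fb, 0.0, 1.0)


def bound_fraction(params: BindingParameters, conc: ConcentrationPair) -> float:
    """Fraction of the observed species bound at equilibrium, in [0, 1]."""
    _check_units(params.unit, conc.unit)
    return float(bound_fraction_raw(params.kd, conc.u0, conc.l0))


def predicted_response(params: BindingParameters, conc: ConcentrationPair) -> float:
    """Observable change delta_max * f_b; tends to delta_max as l0 -> inf."""
    return params.delta_max * bound_fraction(params, conc)


def hybrid_shift(p: ShiftPerturbation, form: str = "rms") -> float:
    """Weighted hybrid 1H/15N amide shift (ppm), symmetric in sign.

    ``form='rms'`` (default): sqrt((w_h^2 dH^2 + w_n^2 dN^2) / 2).
    ``form='quadrature'``: sqrt(dH^2 + (w_n*dN)^2), the other convention in
    common use; the two differ only by peak-independent scaling for the
    default weights, so fitted Kd values are unaffected by the choice.
    """
    if form == "rms":
        return math.sqrt((p.w_h**2 * p.delta_h**2 + p.w_n**2 * p.delta_n**2) / 2.0)
    if form == "quadrature":
        return math.sqrt((p.w_h * p.delta_h) ** 2 + (p.w_n * p.delta_n) ** 2)
    raise ValueError(f"unknown hybrid shift form {form!r}")


def mol_percent(protein_molar: float, lipid_molar: float) -> float:
    """Protein concentration as (moles protein x 100) / (moles long-chain lipid).

    The caller must already have excluded short-chain detergent (e.g. D6PC)
    from ``lipid_molar``: detergent is not counted as lipid in this
    convention.  Both inputs must share the same molarity unit.
    """
    if lipid_molar <= 0:
        raise ValueError("lipid_molar must be > 0")
    if protein_molar < 0:
        raise ValueError("protein_molar must be >= 0")
    return protein_molar * 100.0 / lipid_molar


def bicelle_lipid_molarity(
    total_wv_percent: float, q: float, mw_long: float, mw_short: float
) -> float:
    """Long-chain lipid molarity (mol/L) of a two-component bicelle mix.

    Solves the mass balance mw_long*x + mw_short*(x/q) = 10*total_wv_percent
    g/L, where ``q`` is the long-chain/short-chain mole ratio and
    ``total_wv_percent`` is the total amphiphile in % w/v (1% w/v = 10 g/L).

    For a three-component long-chain mixture (e.g. POPC:POPS 2:1) pass the
    mole-fraction-weighted mean molecular weight as ``mw_long``.
    """
    if min(total_wv_percent, q, mw_long, mw_short) <= 0:
        raise ValueError("all bicelle composition inputs must be > 0")
    grams_per_litre = 10.0 * total_wv_percent
    return grams_per_litre / (mw_long + mw_short / q)


# Molecular weights (g/mol) of the amphiphiles used throughout this package.
MW_DMPC = 677.9
MW_D6PC = 453.5
MW_POPC = 760.1
MW_POPS = 784.0


def popc_pops_mean_mw(popc_to_pops: float = 2.0) -> float:
    """Mole-fraction-weighted mean MW of a POPC:POPS long-chain mixture."""
    if popc_to_pops <= 0:
        raise ValueError("popc_to_pops must be > 0")
    return (popc_to_pops * MW_POPC + MW_POPS) / (popc_to_pops + 1.0)
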