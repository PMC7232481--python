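"""Substrate-side bookkeeping for a defined-substrate digester.

Covers trace-element contributions of the individual substrate components,
the Buswell stoichiometry that converts COD to a theoretical methane volume,
VFA unit conversions (mM to mg/L), and the overall COD balance.

All gas volumes are at dry normal conditions (0 degC, 1 atm), where one mole
of ideal gas occupies 22.414 L and one mole of CH4 is equivalent to 64 g COD
(CH4 + 2 O2 -> CO2 + 2 H2O), giving the canonical 350 mL CH4 per g COD.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "ELEMENTS",
    "ACIDS",
    "AcidSpec",
    "SubstrateTable",
    "SUBSTRATE_TE_TABLE",
    "MOLAR_VOLUME_ML",
    "COD_PER_MOL_CH4_G",
    "round_sig",
    "total_contribution",
    "vfa_mM_to_mgL",
    "vfa_mgL_to_mM",
    "cod_methane_volume",
    "buswell",
    "cod_balance",
]

ELEMENTS = ("Co", "Ni", "Se", "W")

#: Ideal-gas molar volume at 0 degC, 1 atm (mL/mol).
MOLAR_VOLUME_ML = 22414.0
#: COD equivalent of one mole of methane (g O2/mol CH4).
COD_PER_MOL_CH4_G = 64.0

_ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999}


@dataclass(frozen=True)
class AcidSpec:
    """A volatile fatty acid and the molar mass used in all conversions."""

    name: str
    molar_mass: float

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError("molar mass must be > 0 g/mol")


#: Registry of the monitored VFAs (g/mol, 2-decimal IUPAC values).
ACIDS: dict[str, AcidSpec] = {
    spec.name: spec
    for spec in (
        AcidSpec("acetate", 60.05),
        AcidSpec("propionate", 74.08),
        AcidSpec("butyrate", 88.11),
        AcidSpec("iso-butyrate", 88.11),
        AcidSpec("valerate", 102.13),
        AcidSpec("iso-valerate", 102.13),
    )
}


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant digits with round-half-to-even ties."""
    if sig < 1:
        raise ValueError("sig must be >= 1")
    if x == 0 or not math.isfinite(x):
        return float(x)
    magnitude = math.floor(math.log10(abs(x)))
    quantum = Decimal(1).scaleb(magnitude - sig + 1)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class SubstrateTable:
    """Per-component trace-element contributions (ng per L of substrate).

    Rows are substrate components (glucose, casein, tap water, ...), columns
    are elements.  Values are non-negative concentrations contributed to one
    litre of the fed substrate.
    """

    contributions: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.contributions
        unknown = set(df.columns) - set(ELEMENTS)
        if unknown:
            raise ValueError(f"unknown elements in table: {sorted(unknown)}")
        if (df.to_numpy() < 0).any():
            raise ValueError("contributions must be >= 0 ng/L")
        object.__setattr__(self, "contributions", df.astype(float))

    @property
    def components(self) -> list[str]:
        return list(self.contributions.index)

    def concat(self, other: "SubstrateTable") -> "SubstrateTable":
        return SubstrateTable(pd.concat([self.contributions, other.contributions]))

    @classmethod
    def from_csv(cls, path_or_buf, sep: str = "\t") -> "SubstrateTable":
        df = pd.read_csv(path_or_buf, sep=sep, index_col=0)
        return cls(df)

    def to_csv(self, path_or_buf=None, sep: str = "\t"):
        return self.contributions.to_csv(path_or_buf, sep=sep)


def _default_table() -> SubstrateTable:
    text = (
        "component\tCo\tNi\tSe\tW\n"
        "glucose\t1\t63\t75\t0\n"
        "sucrose\t6\t75\t1100\t0\n"
        "casein\t540\t26000\t3000\t230\n"
        "tap water\t8\t210\t14\t0\n"
        "vitamin solution\t2\t0\t2\t0\n"
        "trace element solution\t20\t13\t4\t2\n"
        "Se/W solution\t0\t0\t7\t12\n"
    )
    return SubstrateTable.from_csv(io.StringIO(text))


#: Measured per-component contributions for the chemically defined substrate
#: used throughout this package (ng per L of substrate, 2 significant digits).
SUBSTRATE_TE_TABLE: SubstrateTable = _default_table()


def total_contribution(
    table: SubstrateTable, element: str, sig: int | None = 2
) -> float:
    """Column sum of an element over all components, in ng/L.

    Rounded to ``sig`` significant digits (round-half-to-even) unless
    ``sig`` is None.
    """
    if element not in table.contributions.columns:
        raise ValueError(f"element {element!r} not present in table")
    total = float(table.contributions[element].sum())
    return total if sig is None else round_sig(total, sig)


def vfa_mM_to_mgL(conc: float, acid: str | AcidSpec) -> float:
    """Convert a VFA concentration from mM to mg/L (conc x molar mass)."""
    if conc < 0:
        raise ValueError("concentration must be >= 0 mM")
    spec = ACIDS.get(acid) if isinstance(acid, str) else acid
    if spec is None:
        raise ValueError(f"unknown acid {acid!r}; known: {sorted(ACIDS)}")
    return conc * spec.molar_mass


def vfa_mgL_to_mM(conc: float, acid: str | AcidSpec) -> float:
    """Inverse of :func:`vfa_mM_to_mgL`."""
    if conc < 0:
        raise ValueError("concentration must be >= 0 mg/L")
    spec = ACIDS.get(acid) if isinstance(acid, str) else acid
    if spec is None:
        raise ValueError(f"unknown acid {acid!r}; known: {sorted(ACIDS)}")
    return conc / spec.molar_mass


def cod_methane_volume() -> float:
    """Methane volume equivalent of COD: 22414/64 = 350.2 mL CH4 per g COD.

    The value usually quoted at 3 significant figures is 350 mL/gCOD.
    """
    return MOLAR_VOLUME_ML / COD_PER_MOL_CH4_G


def buswell(n_c: float, n_h: float, n_o: float) -> tuple[float, float]:
    """Buswell stoichiometry for a compound CnHaOb.

    Complete anaerobic conversion gives ``n/2 + a/8 - b/4`` mol CH4 and
    ``n/2 - a/8 + b/4`` mol CO2 per mol of compound.  Returns the CH4 mole
    fraction of the biogas and the CH4 volume per gram of compound at
    0 degC, 1 atm (mL/g).  Glucose, for example, yields a 50:50 biogas and
    about 373 mL CH4/g.
    """
    if n_c <= 0 or n_h < 0 or n_o < 0:
        raise ValueError("composition must describe CnHaOb with n > 0")
    ch4 = n_c / 2.0 + n_h / 8.0 - n_o / 4.0
    co2 = n_c / 2.0 - n_h / 8.0 + n_o / 4.0
    if ch4 < 0:
        raise ValueError("composition yields negative CH4 (too oxidised)")
    if co2 < 0:
        raise ValueError("composition yields negative CO2 (too reduced)")
    total = ch4 + co2
    fraction = ch4 / total if total > 0 else float("nan")
    molar_mass = (
        n_c * _ATOMIC_MASS["C"] + n_h * _ATOMIC_MASS["H"] + n_o * _ATOMIC_MASS["O"]
    )
    ml_per_g = ch4 * MOLAR_VOLUME_ML / molar_mass
    return fraction, ml_per_g


def cod_balance(frac_ch4: float, frac_biomass: float) -> float:
    """Unaccounted fraction of the ingoing COD: 1 - CH4 - biomass.

    Both inputs are fractions of fed COD in [0, 1]; their sum may not
    exceed 1.
    """
    for name, value in (("frac_ch4", frac_ch4), ("frac_biomass", frac_biomass)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be within [0, 1], got {value}")
    total = frac_ch4 + frac_biomass
    if total > 1.0 + 1e-12:
        raise ValueError("CH4 and biomass fractions sum to more than 1")
    return max(0.0, 1.0 - total)
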