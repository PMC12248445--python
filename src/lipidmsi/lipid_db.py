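"""Lipid species database: elemental compositions, monoisotopic masses and
negative-mode adduct m/z values.

The panel covers the glycerophospholipid and sphingolipid classes that are
detected consistently in negative-ion MALDI on lung tissue: diacyl
phosphatidylethanolamine (PE), alkyl-ether PE (PE O), plasmalogen PE (PE P),
phosphatidylinositol (PI), phosphatidylserine (PS) and sphingomyelin (SM).
Species are identified at the "class C:D" level (total chain carbons : total
chain double bonds, chains unresolved); the head group is excluded from the
carbon count and, for plasmalogens, the vinyl-ether double bond is excluded
from D, so PE P c:d is isobaric with PE O c:(d+1).

Compositions are built from the class backbone formulas; masses are sums of
monoisotopic atomic masses kept as compile-time constants, so no external
element table is required.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "LipidClass",
    "LipidSpecies",
    "AdductSpec",
    "PanelEntry",
    "UnsupportedClassError",
    "InvalidChainError",
    "ADDUCTS",
    "composition_of",
    "monoisotopic_mass",
    "adduct_mz",
    "default_panel",
    "panel_to_tsv",
    "panel_from_tsv",
]

# Monoisotopic atomic masses (IUPAC/CODATA), Da.
ATOMIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
}
ELECTRON_MASS = 0.00054857991
PROTON_MASS = ATOMIC_MASS["H"] - ELECTRON_MASS  # 1.00727645216


class UnsupportedClassError(ValueError):
    """Raised for a lipid class outside the supported panel classes."""


class InvalidChainError(ValueError):
    """Raised when a (carbons, double bonds) pair yields an impossible formula."""


class LipidClass(str, enum.Enum):
    PE = "PE"
    PE_O = "PE O"
    PE_P = "PE P"
    PI = "PI"
    PS = "PS"
    SM = "SM"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# Class backbone rules: composition as a function of total chain carbons c and
# chain double bonds d.  Diacyl glycerophospholipids are head group +
# glycerophosphate + two fatty acids - 2 H2O; the ether classes replace one
# ester by an alkyl (PE O) or 1-alkenyl (PE P) ether; SM uses the sphingoid
# "d" backbone convention (2 OH groups, amide-linked fatty acid).
_BACKBONES = {
    LipidClass.PE: lambda c, d: {"C": c + 5, "H": 2 * c + 10 - 2 * d, "N": 1, "O": 8, "P": 1},
    LipidClass.PS: lambda c, d: {"C": c + 6, "H": 2 * c + 10 - 2 * d, "N": 1, "O": 10, "P": 1},
    LipidClass.PI: lambda c, d: {"C": c + 9, "H": 2 * c + 15 - 2 * d, "O": 13, "P": 1},
    LipidClass.PE_O: lambda c, d: {"C": c + 5, "H": 2 * c + 12 - 2 * d, "N": 1, "O": 7, "P": 1},
    # Plasmalogen: one more double bond than the alkyl ether it is isobaric with.
    LipidClass.PE_P: lambda c, d: {"C": c + 5, "H": 2 * c + 10 - 2 * d, "N": 1, "O": 7, "P": 1},
    LipidClass.SM: lambda c, d: {"C": c + 5, "H": 2 * c + 13 - 2 * d, "N": 2, "O": 6, "P": 1},
}


def composition_of(lipid_class: LipidClass, total_carbons: int, double_bonds: int) -> dict[str, int]:
    """Elemental composition {element: count} for one species.

    ``total_carbons`` counts acyl/alkyl/sphingoid chain carbons only (24-48);
    ``double_bonds`` counts chain double bonds (0-8; the plasmalogen
    vinyl-ether bond is not counted).
    """
    try:
        lipid_class = LipidClass(lipid_class)
    except ValueError:
        raise UnsupportedClassError(f"unsupported lipid class: {lipid_class!r}") from None
    if not (24 <= total_carbons <= 48):
        raise InvalidChainError(f"total_carbons {total_carbons} outside plausible range 24-48")
    if not (0 <= double_bonds <= 8):
        raise InvalidChainError(f"double_bonds {double_bonds} outside plausible range 0-8")
    comp = _BACKBONES[lipid_class](total_carbons, double_bonds)
    if comp["H"] <= 0:
        raise InvalidChainError(
            f"{lipid_class} {total_carbons}:{double_bonds} yields non-positive hydrogen count"
        )
    return comp


def monoisotopic_mass(composition: Mapping[str, int]) -> float:
    """Monoisotopic mass (Da) of an elemental composition."""
    try:
        return sum(count * ATOMIC_MASS[el] for el, count in composition.items())
    except KeyError as exc:  # unknown element
        raise KeyError(f"unknown element in composition: {exc.args[0]!r}") from None


def formula_string(composition: Mapping[str, int]) -> str:
    """Hill-ish formula string, e.g. ``C39H76NO8P``."""
    parts = []
    for el in ("C", "H", "N", "O", "P"):
        n = composition.get(el, 0)
        if n == 1:
            parts.append(el)
        elif n > 1:
            parts.append(f"{el}{n}")
    return "".join(parts)


@dataclass(frozen=True)
class LipidSpecies:
    """One species at the "class C:D" shorthand level."""

    lipid_class: LipidClass
    total_carbons: int
    double_bonds: int
    composition: Mapping[str, int] = field(compare=False, default=None)  # type: ignore[assignment]
    neutral_mass: float = field(compare=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        comp = composition_of(self.lipid_class, self.total_carbons, self.double_bonds)
        object.__setattr__(self, "composition", comp)
        object.__setattr__(self, "neutral_mass", monoisotopic_mass(comp))

    @property
    def name(self) -> str:
        cd = f"{self.total_carbons}:{self.double_bonds}"
        if self.lipid_class is LipidClass.SM:
            return f"SM d{cd}"
        return f"{self.lipid_class.value} {cd}"

    @property
    def formula(self) -> str:
        return formula_string(self.composition)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"LipidSpecies({self.name}, {self.formula}, {self.neutral_mass:.4f} Da)"


@dataclass(frozen=True)
class AdductSpec:
    """A negative-mode ionization adduct.

    ``mass_delta`` is signed and applied to the neutral monoisotopic mass;
    electron mass is included so the result is a true singly-charged anion m/z.
    """

    name: str
    mass_delta: float
    applicable_classes: frozenset[LipidClass]

    def __post_init__(self) -> None:
        if abs(self.mass_delta) >= 100:
            raise ValueError(f"implausible adduct mass delta {self.mass_delta}")


_GPL = frozenset({LipidClass.PE, LipidClass.PE_O, LipidClass.PE_P, LipidClass.PI, LipidClass.PS})

#: Adducts observed in negative-mode MALDI of phospholipids.  Glycerophospho-
#: lipids ionize as [M-H]-; zwitterionic SM (quaternary amine) cannot lose a
#: proton from the head group and is observed as an acetate or chloride adduct
#: or after loss of a choline methyl.
ADDUCTS: dict[str, AdductSpec] = {
    "deprotonated": AdductSpec("deprotonated", -PROTON_MASS, _GPL),
    "acetate": AdductSpec(
        # [M+CH3COO]-: + C2H4O2 - H+
        "acetate",
        2 * ATOMIC_MASS["C"] + 4 * ATOMIC_MASS["H"] + 2 * ATOMIC_MASS["O"] - PROTON_MASS,
        frozenset({LipidClass.SM}),
    ),
    "chloride": AdductSpec(
        "chloride", 34.96885268 + ELECTRON_MASS, frozenset({LipidClass.SM})
    ),
    "demethylated": AdductSpec(
        # [M-CH3]-: loss of a choline methyl cation
        "demethylated",
        -(ATOMIC_MASS["C"] + 3 * ATOMIC_MASS["H"]) + ELECTRON_MASS,
        frozenset({LipidClass.SM}),
    ),
}


def adduct_mz(species: LipidSpecies, adduct: AdductSpec) -> float:
    """Singly-charged negative-mode m/z of ``species`` under ``adduct``."""
    if species.lipid_class not in adduct.applicable_classes:
        raise ValueError(f"adduct {adduct.name!r} not applicable to {species.lipid_class}")
    return species.neutral_mass + adduct.mass_delta


@dataclass(frozen=True)
class PanelEntry:
    species: LipidSpecies
    adduct: AdductSpec
    mz: float
    #: Name of the isobaric species this assignment suppresses (PE P c:d hides
    #: PE O c:(d+1)), or None.
    isobar_alternative: str | None = None


# Species exercised by the bronchial-biopsy profiles: every species reported in
# the tumor/non-tumor, COPD and smoker comparisons, plus the minor species
# needed to close each class to 100%.
_PANEL_SPECIES: list[tuple[LipidClass, int, int]] = [
    (LipidClass.PI, 32, 0),
    (LipidClass.PI, 34, 1),
    (LipidClass.PI, 34, 2),
    (LipidClass.PI, 36, 1),
    (LipidClass.PI, 36, 2),
    (LipidClass.PI, 36, 4),
    (LipidClass.PI, 38, 3),
    (LipidClass.PI, 38, 4),
    (LipidClass.PE, 36, 1),
    (LipidClass.PE, 36, 2),
    (LipidClass.PE, 36, 4),
    (LipidClass.PE, 38, 2),
    (LipidClass.PE, 38, 4),
    (LipidClass.PE, 38, 6),
    (LipidClass.PE, 40, 6),
    (LipidClass.PE_P, 34, 1),
    (LipidClass.PE_P, 36, 1),
    (LipidClass.PE_P, 38, 4),
    (LipidClass.PE_P, 40, 4),
    (LipidClass.PE_P, 38, 6),
    (LipidClass.PE_P, 40, 6),
    (LipidClass.PS, 36, 1),
    (LipidClass.PS, 36, 2),
    (LipidClass.PS, 38, 4),
    (LipidClass.PS, 40, 6),
    (LipidClass.SM, 34, 1),
    (LipidClass.SM, 36, 1),
    (LipidClass.SM, 42, 1),
    (LipidClass.SM, 42, 2),
]

MZ_RANGE = (550.0, 1000.0)


def default_panel(sm_adduct: str = "acetate") -> list[PanelEntry]:
    """The default species panel with one adduct per species, sorted by m/z.

    Glycerophospholipids take [M-H]-; SM takes ``sm_adduct`` (acetate by
    default; chloride / demethylated selectable).  Plasmalogen entries record
    the alkyl-ether isobar they suppress.  All m/z fall inside the 550-1000 Da
    scan range.
    """
    sm = ADDUCTS[sm_adduct]
    if LipidClass.SM not in sm.applicable_classes:
        raise ValueError(f"adduct {sm_adduct!r} not applicable to SM")
    entries = []
    for cls, c, d in _PANEL_SPECIES:
        sp = LipidSpecies(cls, c, d)
        adduct = sm if cls is LipidClass.SM else ADDUCTS["deprotonated"]
        alt = f"PE O {c}:{d + 1}" if cls is LipidClass.PE_P else None
        entries.append(PanelEntry(sp, adduct, adduct_mz(sp, adduct), alt))
    entries.sort(key=lambda e: e.mz)
    lo, hi = MZ_RANGE
    assert all(lo <= e.mz <= hi for e in entries)
    return entries


def panel_to_tsv(panel: list[PanelEntry], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "class": [e.species.lipid_class.value for e in panel],
            "carbons": [e.species.total_carbons for e in panel],
            "double_bonds": [e.species.double_bonds for e in panel],
            "adduct": [e.adduct.name for e in panel],
            "formula": [e.species.formula for e in panel],
            "mz_theoretical": [e.mz for e in panel],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def panel_from_tsv(path: str | Path) -> list[PanelEntry]:
    df = pd.read_csv(path, sep="\t")
    entries = []
    for row in df.itertuples(index=False):
        cls = LipidClass(row._0 if hasattr(row, "_0") else getattr(row, "class"))
        sp = LipidSpecies(cls, int(row.carbons), int(row.double_bonds))
        adduct = ADDUCTS[row.adduct]
        alt = (
            f"PE O {sp.total_carbons}:{sp.double_bonds + 1}"
            if cls is LipidClass.PE_P
            else None
        )
        entries.append(PanelEntry(sp, adduct, adduct_mz(sp, adduct), alt))
    entries.sort(key=lambda e: e.mz)
    return entries
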