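"""Residue and modification mass tables.

All arithmetic is on neutral masses in daltons. Two tables are provided:
monoisotopic (the default, appropriate for deconvoluted ESI-Q/ToF data)
and average (appropriate for intact MALDI-ToF comparisons, which are
typically read to the nearest dalton).

Residue masses are the amino-acid masses minus one water, taken from
Biopython's IUPAC tables, so a peptide's neutral mass is the residue sum
plus one water.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from Bio.SeqUtils import IUPACData

__all__ = [
    "MassTable",
    "Modification",
    "MONO",
    "AVERAGE",
    "MODIFICATIONS",
    "get_mass_table",
    "modification_delta",
    "mz",
]

#: Monoisotopic mass of H2O (Da).
WATER_MONO = 18.0105646863
#: Average mass of H2O (Da).
WATER_AVG = 18.01528
#: Mass of a proton (Da); charging adds one proton per charge.
PROTON = 1.00727646688

_STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class MassTable:
    """Residue masses (Da) for one mass convention.

    Attributes
    ----------
    kind : str
        ``"mono"`` or ``"average"``.
    residue_masses : Mapping[str, float]
        One-letter amino acid code -> residue mass (amino acid minus water).
    water : float
        Mass of H2O under this convention.
    proton : float
        Mass of a proton (identical for both conventions).
    """

    kind: str
    residue_masses: Mapping[str, float]
    water: float
    proton: float = PROTON

    def residue(self, letter: str) -> float:
        try:
            return self.residue_masses[letter]
        except KeyError:
            raise KeyError(f"unknown residue letter {letter!r}") from None


def _build_table(kind: str) -> MassTable:
    if kind == "mono":
        weights, water = IUPACData.monoisotopic_protein_weights, WATER_MONO
    else:
        weights, water = IUPACData.protein_weights, WATER_AVG
    residues = MappingProxyType(
        {aa: weights[aa] - water for aa in _STANDARD_RESIDUES}
    )
    return MassTable(kind=kind, residue_masses=residues, water=water)


MONO = _build_table("mono")
AVERAGE = _build_table("average")

_TABLES = {"mono": MONO, "average": AVERAGE, "avg": AVERAGE}


def get_mass_table(mass_type: str = "mono") -> MassTable:
    """Return the mass table for ``mass_type`` ("mono" or "average")."""
    try:
        return _TABLES[mass_type]
    except KeyError:
        raise ValueError(
            f"unknown mass_type {mass_type!r}; expected 'mono' or 'average'"
        ) from None


@dataclass(frozen=True)
class Modification:
    """A named post-translational modification with its mass delta.

    ``delta`` maps the mass convention ("mono"/"average") to the signed
    shift in Da; ``applicable_residues`` names the residue classes the
    modification chemistry acts on.
    """

    name: str
    delta: Mapping[str, float]
    applicable_residues: frozenset = field(default_factory=frozenset)

    def delta_for(self, mass_type: str) -> float:
        key = "average" if mass_type in ("average", "avg") else "mono"
        return self.delta[key]


# Elemental composition deltas:
#   dehydration           -H2O
#   phosphorylation       +HPO3
#   carbamidomethyl       +C2H3NO (iodoacetamide adduct on Cys)
#   phosphate_elimination -H3PO4 (= -HPO3 - H2O), so that
#   phosphorylation + phosphate_elimination == dehydration exactly.
_HPO3_MONO, _HPO3_AVG = 79.96633089, 79.9799
_CAM_MONO, _CAM_AVG = 57.02146372, 57.0513

MODIFICATIONS: Mapping[str, Modification] = MappingProxyType(
    {
        "dehydration": Modification(
            "dehydration",
            MappingProxyType({"mono": -WATER_MONO, "average": -WATER_AVG}),
            frozenset("ST"),
        ),
        "phosphorylation": Modification(
            "phosphorylation",
            MappingProxyType({"mono": _HPO3_MONO, "average": _HPO3_AVG}),
            frozenset("ST"),
        ),
        "carbamidomethyl": Modification(
            "carbamidomethyl",
            MappingProxyType({"mono": _CAM_MONO, "average": _CAM_AVG}),
            frozenset("C"),
        ),
        "phosphate_elimination": Modification(
            "phosphate_elimination",
            MappingProxyType(
                {
                    "mono": -(_HPO3_MONO + WATER_MONO),
                    "average": -(_HPO3_AVG + WATER_AVG),
                }
            ),
            frozenset("ST"),  # acts on phospho-Ser/Thr
        ),
    }
)


def modification_delta(name: str, mass_type: str = "mono") -> float:
    """Signed mass delta (Da) of a registered modification.

    Raises ``KeyError`` naming the modification if it is not registered.
    """
    try:
        mod = MODIFICATIONS[name]
    except KeyError:
        raise KeyError(f"unknown modification {name!r}") from None
    return mod.delta_for(mass_type)


def mz(neutral_mass: float, charge: int) -> float:
    """m/z of a neutral mass at the given positive charge state."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON) / charge
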