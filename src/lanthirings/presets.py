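"""The venezuelin preset: positions, variant series, and text-level
evidence for the VenA/VenL system.

Every positional fact here is published: the GluC core fragment spans
Thr18-Ala51, Cys sit at 32/34/45/50, the dehydro residues are Dhb31,
Dhb39, Dhb43 and Dha49, GluC cuts after Glu17, a ProPheAla signal-
peptidase-like motif spans 27-29, and GlyAla / AlaAla double-Gly-type
pairs sit at 25-26 and 29-30.

The residue string itself is a SYNTHETIC stand-in: the authentic VenA
primary sequence is published only as a figure and is not available as
text, so positions other than the constrained ones are filled with inert
residues (no extra Ser/Thr/Cys/Glu, no extra cleavage motifs). Every
positional computation in this package — digestion, fragmentation
protection, topology deduction — depends only on the constrained
positions and is unaffected by the filler; absolute masses of the full
peptide are NOT those of authentic VenA.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .digestion import PROTEASES, digest
from .fragments import CleavageEvidence
from .peptide import ModifiedPeptide, Topology
from .solver import RingTopologyModel, VariantObservation

__all__ = [
    "VENA_SYNTHETIC_SEQUENCE",
    "CORE_SPAN",
    "CYS_POSITIONS",
    "DEHYDRO_POSITIONS",
    "VENEZUELIN_TOPOLOGY",
    "venezuelin_precursor",
    "venezuelin_core",
    "venezuelin_variants",
    "venezuelin_observations",
    "venezuelin_model",
]

# Positions (1-based precursor coordinates) fixed by the published text:
#   17 E (GluC site), 18 T (core start), 25-26 GA, 27-29 PFA, 29-30 AA,
#   31 T (Dhb31), 32 C, 34 C, 39 T (Dhb39), 43 T (Dhb43), 45 C,
#   49 S (Dha49), 50 C, 51 A (core end).
# Filler residues are synthetic (see module docstring).
VENA_SYNTHETIC_SEQUENCE = (
    "MDLNKVLDVQKLMNGFE"  # leader 1-17, ends in the GluC Glu
    "TVLNKWH"  # 18-24
    "GAPFAA"  # 25-30: GA, PFA, AA motifs
    "TCGC"  # 31-34: Dhb31, Cys32, Cys34
    "LVNK"  # 35-38
    "TWHL"  # 39-42: Dhb39
    "TVC"  # 43-45: Dhb43, Cys45
    "NKW"  # 46-48
    "SCA"  # 49-51: Dha49, Cys50, Ala51
)

CORE_SPAN: Tuple[int, int] = (18, 51)
CYS_POSITIONS = frozenset({32, 34, 45, 50})
DEHYDRO_POSITIONS: Dict[int, str] = {31: "Dhb", 39: "Dhb", 43: "Dhb", 49: "Dha"}

#: The deduced ring topology: MeLan Cys32-Dhb43, MeLan Cys34-Dhb39,
#: Lan Cys45-Dha49, MeLan Cys50-Dhb31.
VENEZUELIN_TOPOLOGY = Topology({(32, 43), (34, 39), (45, 49), (50, 31)})

_CORE_BONDS = list(range(18, 51))  # bonds 18..50


def venezuelin_precursor(
    dehydrated: bool = True, cyclized: bool = True
) -> ModifiedPeptide:
    """The full synthetic-sequence precursor, optionally modified."""
    states = dict(DEHYDRO_POSITIONS) if dehydrated else {}
    rings = VENEZUELIN_TOPOLOGY if (dehydrated and cyclized) else Topology()
    return ModifiedPeptide(
        id="VenA",
        sequence=VENA_SYNTHETIC_SEQUENCE,
        numbering_offset=1,
        states=states,
        crosslinks=rings,
    )


def venezuelin_core(
    dehydrated: bool = True, cyclized: bool = True
) -> ModifiedPeptide:
    """The GluC core fragment Thr18-Ala51 of the modified precursor."""
    precursor = venezuelin_precursor(dehydrated, cyclized)
    frags = digest(precursor, PROTEASES["gluc"])
    core = [f for f in frags if f.first == CORE_SPAN[0]]
    assert len(core) == 1 and core[0].last == CORE_SPAN[1]
    return precursor.subsequence(*CORE_SPAN, new_id="VenA-core")


def venezuelin_variants() -> List[Tuple[str, Dict[int, str]]]:
    """The Cys->Ala variant series used for the topology deduction."""
    return [
        ("WT", {}),
        ("C32A", {32: "A"}),
        ("C34A", {34: "A"}),
        ("C45A", {45: "A"}),
        ("C50A", {50: "A"}),
    ]


def _evidence(variant_id: str, bonds) -> CleavageEvidence:
    return CleavageEvidence(variant_id=variant_id, cleavable_bonds=frozenset(bonds))


def venezuelin_observations() -> List[VariantObservation]:
    """The published fragmentation facts as solver observations.

    Cleavable bonds and protected spans encode the text-level reading of
    the tandem-MS data:

    * WT, C34A, C45A — ions throughout the N-terminal linear region
      (bonds 18-30) and at the Cys50/Ala51 bond only; the whole
      Dhb31-Cys50 region is protected (span (31, 50)).
    * C32A — additional ions flanking Dhb31 (bonds 30, 31) and Dhb43
      (bonds 42, 43): those two dehydro residues are uncyclized in this
      mutant. Two segments stay protected, asserted as the ring spans
      (34, 39) and (45, 49).
    * C50A — extensive C-terminal fragmentation (bonds 43-50: Cys45 is
      left uncyclized), with N-terminal protection asserted as (32, 43).

    Wild type is ``complete`` (zero IAA shift: all four Cys cyclized);
    mutants are ``partial`` (mutating one Cys can leave another ring
    unformed).
    """
    n_term = set(range(18, 31))  # bonds 18..30
    wt_like_bonds = n_term | {50}
    return [
        VariantObservation(
            "WT",
            CYS_POSITIONS,
            DEHYDRO_POSITIONS,
            _evidence("WT", wt_like_bonds),
            asserted_protected_spans=((31, 50),),
            completeness="complete",
        ),
        VariantObservation(
            "C32A",
            CYS_POSITIONS - {32},
            DEHYDRO_POSITIONS,
            _evidence("C32A", n_term | {31, 42, 43, 50}),
            asserted_protected_spans=((34, 39), (45, 49)),
            completeness="partial",
        ),
        VariantObservation(
            "C34A",
            CYS_POSITIONS - {34},
            DEHYDRO_POSITIONS,
            _evidence("C34A", wt_like_bonds),
            asserted_protected_spans=((31, 50),),
            completeness="partial",
        ),
        VariantObservation(
            "C45A",
            CYS_POSITIONS - {45},
            DEHYDRO_POSITIONS,
            _evidence("C45A", wt_like_bonds),
            asserted_protected_spans=((31, 50),),
            completeness="partial",
        ),
        VariantObservation(
            "C50A",
            CYS_POSITIONS - {50},
            DEHYDRO_POSITIONS,
            _evidence("C50A", n_term | set(range(43, 51))),
            asserted_protected_spans=((32, 43),),
            completeness="partial",
        ),
    ]


def venezuelin_model() -> RingTopologyModel:
    """Ready-to-fit model over the published variant series."""
    return RingTopologyModel(
        venezuelin_observations(), span=CORE_SPAN, wild_type_id="WT"
    )
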