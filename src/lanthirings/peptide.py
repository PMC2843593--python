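"""The modified-peptide data model: residue chain, per-position
modification states, and thioether crosslink topology.

Positions are 1-based precursor coordinates throughout. A peptide that is
a proteolytic fragment carries a ``numbering_offset`` so that, e.g., the
GluC core fragment of a precursor keeps its residues numbered 18..51 and
the field literature's residue labels (Cys32, Dhb43) stay usable verbatim.

Backbone bond ``i`` joins residues ``i`` and ``i+1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import FrozenSet, Iterable, Mapping, Tuple

from .masses import MODIFICATIONS, get_mass_table

__all__ = ["Topology", "ModifiedPeptide", "STATES"]

#: Valid per-position modification states. Dha/Dhb are dehydrated Ser/Thr
#: (the identity follows from the original residue and is validated, never
#: stored independently); phospho is phosphorylated Ser/Thr; cam is
#: carbamidomethyl (iodoacetamide-alkylated) Cys.
STATES = frozenset({"unmodified", "Dha", "Dhb", "phospho", "cam"})

Ring = Tuple[int, int]


@dataclass(frozen=True)
class Topology:
    """A partial matching between Cys positions and dehydro positions.

    Each ring is stored as a ``(cys_position, dehydro_position)`` pair; a
    Cys–Dha pair is a lanthionine (Lan), Cys–Dhb a methyllanthionine
    (MeLan). A position appears in at most one ring. The ring *spans*
    backbone bonds ``min(pair) .. max(pair)-1``; those bonds are protected
    from producing b/y'' fragment ions.
    """

    rings: FrozenSet[Ring] = frozenset()

    def __init__(self, rings: Iterable[Ring] = ()):
        normalized = frozenset((int(c), int(d)) for c, d in rings)
        positions = [p for ring in normalized for p in ring]
        if len(positions) != len(set(positions)):
            raise ValueError(f"position reused across rings: {sorted(normalized)}")
        object.__setattr__(self, "rings", normalized)

    def __iter__(self):
        return iter(self.rings)

    def __len__(self) -> int:
        return len(self.rings)

    def positions(self) -> FrozenSet[int]:
        return frozenset(p for ring in self.rings for p in ring)

    def spans_bond(self, bond: int) -> bool:
        """True if some ring spans backbone bond ``bond``."""
        return any(min(r) <= bond < max(r) for r in self.rings)

    def sorted_rings(self) -> Tuple[Ring, ...]:
        return tuple(sorted(self.rings))

    def __repr__(self) -> str:
        return f"Topology({list(self.sorted_rings())})"


@dataclass(frozen=True)
class ModifiedPeptide:
    """A 1-based-numbered residue chain with modification states and rings.

    Parameters
    ----------
    id : str
        Identifier (precursor or variant name).
    sequence : str
        One-letter residues *before* modification: a Dha position holds the
        original ``S``, a Dhb position the original ``T``.
    numbering_offset : int
        1-based precursor position of the first residue (1 for a full
        precursor, 18 for a GluC core fragment starting at Thr18).
    states : Mapping[int, str]
        Position -> state for every non-``unmodified`` position.
    crosslinks : Topology
        Thioether rings between Cys and Dha/Dhb positions.
    """

    id: str
    sequence: str
    numbering_offset: int = 1
    states: Mapping[int, str] = field(default_factory=dict)
    crosslinks: Topology = field(default_factory=Topology)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(
            self, "states", {int(k): v for k, v in dict(self.states).items()}
        )
        self._validate()

    # -- coordinates ---------------------------------------------------

    @property
    def first(self) -> int:
        return self.numbering_offset

    @property
    def last(self) -> int:
        return self.numbering_offset + len(self.sequence) - 1

    @property
    def span(self) -> Tuple[int, int]:
        return (self.first, self.last)

    def residue(self, position: int) -> str:
        """Original residue letter at a 1-based precursor position."""
        if not self.first <= position <= self.last:
            raise IndexError(
                f"position {position} outside peptide span {self.span}"
            )
        return self.sequence[position - self.numbering_offset]

    def state(self, position: int) -> str:
        return self.states.get(position, "unmodified")

    # -- validation ----------------------------------------------------

    def _validate(self):
        for pos, st in self.states.items():
            if st not in STATES:
                raise ValueError(f"unknown state {st!r} at position {pos}")
            res = self.residue(pos)
            if st == "Dha" and res != "S":
                raise ValueError(f"Dha at {pos} requires original Ser, got {res}")
            if st == "Dhb" and res != "T":
                raise ValueError(f"Dhb at {pos} requires original Thr, got {res}")
            if st == "phospho" and res not in "ST":
                raise ValueError(f"phospho at {pos} requires Ser/Thr, got {res}")
            if st == "cam" and res != "C":
                raise ValueError(f"carbamidomethyl at {pos} requires Cys, got {res}")
        for cys_pos, dehydro_pos in self.crosslinks:
            for p in (cys_pos, dehydro_pos):
                if not self.first <= p <= self.last:
                    raise ValueError(
                        f"crosslink endpoint {p} outside span {self.span}"
                    )
            if self.residue(cys_pos) != "C":
                raise ValueError(
                    f"crosslink cys endpoint {cys_pos} is "
                    f"{self.residue(cys_pos)}, not Cys"
                )
            if self.state(dehydro_pos) not in ("Dha", "Dhb"):
                raise ValueError(
                    f"crosslink partner {dehydro_pos} is not Dha/Dhb"
                )

    # -- derived sets ---------------------------------------------------

    def cys_positions(self) -> FrozenSet[int]:
        off = self.numbering_offset
        return frozenset(
            i + off for i, aa in enumerate(self.sequence) if aa == "C"
        )

    def dehydro_positions(self) -> Mapping[int, str]:
        """Position -> 'Dha'/'Dhb' for every dehydrated residue."""
        return {p: s for p, s in self.states.items() if s in ("Dha", "Dhb")}

    # -- mass ------------------------------------------------------------

    def neutral_mass(self, mass_type: str = "mono") -> float:
        """Neutral mass: residue sum + water + modification deltas.

        Ring formation is a Michael addition and shifts the mass by 0 Da,
        so crosslinks do not enter the sum.
        """
        table = get_mass_table(mass_type)
        total = sum(table.residue(aa) for aa in self.sequence) + table.water
        for st in self.states.values():
            if st in ("Dha", "Dhb"):
                total += MODIFICATIONS["dehydration"].delta_for(mass_type)
            elif st == "phospho":
                total += MODIFICATIONS["phosphorylation"].delta_for(mass_type)
            elif st == "cam":
                total += MODIFICATIONS["carbamidomethyl"].delta_for(mass_type)
        return total

    # -- editing helpers -------------------------------------------------

    def with_crosslinks(self, topology: Topology) -> "ModifiedPeptide":
        return replace(self, crosslinks=topology)

    def with_states(self, states: Mapping[int, str]) -> "ModifiedPeptide":
        return replace(self, states=dict(states), crosslinks=self.crosslinks)

    def subsequence(self, first: int, last: int, new_id: str | None = None):
        """The sub-peptide spanning precursor positions [first, last]."""
        if not (self.first <= first <= last <= self.last):
            raise ValueError(f"[{first},{last}] outside span {self.span}")
        off = self.numbering_offset
        seq = self.sequence[first - off : last - off + 1]
        states = {p: s for p, s in self.states.items() if first <= p <= last}
        rings = Topology(
            r for r in self.crosslinks if first <= min(r) and max(r) <= last
        )
        return ModifiedPeptide(
            id=new_id or f"{self.id}[{first}-{last}]",
            sequence=seq,
            numbering_offset=first,
            states=states,
            crosslinks=rings,
        )

    def substitute(self, position: int, new_residue: str, new_id: str):
        """Point-substitute a residue (e.g. a Cys->Ala variant).

        Any modification state or crosslink touching the position is
        dropped, matching what the substitution chemistry removes.
        """
        off = self.numbering_offset
        seq = list(self.sequence)
        seq[position - off] = new_residue.upper()
        states = {p: s for p, s in self.states.items() if p != position}
        rings = Topology(r for r in self.crosslinks if position not in r)
        return ModifiedPeptide(
            id=new_id,
            sequence="".join(seq),
            numbering_offset=off,
            states=states,
            crosslinks=rings,
        )
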