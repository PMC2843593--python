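"""Ring-aware b/y'' fragment-ion prediction and peak matching.

The physical model: collision-induced dissociation of a backbone bond
inside a thioether macrocycle cannot release separate fragments — the two
halves stay tethered through the ring — so only *separating* bonds (bonds
spanned by no ring) yield observable b and y'' ions. The presence or
absence of ions at each bond is therefore direct evidence about the ring
topology, which is what the solver consumes.

Protection is modeled as binary: a bond inside any ring yields no ions.
Bond ``i`` joins residues ``i`` and ``i+1`` in precursor coordinates; a
ring ``(j, k)`` spans bonds ``min(j,k) .. max(j,k)-1``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

from .masses import MODIFICATIONS, PROTON, get_mass_table
from .peptide import ModifiedPeptide, Topology

__all__ = [
    "FragmentIon",
    "PeakList",
    "CleavageEvidence",
    "separating_bonds",
    "predict_fragments",
    "match_peaks",
    "protected_spans_from_evidence",
    "DEFAULT_FRAGMENT_TOL",
]

#: Default fragment-match tolerance (Da), Q/ToF-era accuracy.
DEFAULT_FRAGMENT_TOL = 0.2


@dataclass(frozen=True)
class FragmentIon:
    """One predicted b or y'' ion.

    ``index`` counts residues in the fragment (b from the N-terminus, y''
    from the C-terminus); ``bond`` is the cleaved backbone bond in
    precursor coordinates.
    """

    series: str
    index: int
    charge: int
    bond: int
    mz: float

    @property
    def label(self) -> str:
        z = "+" * self.charge
        return f"{self.series}{self.index}{z if self.charge > 1 else ''}"


@dataclass
class PeakList:
    """Deconvoluted (m/z, intensity) pairs from one spectrum, sorted by m/z."""

    entries: List[Tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        for mz_val, inten in self.entries:
            if mz_val <= 0:
                raise ValueError(f"non-positive m/z {mz_val}")
            if inten < 0:
                raise ValueError(f"negative intensity {inten}")
        self.entries = sorted(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def mzs(self) -> List[float]:
        return [m for m, _ in self.entries]

    def near(self, mz_value: float, tol: float) -> List[Tuple[float, float]]:
        """Peaks within ``tol`` Da of ``mz_value``."""
        mz_list = self.mzs()
        lo = bisect.bisect_left(mz_list, mz_value - tol)
        hi = bisect.bisect_right(mz_list, mz_value + tol)
        return self.entries[lo:hi]


@dataclass
class CleavageEvidence:
    """Backbone bonds proven cleavable by matched ions for one variant."""

    variant_id: str
    cleavable_bonds: FrozenSet[int]
    ion_support: Dict[int, List[FragmentIon]] = field(default_factory=dict)

    def __post_init__(self):
        self.cleavable_bonds = frozenset(self.cleavable_bonds)
        if self.ion_support:
            for bond in self.cleavable_bonds:
                if not self.ion_support.get(bond):
                    raise ValueError(f"bond {bond} has empty ion support")


def separating_bonds(
    span: Tuple[int, int], topology: Topology
) -> Set[int]:
    """Bonds in ``[first, last-1]`` spanned by no ring of ``topology``.

    These are the only bonds whose cleavage can yield separate b/y''
    fragments. Raises if a ring endpoint lies outside the span.
    """
    first, last = span
    for ring in topology:
        for p in ring:
            if not first <= p <= last:
                raise ValueError(
                    f"ring endpoint {p} outside span ({first},{last})"
                )
    return {
        bond
        for bond in range(first, last)
        if not topology.spans_bond(bond)
    }


def _position_mass(peptide: ModifiedPeptide, pos: int, mass_type: str) -> float:
    table = get_mass_table(mass_type)
    mass = table.residue(peptide.residue(pos))
    st = peptide.state(pos)
    if st in ("Dha", "Dhb"):
        mass += MODIFICATIONS["dehydration"].delta_for(mass_type)
    elif st == "phospho":
        mass += MODIFICATIONS["phosphorylation"].delta_for(mass_type)
    elif st == "cam":
        mass += MODIFICATIONS["carbamidomethyl"].delta_for(mass_type)
    return mass


def predict_fragments(
    peptide: ModifiedPeptide,
    charges: Iterable[int] = (1,),
    mass_type: str = "mono",
) -> List[FragmentIon]:
    """Predict b and y'' ions at every separating bond.

    b ions are the N-terminal prefix (neutral = residue+modification sum);
    y'' ions the C-terminal suffix plus one water. m/z adds one proton per
    charge. Non-separating (ring-protected) bonds yield no ions.
    """
    charges = sorted(set(int(z) for z in charges))
    if any(z < 1 for z in charges):
        raise ValueError("charges must be >= 1")
    table = get_mass_table(mass_type)
    first, last = peptide.span
    bonds = separating_bonds(peptide.span, peptide.crosslinks)

    # prefix[i] = sum of position masses for residues first..first+i-1
    pos_masses = [
        _position_mass(peptide, p, mass_type) for p in range(first, last + 1)
    ]
    prefix = [0.0]
    for m in pos_masses:
        prefix.append(prefix[-1] + m)
    total = prefix[-1]

    ions: List[FragmentIon] = []
    for bond in sorted(bonds):
        n_prefix = bond - first + 1
        b_neutral = prefix[n_prefix]
        y_neutral = total - prefix[n_prefix] + table.water
        for z in charges:
            ions.append(
                FragmentIon("b", n_prefix, z, bond, (b_neutral + z * PROTON) / z)
            )
            ions.append(
                FragmentIon(
                    "y",
                    last - bond,
                    z,
                    bond,
                    (y_neutral + z * PROTON) / z,
                )
            )
    return ions


def match_peaks(
    predicted: Sequence[FragmentIon],
    observed: PeakList,
    tol: float = DEFAULT_FRAGMENT_TOL,
    variant_id: str = "",
) -> CleavageEvidence:
    """Match predicted ions against an observed peak list.

    A bond enters ``cleavable_bonds`` iff at least one predicted ion at
    that bond lies within ``tol`` Da of an observed peak. One peak may
    support multiple ions; all supporting matches are recorded.
    """
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    support: Dict[int, List[FragmentIon]] = {}
    for ion in predicted:
        if observed.near(ion.mz, tol):
            support.setdefault(ion.bond, []).append(ion)
    return CleavageEvidence(
        variant_id=variant_id,
        cleavable_bonds=frozenset(support),
        ion_support=support,
    )


def protected_spans_from_evidence(
    evidence: CleavageEvidence,
    span: Tuple[int, int],
    min_bonds: int = 3,
) -> List[Tuple[int, int]]:
    """Maximal ion-free bond runs, as (start, end) residue intervals.

    A run of ``k`` consecutive bonds with no matched ion, ``k >=
    min_bonds``, is returned as the residue interval it delimits (interior
    bonds ``start .. end-1``). This converts an observed fragmentation gap
    into the protected-region assertion used by the solver's
    protection-assertion mode. Short gaps are ignored: with imperfect ion
    coverage a missing ion or two is expected and must not be read as a
    ring.
    """
    first, last = span
    runs: List[Tuple[int, int]] = []
    run_start = None
    for bond in range(first, last):
        if bond not in evidence.cleavable_bonds:
            if run_start is None:
                run_start = bond
        else:
            if run_start is not None and bond - run_start >= min_bonds:
                runs.append((run_start, bond))
            run_start = None
    if run_start is not None and last - run_start >= min_bonds:
        runs.append((run_start, last))
    return runs
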