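"""Crosslink-aware in-silico proteolysis and leader-cleavage proposals.

Proteolysis hydrolyzes backbone bonds matching a protease rule; the
products are the connected components of the residue graph whose edges
are the surviving backbone bonds *plus* the thioether crosslinks. A cut
landing inside a lanthionine ring therefore does not split the peptide —
the two chain segments stay tethered through the ring — but it does add
one water of hydrolysis to that component's mass. This is exactly how an
intact cyclic core (e.g. Thr18–Ala51 excised by GluC at Glu17) comes out
of a digest as one multiply-modified species.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Tuple

from .masses import get_mass_table
from .peptide import ModifiedPeptide

__all__ = [
    "ProteaseRule",
    "PROTEASES",
    "DigestFragment",
    "digest",
    "CleavageSiteProposal",
    "propose_leader_cleavage_sites",
]


@dataclass(frozen=True)
class ProteaseRule:
    """Cleavage specificity: cut the bond C-terminal to ``cut_after``.

    ``cut_after`` is a regex over the residue string; the cut bond is the
    one following the *last* residue of each match. ``exception_after`` is
    a residue class that, immediately following the match, suppresses the
    cut (classically: trypsin does not cut before Pro).
    """

    name: str
    cut_after: str
    exception_after: str = ""

    def cut_sites(self, peptide: ModifiedPeptide) -> List[int]:
        """Backbone bonds (precursor coordinates) this rule hydrolyzes."""
        seq, off = peptide.sequence, peptide.numbering_offset
        sites = []
        for m in re.finditer(self.cut_after, seq):
            end = m.end()  # 0-based index just past the matched motif
            if end >= len(seq):
                continue  # C-terminal residue: no bond to cut
            if self.exception_after and seq[end] in self.exception_after:
                continue
            sites.append(end - 1 + off)  # bond follows the last matched residue
        return sites


#: Registered protease specificities. GluC defaults to cut-after-Glu only
#: (ammonium-bicarbonate-style); use ``gluc_de`` for Glu+Asp specificity.
PROTEASES: Dict[str, ProteaseRule] = {
    "gluc": ProteaseRule("gluc", cut_after="E"),
    "gluc_de": ProteaseRule("gluc_de", cut_after="[ED]"),
    "trypsin": ProteaseRule("trypsin", cut_after="[KR]", exception_after="P"),
    "lysc": ProteaseRule("lysc", cut_after="K"),
    "factorxa": ProteaseRule("factorxa", cut_after="IEGR"),
}


@dataclass(frozen=True)
class DigestFragment:
    """One digest product: possibly several chain segments held together
    by crosslinks.

    ``member_segments`` are inclusive (start, end) precursor-coordinate
    intervals; ``n_internal_cuts`` counts hydrolyzed bonds whose two
    residues both remain in this fragment; ``neutral_mass`` includes one
    water per segment (each hydrolysis adds H to one new N-terminus and OH
    to the matching new C-terminus).
    """

    member_segments: Tuple[Tuple[int, int], ...]
    n_internal_cuts: int
    neutral_mass: float

    @property
    def first(self) -> int:
        return self.member_segments[0][0]

    @property
    def last(self) -> int:
        return self.member_segments[-1][1]

    def positions(self) -> FrozenSet[int]:
        return frozenset(
            p for a, b in self.member_segments for p in range(a, b + 1)
        )


def _components(
    peptide: ModifiedPeptide, cut_bonds: FrozenSet[int]
) -> List[FrozenSet[int]]:
    """Connected components under surviving backbone bonds + crosslinks."""
    parent = {p: p for p in range(peptide.first, peptide.last + 1)}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for bond in range(peptide.first, peptide.last):
        if bond not in cut_bonds:
            union(bond, bond + 1)
    for ring in peptide.crosslinks:
        union(min(ring), max(ring))

    groups: Dict[int, List[int]] = {}
    for p in parent:
        groups.setdefault(find(p), []).append(p)
    return [frozenset(g) for g in sorted(groups.values(), key=min)]


def _fragment_from_positions(
    peptide: ModifiedPeptide,
    positions: FrozenSet[int],
    cut_bonds: FrozenSet[int],
    mass_type: str,
) -> DigestFragment:
    table = get_mass_table(mass_type)
    ordered = sorted(positions)
    # a segment is a maximal run joined by *uncut* backbone bonds: two
    # adjacent residues separated by a hydrolyzed bond are distinct chains
    # even when a crosslink keeps them in the same fragment
    segments: List[Tuple[int, int]] = []
    for pos in ordered:
        if (
            segments
            and pos == segments[-1][1] + 1
            and (pos - 1) not in cut_bonds
        ):
            segments[-1] = (segments[-1][0], pos)
        else:
            segments.append((pos, pos))
    n_internal = sum(
        1 for b in cut_bonds if b in positions and b + 1 in positions
    )
    mass = sum(table.residue(peptide.residue(p)) for p in ordered)
    mass += table.water * len(segments)
    from .masses import MODIFICATIONS

    for p in ordered:
        st = peptide.state(p)
        if st in ("Dha", "Dhb"):
            mass += MODIFICATIONS["dehydration"].delta_for(mass_type)
        elif st == "phospho":
            mass += MODIFICATIONS["phosphorylation"].delta_for(mass_type)
        elif st == "cam":
            mass += MODIFICATIONS["carbamidomethyl"].delta_for(mass_type)
    return DigestFragment(
        member_segments=tuple(segments),
        n_internal_cuts=n_internal,
        neutral_mass=mass,
    )


def digest(
    peptide: ModifiedPeptide,
    rule: ProteaseRule | str,
    missed_cleavages: int = 0,
    mass_type: str = "mono",
) -> List[DigestFragment]:
    """In-silico digest of a (possibly crosslinked) peptide.

    With ``missed_cleavages = 0`` every matching bond is hydrolyzed and the
    fragments are the crosslink-connected components. With ``k > 0``,
    products arising from leaving up to ``k`` sites uncut are appended
    (deduplicated), as in a standard partial digest.

    A peptide with no matching sites returns itself as a single fragment.
    """
    if isinstance(rule, str):
        try:
            rule = PROTEASES[rule]
        except KeyError:
            raise KeyError(f"unknown protease {rule!r}") from None
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")

    all_sites = rule.cut_sites(peptide)
    seen = set()
    fragments: List[DigestFragment] = []

    def add_for(cuts: FrozenSet[int]):
        for comp in _components(peptide, cuts):
            frag = _fragment_from_positions(peptide, comp, cuts, mass_type)
            key = frag.member_segments
            if key not in seen:
                seen.add(key)
                fragments.append(frag)

    add_for(frozenset(all_sites))
    for k in range(1, missed_cleavages + 1):
        if k > len(all_sites):
            break
        for skipped in itertools.combinations(all_sites, k):
            add_for(frozenset(set(all_sites) - set(skipped)))
    fragments.sort(key=lambda f: (f.first, f.last, f.member_segments))
    return fragments


@dataclass(frozen=True)
class CleavageSiteProposal:
    """A candidate leader-peptide cleavage bond.

    ``site`` is the bond cut (after this residue position); ``motif_class``
    is ``AFA_like`` for Ala/Pro-Phe-Ala signal-peptidase-type motifs,
    ``double_gly_like`` for Gly-Ala / Ala-Ala double-glycine-type motifs.
    """

    site: int
    motif_class: str
    matched_text: str
    motif_span: Tuple[int, int]


def propose_leader_cleavage_sites(
    sequence: str, numbering_offset: int = 1
) -> List[CleavageSiteProposal]:
    """Scan a precursor for candidate leader-cleavage motifs.

    Two motif families are recognized, both taken from characterized
    lanthipeptide precursors: X-Phe-Ala with X in {Ala, Pro} (cut after the
    terminal Ala, as for cinnamycin's AFA site), and the double-Gly-type
    pairs Gly-Ala and Ala-Ala (cut after the second residue). All matches
    are reported in position order; overlapping motifs are all kept, since
    the actual processing protease is generally unknown.
    """
    if len(sequence) < 3:
        raise ValueError("sequence must have length >= 3")
    seq = sequence.upper()
    proposals: List[CleavageSiteProposal] = []
    for m in re.finditer("(?=([AP]FA))", seq):
        start = m.start() + numbering_offset
        proposals.append(
            CleavageSiteProposal(
                site=start + 2,
                motif_class="AFA_like",
                matched_text=m.group(1),
                motif_span=(start, start + 2),
            )
        )
    for m in re.finditer("(?=(GA|AA))", seq):
        start = m.start() + numbering_offset
        proposals.append(
            CleavageSiteProposal(
                site=start + 1,
                motif_class="double_gly_like",
                matched_text=m.group(1),
                motif_span=(start, start + 1),
            )
        )
    proposals.sort(key=lambda p: (p.motif_span[0], p.motif_class))
    return proposals
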