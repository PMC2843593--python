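"""Ring-topology inference from a wild-type + Cys->Ala variant series.

The unknown is a partial matching between Cys positions and dehydro
(Dha/Dhb) positions. Constraints come from tandem-MS fragmentation:

* **strict** constraints — an observed b/y'' ion at bond ``i`` proves the
  bond is cleavable, hence spanned by no ring. These are positive facts
  and are always applied.
* **protection assertions** — a contiguous ion-free span read as "this
  region is ring-covered". Absence of ions is weaker evidence (an ion may
  simply not have been detected), so these are applied only in
  ``protection_assertion`` mode, where they are what makes the deduction
  converge to a unique topology.

Each variant is solved independently (mutants default to *partial*
matchings because knocking out one Cys can leave another uncyclized);
rings necessary in *every* consistent topology of some variant are then
promoted to requirements for the wild type, whose surviving candidate set
is the answer.

The model/results surface follows the statsmodels convention:
``RingTopologyModel(observations, span=...).fit()`` returns a
:class:`RingTopologyResults` with the candidate set, per-variant
diagnostics, and a ``summary()`` table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .fragments import CleavageEvidence
from .peptide import Topology

__all__ = [
    "VariantObservation",
    "SolverResult",
    "enumerate_topologies",
    "filter_consistent",
    "apply_protection_assertions",
    "combine_evidence",
    "RingTopologyModel",
    "RingTopologyResults",
    "MAX_CYS_DEFAULT",
]

#: Refuse enumeration above this many Cys without an explicit override
#: (8! complete matchings is still desk-scale; beyond that, opt in).
MAX_CYS_DEFAULT = 8


@dataclass(frozen=True)
class VariantObservation:
    """One peptide variant's residue sets plus its MS evidence.

    ``cys_positions`` reflects the substitution (a Cys->Ala variant loses
    that position); ``dehydro_positions`` maps position -> "Dha"/"Dhb".
    ``completeness`` is ``"complete"`` when every present Cys is known to
    be cyclized (zero iodoacetamide shift), ``"partial"`` otherwise.
    """

    variant_id: str
    cys_positions: FrozenSet[int]
    dehydro_positions: Mapping[int, str]
    evidence: CleavageEvidence
    asserted_protected_spans: Tuple[Tuple[int, int], ...] = ()
    completeness: str = "partial"

    def __post_init__(self):
        object.__setattr__(self, "cys_positions", frozenset(self.cys_positions))
        object.__setattr__(
            self, "dehydro_positions", dict(self.dehydro_positions)
        )
        object.__setattr__(
            self,
            "asserted_protected_spans",
            tuple((int(a), int(b)) for a, b in self.asserted_protected_spans),
        )
        if self.completeness not in ("complete", "partial"):
            raise ValueError(f"bad completeness {self.completeness!r}")
        overlap = self.cys_positions & set(self.dehydro_positions)
        if overlap:
            raise ValueError(f"positions both Cys and dehydro: {sorted(overlap)}")


@dataclass
class SolverResult:
    """Consistent topologies for one variant (deduplicated, sorted)."""

    variant_id: str
    consistent_topologies: List[Topology]
    mode: str

    def necessary_rings(self) -> FrozenSet[Tuple[int, int]]:
        """Rings present in every consistent topology (empty set if none
        or if no topology is consistent)."""
        if not self.consistent_topologies:
            return frozenset()
        common = set(self.consistent_topologies[0].rings)
        for t in self.consistent_topologies[1:]:
            common &= t.rings
        return frozenset(common)


def _normalize_pairs(
    pairs: Iterable[Tuple[int, int]],
    cys: FrozenSet[int],
    dehydro: FrozenSet[int],
    what: str,
) -> Set[Tuple[int, int]]:
    """Orient (a, b) pairs as (cys, dehydro); error on missing positions."""
    out: Set[Tuple[int, int]] = set()
    for a, b in pairs:
        if a in cys and b in dehydro:
            out.add((a, b))
        elif b in cys and a in dehydro:
            out.add((b, a))
        else:
            raise ValueError(
                f"{what} ring ({a},{b}) uses positions absent from the "
                f"available Cys {sorted(cys)} / dehydro {sorted(dehydro)} sets"
            )
    return out


def enumerate_topologies(
    cys: Iterable[int],
    dehydro: Iterable[int],
    required_rings: Iterable[Tuple[int, int]] = (),
    forbidden_pairs: Iterable[Tuple[int, int]] = (),
    complete: bool = True,
    max_cys: int = MAX_CYS_DEFAULT,
) -> List[Topology]:
    """All injective Cys -> dehydro matchings under the given constraints.

    ``required_rings`` must appear in every topology; ``forbidden_pairs``
    may appear in none. With ``complete=True`` every Cys is paired; with
    ``complete=False`` any subset of Cys may remain unpaired (partial
    matchings). Pairing is direction-agnostic: a Cys may precede or follow
    its dehydro partner in the sequence. Output is deduplicated and sorted
    lexicographically by sorted ring pairs.
    """
    cys_set = frozenset(int(c) for c in cys)
    dehydro_set = frozenset(int(d) for d in dehydro)
    if cys_set & dehydro_set:
        raise ValueError("cys and dehydro position sets must be disjoint")
    if len(cys_set) > max_cys:
        raise ValueError(
            f"{len(cys_set)} Cys exceeds the enumeration guard "
            f"(max_cys={max_cys}); pass a larger max_cys to override"
        )
    required = _normalize_pairs(required_rings, cys_set, dehydro_set, "required")
    req_cys = {c for c, _ in required}
    req_dehydro = {d for _, d in required}
    if len(req_cys) != len(required) or len(req_dehydro) != len(required):
        return []  # required rings conflict on a shared position
    forbidden: Set[FrozenSet[int]] = {
        frozenset(p) for p in forbidden_pairs
    }
    if any(frozenset((c, d)) in forbidden for c, d in required):
        return []

    free_cys = sorted(cys_set - req_cys)
    free_dehydro = sorted(dehydro_set - req_dehydro)

    results: Set[Topology] = set()
    if complete:
        cys_subsets = [tuple(free_cys)]
        if len(free_cys) > len(free_dehydro):
            cys_subsets = []  # infeasible: some Cys cannot be paired
    else:
        cys_subsets = [
            subset
            for r in range(len(free_cys) + 1)
            for subset in itertools.combinations(free_cys, r)
        ]
    for subset in cys_subsets:
        for partners in itertools.permutations(free_dehydro, len(subset)):
            pairs = set(zip(subset, partners))
            if any(frozenset(p) in forbidden for p in pairs):
                continue
            results.add(Topology(required | pairs))
    return sorted(results, key=lambda t: t.sorted_rings())


def filter_consistent(
    candidates: Sequence[Topology],
    evidence: CleavageEvidence,
    span: Tuple[int, int],
) -> List[Topology]:
    """Keep topologies under which every evidenced bond is separating.

    An observed cleavage at bond ``i`` proves no ring spans it. Absence of
    ions imposes no constraint here (that is what protection assertions
    are for).
    """
    first, last = span
    for bond in evidence.cleavable_bonds:
        if not first <= bond < last:
            raise ValueError(f"evidence bond {bond} outside span {span}")
    return [
        t
        for t in candidates
        if not any(t.spans_bond(b) for b in evidence.cleavable_bonds)
    ]


def apply_protection_assertions(
    candidates: Sequence[Topology],
    spans: Iterable[Tuple[int, int]],
) -> List[Topology]:
    """Keep topologies whose rings cover every bond of each asserted span.

    A span ``(start, end)`` asserts that bonds ``start .. end-1`` are all
    ring-protected. An empty span list is the identity.
    """
    spans = list(spans)
    kept = []
    for t in candidates:
        ok = all(
            t.spans_bond(b) for a, e in spans for b in range(a, e)
        )
        if ok:
            kept.append(t)
    return kept


def solve_variant(
    obs: VariantObservation,
    span: Tuple[int, int],
    mode: str = "strict",
    max_cys: int = MAX_CYS_DEFAULT,
    required_rings: Iterable[Tuple[int, int]] = (),
) -> SolverResult:
    """Enumerate-and-filter for a single variant observation."""
    if mode not in ("strict", "protection_assertion"):
        raise ValueError(f"unknown mode {mode!r}")
    candidates = enumerate_topologies(
        obs.cys_positions,
        obs.dehydro_positions,
        required_rings=required_rings,
        complete=(obs.completeness == "complete"),
        max_cys=max_cys,
    )
    candidates = filter_consistent(candidates, obs.evidence, span)
    if mode == "protection_assertion":
        candidates = apply_protection_assertions(
            candidates, obs.asserted_protected_spans
        )
    return SolverResult(obs.variant_id, candidates, mode)


def _first_violation(
    topology: Topology,
    obs: VariantObservation,
    mode: str,
) -> Optional[str]:
    """Name the first constraint of ``obs`` this topology violates."""
    for bond in sorted(obs.evidence.cleavable_bonds):
        if topology.spans_bond(bond):
            return (
                f"{obs.variant_id}: observed cleavage at bond {bond} "
                f"but a ring spans it"
            )
    if mode == "protection_assertion":
        for a, e in obs.asserted_protected_spans:
            for bond in range(a, e):
                if not topology.spans_bond(bond):
                    return (
                        f"{obs.variant_id}: asserted protected span "
                        f"({a},{e}) has uncovered bond {bond}"
                    )
    return None


def combine_evidence(
    observations: Sequence[VariantObservation],
    wild_type_id: str,
    span: Tuple[int, int],
    mode: str = "strict",
    max_cys: int = MAX_CYS_DEFAULT,
) -> "RingTopologyResults":
    """Intersect evidence across a variant series; see module docstring.

    Returns a :class:`RingTopologyResults`. An empty final set is returned
    with a conflict report (one line per eliminated wild-type candidate),
    not raised: contradictory evidence is a finding, not a crash.
    """
    by_id = {o.variant_id: o for o in observations}
    if wild_type_id not in by_id:
        raise KeyError(f"wild-type id {wild_type_id!r} not among observations")
    wt = by_id[wild_type_id]

    variant_results: Dict[str, SolverResult] = {}
    evidenced: Set[Tuple[int, int]] = set()
    for obs in observations:
        res = solve_variant(obs, span, mode=mode, max_cys=max_cys)
        variant_results[obs.variant_id] = res
        if obs.variant_id == wild_type_id:
            continue
        present = obs.cys_positions | set(obs.dehydro_positions)
        for ring in res.necessary_rings():
            if set(ring) <= present:
                evidenced.add(ring)

    # Rings necessary in a mutant are rings the mutant truly carries, and a
    # mutant's rings are a subset of the wild type's; require them.
    wt_candidates = enumerate_topologies(
        wt.cys_positions,
        wt.dehydro_positions,
        required_rings=evidenced,
        complete=(wt.completeness == "complete"),
        max_cys=max_cys,
    )
    survivors = filter_consistent(wt_candidates, wt.evidence, span)
    if mode == "protection_assertion":
        survivors = apply_protection_assertions(
            survivors, wt.asserted_protected_spans
        )

    conflict_report: List[str] = []
    if not survivors:
        for cand in wt_candidates:
            msg = _first_violation(cand, wt, mode)
            if msg is not None:
                conflict_report.append(f"{cand!r}: {msg}")
        if not wt_candidates:
            conflict_report.append(
                "no wild-type candidate admits the variant-evidenced rings "
                f"{sorted(evidenced)}"
            )

    return RingTopologyResults(
        topologies=survivors,
        mode=mode,
        wild_type_id=wild_type_id,
        variant_results=variant_results,
        evidenced_rings=frozenset(evidenced),
        conflict_report=conflict_report,
        span=span,
        dehydro_classes=dict(wt.dehydro_positions),
    )


class RingTopologyModel:
    """Ring-topology deduction model over a variant observation series.

    Parameters
    ----------
    observations : sequence of VariantObservation
        The wild type plus any number of Cys->Ala variants.
    span : (first, last)
        Residue span (precursor coordinates) of the analyzed peptide.
    wild_type_id : str
        Which observation is the wild type (default ``"WT"``).
    """

    def __init__(
        self,
        observations: Sequence[VariantObservation],
        span: Tuple[int, int],
        wild_type_id: str = "WT",
        max_cys: int = MAX_CYS_DEFAULT,
    ):
        self.observations = list(observations)
        self.span = (int(span[0]), int(span[1]))
        self.wild_type_id = wild_type_id
        self.max_cys = max_cys
        if not self.observations:
            raise ValueError("at least one observation required")
        if wild_type_id not in {o.variant_id for o in self.observations}:
            raise KeyError(f"wild-type id {wild_type_id!r} not among observations")

    def fit(self, mode: str = "protection_assertion") -> "RingTopologyResults":
        """Solve the series. ``mode`` is ``"strict"`` (positive cleavage
        constraints only) or ``"protection_assertion"`` (additionally
        require asserted ion-free spans to be ring-covered)."""
        return combine_evidence(
            self.observations,
            self.wild_type_id,
            self.span,
            mode=mode,
            max_cys=self.max_cys,
        )


@dataclass
class RingTopologyResults:
    """Outcome of a :class:`RingTopologyModel` fit.

    ``topologies`` is the surviving wild-type candidate set (the answer:
    unique when the evidence pins the structure); ``evidenced_rings`` are
    the rings promoted from variant necessity; ``variant_results`` hold
    the per-variant candidate sets for diagnostics.
    """

    topologies: List[Topology]
    mode: str
    wild_type_id: str
    variant_results: Dict[str, SolverResult]
    evidenced_rings: FrozenSet[Tuple[int, int]]
    conflict_report: List[str] = field(default_factory=list)
    span: Tuple[int, int] = (0, 0)
    dehydro_classes: Mapping[int, str] = field(default_factory=dict)

    @property
    def unique(self) -> bool:
        return len(self.topologies) == 1

    @property
    def topology(self) -> Topology:
        if not self.unique:
            raise ValueError(
                f"{len(self.topologies)} topologies remain; no unique answer"
            )
        return self.topologies[0]

    def ring_table(self):
        """The unique topology as a pandas DataFrame (cys, dehydro, class).

        A Cys paired with a Dha is a lanthionine (Lan), with a Dhb a
        methyllanthionine (MeLan).
        """
        import pandas as pd

        rows = [
            {
                "cys": c,
                "dehydro": d,
                "ring": "Lan" if self.dehydro_classes.get(d) == "Dha" else "MeLan",
            }
            for c, d in self.topology.sorted_rings()
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Ring topology inference",
            "=" * 55,
            f"mode:                 {self.mode}",
            f"wild type:            {self.wild_type_id}",
            f"span:                 {self.span[0]}..{self.span[1]}",
            f"variants:             {len(self.variant_results)}",
            f"variant-evidenced:    {sorted(self.evidenced_rings)}",
            f"surviving topologies: {len(self.topologies)}",
        ]
        for vid in sorted(self.variant_results):
            res = self.variant_results[vid]
            lines.append(
                f"  {vid:<12} consistent topologies: "
                f"{len(res.consistent_topologies)}"
            )
        if self.unique:
            lines.append("final topology (cys, dehydro):")
            for c, d in self.topology.sorted_rings():
                lines.append(f"  Cys{c} -- {d}")
        elif not self.topologies:
            lines.append("CONFLICT: no topology satisfies all constraints")
            lines.extend(f"  {msg}" for msg in self.conflict_report[:10])
        else:
            for t in self.topologies:
                lines.append(f"  candidate: {list(t.sorted_rings())}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "wild_type_id": self.wild_type_id,
            "span": list(self.span),
            "evidenced_rings": sorted(map(list, self.evidenced_rings)),
            "topologies": [
                [list(r) for r in t.sorted_rings()] for t in self.topologies
            ],
            "conflict_report": list(self.conflict_report),
            "variant_results": {
                vid: [
                    [list(r) for r in t.sorted_rings()]
                    for t in res.consistent_topologies
                ]
                for vid, res in self.variant_results.items()
            },
        }
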