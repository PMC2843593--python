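"""Seeded generator of synthetic lanthipeptide instances and observations.

Emulates the experimental design end to end without instrument data:

1. draw a precursor with a leader/core split, Cys and Ser/Thr placed
   uniformly in the core, and a hidden injective Cys<->dehydro matching
   (the true ring topology);
2. emit intact neutral masses for each processing stage (unmodified, a
   partial phosphorylation ladder, fully dehydrated, cyclized, and
   iodoacetamide-treated);
3. emit per-variant fragment peak lists for the wild type plus one
   Cys->Ala variant per Cys, with configurable ion-detection probability,
   Gaussian m/z noise, uniform decoy peaks, and optional collateral ring
   loss (mutating one Cys may abolish another Cys's ring, as observed for
   the C32A variant of VenA).

All randomness flows from a single seed through ``numpy`` spawned child
generators, so per-variant streams are independent yet reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .digestion import PROTEASES, ProteaseRule
from .fragments import (
    PeakList,
    match_peaks,
    predict_fragments,
    protected_spans_from_evidence,
)
from .masses import modification_delta
from .peptide import ModifiedPeptide, Topology
from .solver import VariantObservation

__all__ = [
    "SimulationConfig",
    "SimulatedInstance",
    "generate_instance",
    "simulate_stage_masses",
    "simulate_variant_spectra",
    "observations_from_instance",
]

_LEADER_ALPHABET = "ADEFGHIKLMNPQRVWY"  # no Ser/Thr/Cys in the leader
_FILLER_ALPHABET = "AFGHIKLMNPQRVWY"  # core filler: no Ser/Thr/Cys/Asp/Glu


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings. Defaults state a venezuelin-like world:
    a 34-residue core carrying four Cys and four dehydro residues, full
    ion coverage and no noise (the regime in which the published data were
    interpretable), with noise knobs available for degradation studies.
    """

    seed: int = 0
    core_length: int = 34
    n_cys: int = 4
    n_dehydro: int = 4
    leader_length: int = 17
    allow_crossing_rings: bool = True
    p_ion_detect: float = 1.0
    mass_noise_sd: float = 0.0
    n_noise_peaks: int = 0
    collateral_loss: Mapping[int, FrozenSet[Tuple[int, int]]] = field(
        default_factory=dict
    )
    protease: ProteaseRule = field(default_factory=lambda: PROTEASES["gluc"])

    def validate(self) -> None:
        if self.n_cys < 0 or self.n_dehydro < 0:
            raise ValueError("counts must be non-negative")
        if self.n_cys > self.n_dehydro:
            raise ValueError("n_cys must not exceed n_dehydro")
        if self.n_cys + self.n_dehydro > self.core_length:
            raise ValueError("core too short for requested Cys + dehydro sites")
        if not 0.0 <= self.p_ion_detect <= 1.0:
            raise ValueError("p_ion_detect must be in [0, 1]")
        if self.mass_noise_sd < 0:
            raise ValueError("mass_noise_sd must be >= 0")
        if self.leader_length < 1:
            raise ValueError("leader_length must be >= 1")


@dataclass
class SimulatedInstance:
    """One generated world: precursor, hidden truth, and variant series."""

    config: SimulationConfig
    precursor: ModifiedPeptide
    core_span: Tuple[int, int]
    true_topology: Topology
    #: (variant_id, substituted Cys position or None, rings present)
    variant_series: List[Tuple[str, Optional[int], Topology]]

    def core(self) -> ModifiedPeptide:
        return self.precursor.subsequence(*self.core_span, new_id="core")


def _sample_positions(rng: np.random.Generator, cfg: SimulationConfig):
    """Place Cys and dehydro sites uniformly in the core, no collisions
    and no Cys-Cys adjacency (keeps b/y bookkeeping unambiguous)."""
    first = cfg.leader_length + 1
    last = cfg.leader_length + cfg.core_length
    positions = np.arange(first, last + 1)
    for _ in range(1000):
        chosen = rng.choice(positions, size=cfg.n_cys + cfg.n_dehydro, replace=False)
        cys = sorted(int(p) for p in chosen[: cfg.n_cys])
        dehydro = sorted(int(p) for p in chosen[cfg.n_cys :])
        if all(b - a > 1 for a, b in zip(cys, cys[1:])):
            return cys, dehydro
    raise RuntimeError("could not place Cys without adjacency")


def _crossing(pairs: Sequence[Tuple[int, int]]) -> bool:
    ivals = [tuple(sorted(p)) for p in pairs]
    for i, (a1, b1) in enumerate(ivals):
        for a2, b2 in ivals[i + 1 :]:
            if a1 < a2 < b1 < b2 or a2 < a1 < b2 < b1:
                return True
    return False


def _sample_matching(
    rng: np.random.Generator,
    cys: Sequence[int],
    dehydro: Sequence[int],
    allow_crossing: bool = True,
    max_tries: int = 10000,
) -> Topology:
    """Uniform random injective Cys -> dehydro matching (rejection-sampled
    to be non-crossing when requested)."""
    dehydro = list(dehydro)
    for _ in range(max_tries):
        partners = rng.permutation(len(dehydro))[: len(cys)]
        pairs = [(c, dehydro[int(i)]) for c, i in zip(cys, partners)]
        if allow_crossing or not _crossing(pairs):
            return Topology(pairs)
    raise RuntimeError("no non-crossing matching found")


def generate_instance(cfg: SimulationConfig) -> SimulatedInstance:
    """Draw a complete synthetic instance; deterministic given the seed."""
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    ss_layout, ss_match, _ = root.spawn(3)
    rng = np.random.default_rng(ss_layout)

    cys, dehydro = _sample_positions(rng, cfg)
    first = cfg.leader_length + 1
    last = cfg.leader_length + cfg.core_length

    # dehydro residue class: coin flip Ser (-> Dha) vs Thr (-> Dhb)
    classes = {
        p: ("Dha" if rng.random() < 0.5 else "Dhb") for p in dehydro
    }

    leader = "".join(
        rng.choice(list(_LEADER_ALPHABET), size=cfg.leader_length - 1)
    )
    leader += "E"  # GluC site at the leader/core junction
    core = [
        str(rng.choice(list(_FILLER_ALPHABET)))
        for _ in range(cfg.core_length)
    ]
    for p in cys:
        core[p - first] = "C"
    for p in dehydro:
        core[p - first] = "S" if classes[p] == "Dha" else "T"

    topology = _sample_matching(
        np.random.default_rng(ss_match), cys, dehydro, cfg.allow_crossing_rings
    )

    precursor = ModifiedPeptide(
        id=f"sim{cfg.seed}",
        sequence=leader + "".join(core),
        numbering_offset=1,
        states=classes,
        crosslinks=topology,
    )

    collateral = {
        int(c): frozenset(tuple(sorted(r)) for r in rings)
        for c, rings in cfg.collateral_loss.items()
    }
    series: List[Tuple[str, Optional[int], Topology]] = [
        ("WT", None, topology)
    ]
    for c in cys:
        lost = {r for r in topology if c in r}
        lost |= {
            r
            for r in topology
            if tuple(sorted(r)) in collateral.get(c, frozenset())
        }
        series.append((f"C{c}A", c, Topology(topology.rings - lost)))

    return SimulatedInstance(
        config=cfg,
        precursor=precursor,
        core_span=(first, last),
        true_topology=topology,
        variant_series=series,
    )


def simulate_stage_masses(
    inst: SimulatedInstance, mass_type: str = "mono"
) -> List[Tuple[str, float]]:
    """Neutral masses of the precursor at each processing stage.

    Stages: unmodified; a partial phosphorylation ladder (2..n events, as
    a kinase-domain-only assay shows); fully dehydrated; cyclized (mass
    identical to dehydrated — Michael addition adds nothing); and
    iodoacetamide-treated cyclized material (+57.0215 Da per free Cys).
    Gaussian noise of ``mass_noise_sd`` is added to every emitted mass.
    """
    cfg = inst.config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[2])
    base = ModifiedPeptide(
        id=inst.precursor.id,
        sequence=inst.precursor.sequence,
        numbering_offset=inst.precursor.numbering_offset,
    ).neutral_mass(mass_type)
    n = len(inst.precursor.dehydro_positions())
    dehydrated = base + n * modification_delta("dehydration", mass_type)
    free_cys = inst.precursor.cys_positions() - inst.true_topology.positions()
    iaa = dehydrated + len(free_cys) * modification_delta(
        "carbamidomethyl", mass_type
    )

    def noisy(m: float) -> float:
        return m + (rng.normal(0.0, cfg.mass_noise_sd) if cfg.mass_noise_sd else 0.0)

    out = [("unmodified", noisy(base))]
    for k in range(2, n + 1):
        out.append(
            (
                f"phospho_{k}",
                noisy(base + k * modification_delta("phosphorylation", mass_type)),
            )
        )
    out.append(("dehydrated", noisy(dehydrated)))
    out.append(("cyclized", noisy(dehydrated)))
    out.append(("iaa", noisy(iaa)))
    return out


def _variant_core(
    inst: SimulatedInstance, substituted: Optional[int], rings: Topology
) -> ModifiedPeptide:
    precursor = inst.precursor
    if substituted is not None:
        precursor = precursor.substitute(substituted, "A", f"C{substituted}A")
    core = precursor.subsequence(*inst.core_span)
    return core.with_crosslinks(rings)


def simulate_variant_spectra(
    inst: SimulatedInstance,
    charges: Sequence[int] = (1,),
    mass_type: str = "mono",
) -> Dict[str, PeakList]:
    """Per-variant peak lists for the digested core peptide.

    Each separating bond's b and y'' ions are emitted with probability
    ``p_ion_detect``, jittered by ``mass_noise_sd``; ``n_noise_peaks``
    uniform decoys are appended within the observed m/z range.
    """
    cfg = inst.config
    root = np.random.SeedSequence(cfg.seed).spawn(4)[3]
    child_seeds = root.spawn(len(inst.variant_series))
    spectra: Dict[str, PeakList] = {}
    for (variant_id, substituted, rings), ss in zip(
        inst.variant_series, child_seeds
    ):
        rng = np.random.default_rng(ss)
        core = _variant_core(inst, substituted, rings)
        ions = predict_fragments(core, charges, mass_type)
        entries: List[Tuple[float, float]] = []
        for ion in ions:
            # rng.random() is in [0, 1): detect-all and detect-none are exact
            if cfg.p_ion_detect >= 1.0 or rng.random() < cfg.p_ion_detect:
                jitter = (
                    rng.normal(0.0, cfg.mass_noise_sd)
                    if cfg.mass_noise_sd
                    else 0.0
                )
                entries.append((ion.mz + jitter, float(rng.random())))
        if cfg.n_noise_peaks and ions:
            lo = min(i.mz for i in ions)
            hi = max(i.mz for i in ions)
            for _ in range(cfg.n_noise_peaks):
                entries.append(
                    (float(rng.uniform(lo, hi)), float(rng.random()))
                )
        spectra[variant_id] = PeakList(entries)
    return spectra


def observations_from_instance(
    inst: SimulatedInstance,
    spectra: Optional[Mapping[str, PeakList]] = None,
    tol: Optional[float] = None,
    min_protected_bonds: int = 3,
    charges: Sequence[int] = (1,),
    mass_type: str = "mono",
) -> List[VariantObservation]:
    """Run the matching pipeline on simulated spectra and package the
    results as solver observations.

    Predicted ions for matching are computed from the *unknown-topology*
    (ring-free) variant core — the analyst does not know the rings — so
    every bond's b/y'' ions are candidates. Protected spans are the
    maximal ion-free runs of at least ``min_protected_bonds`` bonds. Wild
    type is marked ``complete`` when the simulated IAA stage shows no free
    thiols.

    ``tol`` defaults to five standard deviations of the simulated m/z
    noise (floored at 0.001 Da for noiseless data): the tolerance should
    track the mass accuracy, and a needlessly wide window on clean data
    invites coincidental cross-matches between unrelated ions.
    """
    if tol is None:
        tol = max(5.0 * inst.config.mass_noise_sd, 0.001)
    if spectra is None:
        spectra = simulate_variant_spectra(inst, charges, mass_type)
    free_cys = inst.precursor.cys_positions() - inst.true_topology.positions()
    observations: List[VariantObservation] = []
    for variant_id, substituted, _rings in inst.variant_series:
        naked = _variant_core(inst, substituted, Topology())
        predicted = predict_fragments(naked, charges, mass_type)
        evidence = match_peaks(
            predicted, spectra[variant_id], tol=tol, variant_id=variant_id
        )
        spans = protected_spans_from_evidence(
            evidence, inst.core_span, min_bonds=min_protected_bonds
        )
        cys = naked.cys_positions()
        completeness = (
            "complete"
            if variant_id == "WT" and not free_cys
            else "partial"
        )
        observations.append(
            VariantObservation(
                variant_id=variant_id,
                cys_positions=cys,
                dehydro_positions=naked.dehydro_positions(),
                evidence=evidence,
                asserted_protected_spans=tuple(spans),
                completeness=completeness,
            )
        )
    return observations
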