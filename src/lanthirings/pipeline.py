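"""End-to-end analysis: digest -> predict -> match -> solve.

The pipeline mirrors the experimental workflow for characterizing an
enzymatically cyclized precursor: excise the modified core by
proteolysis, predict b/y'' ions per variant, match them against the
observed peak lists, convert ion-free runs into protection assertions,
and intersect the evidence across the variant series to deduce the ring
topology.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from . import presets
from .digestion import PROTEASES, digest
from .fragments import (
    PeakList,
    match_peaks,
    predict_fragments,
    protected_spans_from_evidence,
)
from .io import RunConfig, write_json_atomic
from .peptide import ModifiedPeptide, Topology
from .solver import RingTopologyModel, RingTopologyResults, VariantObservation

__all__ = ["AnalysisReport", "run_pipeline"]


@dataclass
class AnalysisReport:
    """Serializable record of one pipeline run."""

    config: Dict
    stages: Dict = field(default_factory=dict)
    mod_count_calls: List[Dict] = field(default_factory=list)
    evidence: Dict[str, List[int]] = field(default_factory=dict)
    asserted_spans: Dict[str, List[List[int]]] = field(default_factory=dict)
    topologies: List[List[List[int]]] = field(default_factory=list)
    evidenced_rings: List[List[int]] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)
    timestamp: Optional[float] = None

    def to_dict(self) -> Dict:
        return {
            "config": self.config,
            "stages": self.stages,
            "mod_count_calls": self.mod_count_calls,
            "evidence": self.evidence,
            "asserted_spans": self.asserted_spans,
            "topologies": self.topologies,
            "evidenced_rings": self.evidenced_rings,
            "warnings": self.warnings,
            "timestamp": self.timestamp,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "AnalysisReport":
        return cls(**dict(data))


def _observations_from_peaklists(
    precursor: ModifiedPeptide,
    variants: Sequence[Tuple[str, Mapping[int, str]]],
    peaklists: Mapping[str, PeakList],
    config: RunConfig,
    report: AnalysisReport,
) -> Tuple[List[VariantObservation], Tuple[int, int]]:
    """Digest each variant precursor, predict ions (no ring knowledge),
    match against that variant's peaks, and derive protected spans."""
    rule = PROTEASES[config.protease]
    fragments = digest(precursor, rule, mass_type=config.mass_type)
    core_frag = max(fragments, key=lambda f: f.last - f.first)
    span = (core_frag.first, core_frag.last)
    report.stages["digest"] = {
        "protease": config.protease,
        "fragments": [
            {
                "segments": [list(s) for s in f.member_segments],
                "n_internal_cuts": f.n_internal_cuts,
                "neutral_mass": round(f.neutral_mass, 4),
            }
            for f in fragments
        ],
        "core_span": list(span),
    }

    observations: List[VariantObservation] = []
    for variant_id, substitutions in variants:
        var = precursor
        for pos, aa in substitutions.items():
            var = var.substitute(pos, aa, variant_id)
        core = var.subsequence(*span).with_crosslinks(Topology())
        predicted = predict_fragments(core, (1,), config.mass_type)
        if variant_id not in peaklists:
            report.warnings.append(f"no peak list for variant {variant_id!r}")
            continue
        ev = match_peaks(
            predicted,
            peaklists[variant_id],
            tol=config.fragment_tol,
            variant_id=variant_id,
        )
        if not ev.cleavable_bonds:
            report.warnings.append(
                f"variant {variant_id!r}: empty peak list or no matches; "
                "no cleavage constraints derived"
            )
        spans = protected_spans_from_evidence(ev, span)
        observations.append(
            VariantObservation(
                variant_id=variant_id,
                cys_positions=core.cys_positions(),
                dehydro_positions=core.dehydro_positions(),
                evidence=ev,
                asserted_protected_spans=tuple(spans),
                completeness="complete" if not substitutions else "partial",
            )
        )
    return observations, span


def run_pipeline(
    config: RunConfig,
    precursor: Optional[ModifiedPeptide] = None,
    variants: Optional[Sequence[Tuple[str, Mapping[int, str]]]] = None,
    peaklists: Optional[Mapping[str, PeakList]] = None,
    observations: Optional[Sequence[VariantObservation]] = None,
    span: Optional[Tuple[int, int]] = None,
    wild_type_id: str = "WT",
    preset: Optional[str] = None,
    report_path: Optional[str | Path] = None,
) -> Tuple[AnalysisReport, RingTopologyResults]:
    """Execute digest -> predict -> match -> solve and assemble a report.

    Inputs are either a ``preset`` name ("venezuelin"), pre-built
    ``observations`` (with ``span``), or a ``precursor`` + ``variants`` +
    per-variant ``peaklists``. The report is written atomically when
    ``report_path`` is given.
    """
    report = AnalysisReport(config=vars(config).copy(), timestamp=time.time())

    if preset is not None:
        if preset != "venezuelin":
            raise ValueError(f"unknown preset {preset!r}")
        observations = presets.venezuelin_observations()
        span = presets.CORE_SPAN
        wild_type_id = "WT"
        # record the digest stage for the preset precursor too
        frags = digest(presets.venezuelin_precursor(), PROTEASES[config.protease])
        report.stages["digest"] = {
            "protease": config.protease,
            "fragments": [
                {
                    "segments": [list(s) for s in f.member_segments],
                    "n_internal_cuts": f.n_internal_cuts,
                    "neutral_mass": round(f.neutral_mass, 4),
                }
                for f in frags
            ],
            "core_span": list(span),
        }
    elif observations is None:
        if precursor is None or variants is None or peaklists is None:
            raise ValueError(
                "provide a preset, observations, or "
                "precursor + variants + peaklists"
            )
        observations, span = _observations_from_peaklists(
            precursor, variants, peaklists, config, report
        )
    if span is None:
        raise ValueError("span is required with pre-built observations")

    for obs in observations:
        report.evidence[obs.variant_id] = sorted(obs.evidence.cleavable_bonds)
        report.asserted_spans[obs.variant_id] = [
            list(s) for s in obs.asserted_protected_spans
        ]

    model = RingTopologyModel(observations, span=span, wild_type_id=wild_type_id)
    results = model.fit(mode=config.solver_mode)

    report.topologies = [
        [list(r) for r in t.sorted_rings()] for t in results.topologies
    ]
    report.evidenced_rings = sorted(map(list, results.evidenced_rings))
    if not results.topologies:
        report.warnings.append("empty topology set: contradictory evidence")
        report.warnings.extend(results.conflict_report[:10])
    elif len(results.topologies) > 1:
        report.warnings.append(
            f"{len(results.topologies)} topologies remain; evidence does "
            "not pin a unique structure"
        )

    if report_path is not None:
        write_json_atomic(report.to_dict(), report_path)
    return report, results
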