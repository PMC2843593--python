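"""File formats and run configuration.

Formats are deliberately plain: FASTA for sequences (the description line
may carry ``pos=<offset>`` so precursor numbering survives fragment
records), a JSON sidecar for modification states and crosslinks keyed by
precursor id and 1-based position, two-column TSV and minimal MGF for
peak lists, TSV for labeled intact masses, and JSON for observations,
configuration and reports. All coordinates in every file are 1-based
inclusive residue positions; bonds are labeled by their N-terminal
residue.
"""

from __future__ import annotations

import json
import os
import re
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fragments import CleavageEvidence, PeakList
from .peptide import ModifiedPeptide, Topology
from .solver import VariantObservation

__all__ = [
    "ParseError",
    "RunConfig",
    "load_config",
    "read_fasta",
    "write_fasta",
    "apply_sidecar",
    "read_peaklist_tsv",
    "write_peaklist_tsv",
    "read_mgf",
    "read_masses_tsv",
    "read_observations",
    "write_observations",
    "write_json_atomic",
]


class ParseError(ValueError):
    """Malformed input; the message names the file and line."""


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings with instrument-class defaults."""

    mass_type: str = "mono"
    intact_tol: float = 1.0  # Da, intact MALDI-style masses
    fragment_tol: float = 0.2  # Da, Q/ToF fragment matching
    solver_mode: str = "protection_assertion"
    protease: str = "gluc"
    output_dir: str = "."
    seed: int = 0

    def __post_init__(self):
        if self.intact_tol <= 0 or self.fragment_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.solver_mode not in ("strict", "protection_assertion"):
            raise ValueError(f"unknown solver_mode {self.solver_mode!r}")


def load_config(path: str | Path) -> RunConfig:
    """Load a JSON or YAML run configuration; unknown keys are rejected."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ParseError(
            f"{path}: unknown config keys {sorted(unknown)}; "
            f"expected a subset of {sorted(known)}"
        )
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# FASTA + JSON sidecar


def read_fasta(path: str | Path) -> List[ModifiedPeptide]:
    """Read peptides from FASTA; ``pos=<n>`` in the description sets the
    numbering offset (default 1)."""
    path = Path(path)
    peptides = []
    for record in SeqIO.parse(str(path), "fasta"):
        offset = 1
        m = re.search(r"\bpos=(\d+)", record.description)
        if m:
            offset = int(m.group(1))
        seq = str(record.seq).upper()
        if not seq:
            raise ParseError(f"{path}: record {record.id!r} has empty sequence")
        peptides.append(
            ModifiedPeptide(id=record.id, sequence=seq, numbering_offset=offset)
        )
    if not peptides:
        raise ParseError(f"{path}: no FASTA records found")
    return peptides


def write_fasta(peptides: Sequence[ModifiedPeptide], path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(p.sequence), id=p.id, description=f"pos={p.numbering_offset}"
        )
        for p in peptides
    ]
    SeqIO.write(records, str(path), "fasta")


def apply_sidecar(
    peptides: Sequence[ModifiedPeptide], path: str | Path
) -> List[ModifiedPeptide]:
    """Attach modification states and crosslinks from a JSON sidecar.

    Sidecar schema: ``{peptide_id: {"states": {"31": "Dhb", ...},
    "crosslinks": [[32, 43], ...]}}``.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: line {exc.lineno}: {exc.msg}") from None
    out = []
    for p in peptides:
        entry = data.get(p.id)
        if entry is None:
            out.append(p)
            continue
        states = {int(k): v for k, v in entry.get("states", {}).items()}
        rings = Topology(tuple(r) for r in entry.get("crosslinks", []))
        out.append(
            ModifiedPeptide(
                id=p.id,
                sequence=p.sequence,
                numbering_offset=p.numbering_offset,
                states=states,
                crosslinks=rings,
            )
        )
    return out


# ---------------------------------------------------------------------------
# peak lists and intact masses


def read_peaklist_tsv(path: str | Path) -> PeakList:
    """Two-column TSV (m/z, intensity); '#' comments and blank lines ok."""
    path = Path(path)
    entries: List[Tuple[float, float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise ParseError(
                f"{path}: line {lineno}: expected two columns (mz, intensity)"
            )
        try:
            entries.append((float(parts[0]), float(parts[1])))
        except ValueError:
            raise ParseError(
                f"{path}: line {lineno}: non-numeric value in {parts[:2]}"
            ) from None
    return PeakList(entries)


def write_peaklist_tsv(peaks: PeakList, path: str | Path) -> None:
    lines = ["#mz\tintensity"]
    lines += [f"{mz:.5f}\t{inten:.4f}" for mz, inten in peaks.entries]
    Path(path).write_text("\n".join(lines) + "\n")


def read_mgf(path: str | Path) -> Dict[str, PeakList]:
    """Minimal MGF reader: BEGIN IONS / TITLE / PEPMASS / peaks / END IONS.

    Returns a mapping from spectrum title (or ``spectrum_<n>``) to
    :class:`PeakList`. Only the features this analysis needs are parsed.
    """
    path = Path(path)
    spectra: Dict[str, PeakList] = {}
    entries: Optional[List[Tuple[float, float]]] = None
    title = None
    count = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "BEGIN IONS":
            if entries is not None:
                raise ParseError(f"{path}: line {lineno}: nested BEGIN IONS")
            entries, title = [], None
        elif line == "END IONS":
            if entries is None:
                raise ParseError(f"{path}: line {lineno}: END IONS without BEGIN")
            count += 1
            spectra[title or f"spectrum_{count}"] = PeakList(entries)
            entries = None
        elif entries is not None:
            if "=" in line:
                key, _, value = line.partition("=")
                if key.upper() == "TITLE":
                    title = value.strip()
                continue  # PEPMASS/CHARGE/etc. are not needed
            parts = line.split()
            try:
                mz_val = float(parts[0])
                inten = float(parts[1]) if len(parts) > 1 else 0.0
            except (ValueError, IndexError):
                raise ParseError(
                    f"{path}: line {lineno}: bad peak line {line!r}"
                ) from None
            entries.append((mz_val, inten))
    if entries is not None:
        raise ParseError(f"{path}: unterminated BEGIN IONS block")
    if not spectra:
        raise ParseError(f"{path}: no spectra found")
    return spectra


def read_masses_tsv(path: str | Path) -> List[Tuple[str, float]]:
    """TSV of (label, neutral mass in Da)."""
    path = Path(path)
    out: List[Tuple[str, float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise ParseError(
                f"{path}: line {lineno}: expected (label, mass) columns"
            )
        try:
            out.append((parts[0], float(parts[1])))
        except ValueError:
            raise ParseError(
                f"{path}: line {lineno}: non-numeric mass {parts[1]!r}"
            ) from None
    if not out:
        raise ParseError(f"{path}: no masses found")
    return out


# ---------------------------------------------------------------------------
# observations


def read_observations(
    path: str | Path,
) -> Tuple[List[VariantObservation], Tuple[int, int], str]:
    """Load a variant-observation document.

    Schema::

        {"span": [18, 51], "wild_type_id": "WT",
         "variants": [
            {"variant_id": "WT", "cys_positions": [32, 34, 45, 50],
             "dehydro_positions": {"31": "Dhb", "49": "Dha"},
             "evidence_bonds": [18, 19, 50],
             "asserted_protected_spans": [[31, 50]],
             "completeness": "complete"}, ...]}

    Returns (observations, span, wild_type_id).
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: line {exc.lineno}: {exc.msg}") from None
    try:
        span = tuple(int(x) for x in data["span"])
        wild_type_id = data["wild_type_id"]
        observations = []
        for v in data["variants"]:
            observations.append(
                VariantObservation(
                    variant_id=v["variant_id"],
                    cys_positions=frozenset(v["cys_positions"]),
                    dehydro_positions={
                        int(k): s for k, s in v["dehydro_positions"].items()
                    },
                    evidence=CleavageEvidence(
                        variant_id=v["variant_id"],
                        cleavable_bonds=frozenset(v.get("evidence_bonds", [])),
                    ),
                    asserted_protected_spans=tuple(
                        tuple(s) for s in v.get("asserted_protected_spans", [])
                    ),
                    completeness=v.get("completeness", "partial"),
                )
            )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: missing or malformed field: {exc}") from None
    return observations, span, wild_type_id


def write_observations(
    observations: Sequence[VariantObservation],
    span: Tuple[int, int],
    wild_type_id: str,
    path: str | Path,
) -> None:
    data = {
        "span": list(span),
        "wild_type_id": wild_type_id,
        "variants": [
            {
                "variant_id": o.variant_id,
                "cys_positions": sorted(o.cys_positions),
                "dehydro_positions": {
                    str(k): v for k, v in sorted(o.dehydro_positions.items())
                },
                "evidence_bonds": sorted(o.evidence.cleavable_bonds),
                "asserted_protected_spans": [
                    list(s) for s in o.asserted_protected_spans
                ],
                "completeness": o.completeness,
            }
            for o in observations
        ],
    }
    write_json_atomic(data, path)


def write_json_atomic(data, path: str | Path) -> None:
    """Write JSON via a temp file + rename so readers never see a torn file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)
            fh.write("\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
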