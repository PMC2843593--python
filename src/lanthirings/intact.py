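"""Modification-event counting from intact-mass shifts.

Given the observed mass difference between a product and its starting
material, find the non-negative integer combination of registered
modification events (dehydrations, phosphorylations, carbamidomethyls)
that best accounts for it. This reproduces the accounting used to read
intact MALDI/ESI spectra of enzyme assays: a -72 Da shift of a peptide
with four Ser/Thr is four dehydrations; a +228 Da shift after
iodoacetamide treatment of a peptide with four Cys is four alkylations
(four free thiols); zero shift after IAA means every Cys sits in a
thioether ring.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence

from .masses import modification_delta

__all__ = [
    "ModCountCall",
    "infer_mod_counts",
    "count_free_thiols",
    "call_ladder",
    "DEFAULT_TOL_MALDI",
    "DEFAULT_TOL_ESI",
]

#: Default tolerance (Da) for intact MALDI-style masses.
DEFAULT_TOL_MALDI = 1.0
#: Default tolerance (Da) for deconvoluted ESI neutral masses.
DEFAULT_TOL_ESI = 0.05


@dataclass(frozen=True)
class ModCountCall:
    """One mass-shift assignment.

    ``counts`` maps modification name -> event count; ``residual`` is the
    observed minus explained mass (Da); ``within_tolerance`` is False when
    no combination under the site caps lands within tolerance (the best
    out-of-tolerance combination is still reported).
    """

    counts: Mapping[str, int]
    residual: float
    within_tolerance: bool

    def total_events(self) -> int:
        return sum(self.counts.values())


def infer_mod_counts(
    delta_mass: float,
    allowed: Iterable[str],
    site_caps: Mapping[str, int],
    tol: float = DEFAULT_TOL_MALDI,
    mass_type: str = "mono",
) -> ModCountCall:
    """Best integer combination of modification events for a mass shift.

    Exhaustively searches counts ``0..site_caps[name]`` for each allowed
    modification and returns the combination minimizing ``|residual|``;
    ties break toward the smallest total event count, then lexicographic
    by modification name sequence. Out-of-tolerance fits are returned with
    ``within_tolerance=False`` rather than raised, so ladders containing a
    stray peak still process.
    """
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    names = sorted(set(allowed))
    for name in names:
        if name not in site_caps:
            raise KeyError(f"no site cap given for modification {name!r}")
        if site_caps[name] < 0:
            raise ValueError(f"negative site cap for {name!r}")
    deltas = {n: modification_delta(n, mass_type) for n in names}

    best_key = None
    best: Dict[str, int] = {}
    best_residual = delta_mass
    ranges = [range(site_caps[n] + 1) for n in names]
    for combo in itertools.product(*ranges) if names else [()]:
        explained = sum(k * deltas[n] for n, k in zip(names, combo))
        residual = delta_mass - explained
        key = (abs(residual), sum(combo), combo)
        if best_key is None or key < best_key:
            best_key = key
            best = dict(zip(names, combo))
            best_residual = residual
    return ModCountCall(
        counts=best,
        residual=best_residual,
        within_tolerance=abs(best_residual) <= tol,
    )


def count_free_thiols(
    delta_after_iaa: float,
    n_cys: int,
    tol: float = DEFAULT_TOL_MALDI,
    mass_type: str = "mono",
) -> int:
    """Number of free (uncyclized) Cys thiols from the post-IAA mass shift.

    Each free thiol gains one carbamidomethyl (+57.0215 Da); Cys engaged in
    thioether rings are not alkylated. A rounded count that is negative or
    exceeds ``n_cys``, or a residual beyond ``tol``, signals inconsistent
    input and raises.
    """
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    cam = modification_delta("carbamidomethyl", mass_type)
    k = round(delta_after_iaa / cam)
    if k < 0 or k > n_cys:
        raise ValueError(
            f"shift {delta_after_iaa:+.3f} Da implies {k} alkylations, "
            f"outside 0..{n_cys}"
        )
    residual = delta_after_iaa - k * cam
    if abs(residual) > tol:
        raise ValueError(
            f"shift {delta_after_iaa:+.3f} Da is {residual:+.3f} Da away "
            f"from {k} alkylations (tol {tol} Da)"
        )
    return k


def call_ladder(
    observed_masses: Sequence[float],
    base_mass: float,
    allowed: Iterable[str],
    site_caps: Mapping[str, int],
    tol: float = DEFAULT_TOL_MALDI,
    mass_type: str = "mono",
) -> List[ModCountCall]:
    """Call one :class:`ModCountCall` per observed mass, in input order.

    Used for partial-conversion ladders, e.g. a kinase-only assay showing
    the starting material plus 2x/3x/4x phosphorylated products.
    """
    if not observed_masses:
        raise ValueError("observed_masses must be non-empty")
    return [
        infer_mod_counts(m - base_mass, allowed, site_caps, tol, mass_type)
        for m in observed_masses
    ]
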