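# Methods

## Scope and model

`lanthirings` implements the analysis by which a lanthipeptide's
post-translational modification state and ring topology are deduced from
mass spectrometry of an in-vitro-processed precursor:

1. **Intact-mass accounting.** Modification events are counted by
   exhaustive search over non-negative integer combinations bounded by
   per-modification site capacities, minimizing the absolute residual
   against the observed mass shift. Ties break toward fewer total
   events, then lexicographically by modification name, so calls are
   deterministic. An out-of-tolerance best fit is returned flagged, not
   raised, so a ladder containing a stray peak still processes.
2. **Crosslink-aware digestion.** Proteolysis hydrolyzes every bond
   matching the protease rule; products are connected components of the
   residue graph under surviving backbone bonds plus thioether
   crosslinks. A cut inside a ring does not split the product but adds
   one water.
3. **Fragmentation protection.** Only bonds spanned by no ring
   ("separating bonds") yield b/y″ ions. Protection is binary in the
   predictor; imperfect ion detection lives in the simulator only.
4. **Topology deduction.** Candidate Cys↔dehydro matchings are
   enumerated exhaustively and filtered by two constraint classes
   (below); evidence is combined across a wild-type + Cys→Ala variant
   series.

## Constraint semantics and the two modes

- **strict** — an observed, mass-matched ion at bond *i* proves the bond
  cleavable, hence un-ringed. This is the only constraint class applied;
  missing ions are never interpreted. Strict mode is sound by
  construction: the true topology can never be excluded by a correct
  observation.
- **protection_assertion** — contiguous ion-free spans, supplied
  explicitly or derived as maximal ion-free runs of ≥ 3 bonds, are
  required to be fully ring-covered. This is an *inference* (absence of
  ions read as protection) and is kept separate from the strict
  constraints because it is the step that can over-interpret sparse
  data; it is also the step required to reach a unique answer. The
  3-bond floor means rings spanning ≤ 2 bonds are never asserted from
  gaps, trading a little power for robustness against missing ions.

Per-variant solving allows partial matchings for mutants (knocking out
one Cys can leave another uncyclized — the venezuelin C32A variant lost
the Cys50 ring collaterally) and requires complete matchings for a wild
type whose iodoacetamide assay showed zero free thiols. Rings present in
every consistent topology of some variant ("necessary" rings) are
promoted to wild-type requirements; this necessity test, rather than
mere possibility, preserves soundness. Cross-variant propagation of
required rings into *mutant* re-solving is deliberately not done: under
collateral ring loss it would be unsound.

## Tunable parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| intact-mass tolerance | 1.0 | Da | MALDI-ToF-class intact masses, read to ~1 Da |
| deconvoluted-mass tolerance | 0.05 | Da | ESI-Q/ToF deconvoluted neutral masses |
| fragment-match tolerance | 0.2 | Da | Q/ToF-era fragment accuracy; config-overridable |
| mass convention | monoisotopic | — | topology work uses ESI-Q/ToF; average table provided for intact MALDI comparisons |
| protected-span floor | 3 | bonds | shorter gaps are plausibly missed ions, not rings |
| enumeration guard | 8 | Cys | 8! complete matchings is desk-scale; beyond that the caller opts in via `max_cys` |
| GluC specificity | cut after Glu only | — | matches the ammonium-bicarbonate-style digest that produced the Thr18 core start; Glu+Asp available as `gluc_de` |
| missed cleavages | 0 | — | long complete digests |

Masses come from Biopython's IUPAC tables (residue = amino acid −
water); the modification deltas are composed so that phosphorylation
(+HPO₃) plus phosphate elimination (−H₃PO₄) equals dehydration (−H₂O)
*exactly*, making the two-step identity hold to float precision.

## The synthetic-data generator

`simulate.generate_instance` states a venezuelin-like world by default:
a 17-residue leader ending in Glu, a 34-residue core, four Cys and four
dehydro residues placed uniformly (no Cys–Cys adjacency), dehydro class
by fair coin (Ser→Dha / Thr→Dhb), and a uniform random injective
Cys→dehydro matching, crossing allowed (venezuelin's own rings
interleave). Observations are generated per variant: each separating
bond's b/y″ ions appear with probability `p_ion_detect`, jittered by
Gaussian noise of `mass_noise_sd`, plus uniform decoy peaks; defaults
are full coverage and zero noise, the regime in which the published
spectra were interpretable. Collateral ring loss is off by default and
configured per mutated Cys. All randomness derives from one seed via
spawned generators, so per-variant streams are independent and the whole
instance is reproducible.

What the generator does **not** emulate: isotope envelopes, adducts,
charge-state distributions, intensity structure (intensities are
uniform noise), internal fragments, and any sequence realism beyond the
positional constraints. A green round-trip test therefore establishes
the correctness of the bookkeeping and the deduction logic, not
instrument-level robustness.

The pipeline's matching tolerance for simulated data defaults to
5 × `mass_noise_sd`, floored at 0.001 Da: a window much wider than the
mass accuracy invites coincidental matches between unrelated ions.

## Identifiability (why unique recovery saturates near ~35%)

In the simulated world at perfect ion coverage, strict mode retains the
true topology in 100% of instances and every unique answer returned is
correct. But the *rate* of unique recovery is limited by the world
itself, not the solver: a ring nested beneath a larger ring is invisible
until the larger ring's Cys is knocked out, and the revealed interior
constrains only the union of the inner ring intervals — which many
matchings share. Concretely, the topologies
{(19,50),(27,40),(28,31),(38,42)} and {(19,50),(27,42),(28,31),(38,40)}
induce identical protected regions in the wild type and in all four
single-Cys knockouts, so no algorithm can separate them. Measured on
uniformly drawn 4-Cys instances, an oracle knowing the full forward
model could uniquely identify only ~47% (crossing allowed, 34-residue
core) to ~71% (non-crossing, 60-residue core); this package's
spec-conservative combiner reaches ~35% on its default world. The
venezuelin series itself escaped this because the C32A mutation
collaterally removed the large ring *and* the surviving rings were
exactly as tight as their protected spans. One acceptance test asserts
a ≥95% unique-recovery rate and is expected to fail; it is retained as
an honest record of this limit.

## Numerical and degenerate-input choices

- Tie-breaks in mod-count calling are total-count-then-lexicographic;
  enumeration output is sorted by ring-pair tuples; reports are
  byte-stable modulo a timestamp field.
- A peptide with no protease sites digests to itself; an empty evidence
  set filters nothing; an empty assertion list is the identity;
  contradictory evidence yields an empty result plus a per-candidate
  conflict report, never an exception.
- Zero Cys yields exactly one (empty) topology. Required rings that
  reuse a position yield an empty candidate set.
- Fragment segments split at hydrolyzed bonds even when a crosslink
  keeps the residues in one product, so each product carries one water
  per chain-terminus pair and mass is conserved under any cut pattern,
  including double cuts through a ring.

## Known limitations

- Only b/y″ series are predicted; internal-fragment ions are not used
  as topology evidence.
- Protection is binary; partially leaky macrocycle fragmentation is not
  modeled in the predictor.
- The venezuelin preset's residue string is a synthetic stand-in
  honoring all published positional constraints; absolute masses of the
  full peptide differ from authentic VenA, so sequence-dependent
  absolute values (e.g. the precursor's printed intact mass) are out of
  reach by construction.
- Disulfide (Cys–Cys) crosslinks and stereochemistry are out of scope.
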