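# lanthirings

Mass accounting and ring-topology inference for lanthipeptides
(lanthionine-containing ribosomal peptides), built around the analysis
used to characterize venezuelin, the product of the VenA precursor
processed by the three-domain synthetase VenL from *Streptomyces
venezuelae*.

The package is for protein-chemistry and natural-product researchers who
have intact-mass and tandem-MS data for an enzymatically modified
precursor peptide and need to answer, reproducibly:

1. **How many modification events happened?** Dehydrations of Ser/Thr
   (−18.011 Da each), phosphorylations (+79.966 Da), and free-thiol
   alkylations by iodoacetamide (+57.021 Da per uncyclized Cys) are
   called from intact-mass shifts by exhaustive integer accounting.
2. **Which Cys is crosslinked to which dehydro residue?** Thioether
   rings protect the backbone bonds they span from collision-induced
   dissociation, so the pattern of observed b/y″ ions across a wild-type
   + Cys→Ala variant series constrains the ring topology. The solver
   enumerates candidate matchings and intersects the evidence.

## The model

A modified core peptide spanning residues *f..l* carries Cys at
positions *C* and dehydro residues (Dha from Ser, Dhb from Thr) at
positions *D*. The unknown is a partial injective matching
*T ⊆ C × D*; a Cys–Dha pair is a lanthionine (Lan), Cys–Dhb a
methyllanthionine (MeLan). A ring (j,k) spans backbone bonds
min(j,k) … max(j,k)−1. Bond *i* is **separating** iff no ring spans it;
only separating bonds yield b/y″ fragment ions:

- observed ion at bond *i*  ⇒  no ring of *T* spans *i* (strict
  constraint, always applied);
- an extended ion-free run, asserted as a protected span (a,e)  ⇒  every
  bond a … e−1 is spanned by some ring (protection-assertion mode, the
  inferential step needed for a unique answer).

Each variant is solved independently (a mutated Cys may leave other
partners uncyclized, so mutants allow partial matchings); rings present
in *every* consistent topology of a variant are promoted to requirements
for the wild type, whose surviving candidates are the result.

Mass bookkeeping: peptide neutral mass = Σ residue masses + H₂O +
Σ modification deltas; ring formation is a Michael addition and adds
0 Da; phosphorylation followed by phosphate elimination equals direct
dehydration exactly (the kinase + lyase route of the LanL enzymes).

## Worked example

```python
from lanthirings import presets

model = presets.venezuelin_model()          # WT + C32A/C34A/C45A/C50A series
results = model.fit(mode="protection_assertion")
print(results.summary())
```

prints

```
Ring topology inference
=======================================================
mode:                 protection_assertion
wild type:            WT
span:                 18..51
variants:             5
variant-evidenced:    [(34, 39), (45, 49)]
surviving topologies: 1
  C32A         consistent topologies: 1
  C34A         consistent topologies: 19
  C45A         consistent topologies: 16
  C50A         consistent topologies: 4
  WT           consistent topologies: 13
final topology (cys, dehydro):
  Cys32 -- 43
  Cys34 -- 39
  Cys45 -- 49
  Cys50 -- 31
```

Reading: the C32A variant's spectrum pins the MeLan Cys34–Dhb39 and Lan
Cys45–Dha49 rings (its only consistent topology), and the wild-type
protected region Dhb31..Cys50 then forces Cys32–Dhb43 and Cys50–Dhb31 —
four overlapping rings, with one 20-residue macrocycle. In strict mode
(positive cleavage constraints only) 24 candidates survive; the
protection assertions are what make the answer unique.

The same run is available from the shell:

```sh
lanthirings run --preset venezuelin --report report.json
lanthirings simulate --seed 3 --preset random --outdir sim/
lanthirings solve-topology sim_observations.json --mode assert
```

Coordinates everywhere are 1-based precursor positions; a backbone bond
is labeled by its N-terminal residue (bond 50 joins residues 50 and 51).

The `venezuelin` preset uses a synthetic stand-in sequence that
satisfies every published positional constraint (core Thr18–Ala51, Cys
32/34/45/50, dehydro 31/39/43/49, GluC site after Glu17, the PFA/GA/AA
leader-cleavage motifs); absolute masses of the full peptide are
therefore not those of authentic VenA, while all positional results are.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: the intact-mass accounting calls (4×
dehydration, free-thiol counting, the phosphorylation ladder), the full
venezuelin topology deduction, and a 100-instance seeded simulation
study (strict-mode truth containment and protection-assertion unique
recovery), then writes the results JSON to `--out`.
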