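# polydom

Rigid-body assembly of multi-domain protein structures from individual
domain models and inter-residue distance restraints, with optional
template guidance and cryo-EM density fitting.

## The problem

Structure prediction is most reliable at the level of single domains.
Large proteins, however, are chains of two or more domains, and the
*relative placement* of those domains is what determines interfaces,
substrate channels and overall shape. `polydom` takes:

- two or more domain models (PDB, Cα required, backbone optional),
- predicted or measured inter-domain restraints (Gaussian distances,
  binned distograms, contacts, optional inter-residue orientations),
- optionally a template library (full-chain PDB structures) and/or a
  cryo-EM density map (CCP4/MRC),

and searches for the rigid-body pose of every domain simultaneously, by
multi-start L-BFGS minimization of a hybrid energy. It emits ranked
full-length models with reconstructed linkers and a confidence estimate
(eTM-score / eRMSD) that does not require the native structure.

## The model

Each domain is a rigid body with 6 pose parameters (intrinsic Z-Y-X Euler
rotation about the domain centroid plus translation). The energy of a
candidate assembly is a weighted sum of:

| term | content |
|---|---|
| distance | capped harmonic wells on Gaussian restraints; cubic-spline −log p on distograms |
| contact | harmonic wells pulling predicted contacts below 18 Å |
| orientation | circular wells on inter-residue ω/θ/φ angles (needs backbone) |
| template | distance profiles from the best-ranked templates |
| clash | soft inter-domain Cα overlap penalty below 3.8 Å |
| generic | weak reward for interface pairs in the 4.5–8 Å band |
| connectivity | penalty when a linker would have to stretch beyond 3.8 Å per residue |
| density | 1 − real-space correlation against the map (when a map is given) |

Templates are ranked by the harmonic mean of per-domain TM-scores
(TM-score_h), evaluated both locally (overlap allowed) and globally
(sequential N→C and C→N threading, overlap forbidden). Model accuracy is
scored with the rTM-score: a TM-score under a single fixed superposition,
so inter-domain orientation errors are fully penalized. Confidence
combines the best template score, restraint satisfaction, multi-start
convergence and per-domain confidence into an eTM-score; eRMSD is derived
from it by inverting the TM-score kernel (heuristic, flagged as such).

A fixtures module generates seeded synthetic multi-domain proteins
(helix bundles and compact self-avoiding walks, continuous or
discontinuous topology), native-derived restraints and simulated maps, so
the whole pipeline runs without any external data.

## Worked example

Generate a two-domain toy protein, derive exact restraints from its
native structure, then reassemble it from the isolated domains:

```sh
$ polydom gen-fixture --n-domains 2 --residues 60 --seed 7 --out fixture
wrote native.pdb and 2 domain files to fixture

$ polydom gen-restraints --native fixture/native.pdb --subsample 0.25 --seed 7 \
      --out restraints.txt
wrote 900 distance restraints to restraints.txt

$ polydom assemble --domain fixture/domain1.pdb --domain fixture/domain2.pdb \
      --restraints restraints.txt --seed 7 --n-starts 4 --out out
best model: out/model1.pdb  eTM-score 0.690

$ cat out/report.txt
polydom 0.1.0  seed 7

model1.pdb  energy     -0.033  start start-0 (random)

eTM-score (model1): 0.690
eRMSD (model1, heuristic): 2.71 A
components: template=0.000  restraint=1.000  convergence=1.000  domain=0.800

$ polydom score --model out/model1.pdb --reference fixture/native.pdb
TM-score   1.0000
rTM-score  1.0000
TM-score_h 1.0000  (over 2 segment(s))
```

The assembled model reproduces the native arrangement exactly
(rTM-score 1.0). The eTM-score is deliberately conservative here: no
template was used, so the template component contributes zero.

The same pipeline is available as a library:

```python
from polydom.assemble import AssemblyConfig, assemble
from polydom.core import infer_layout, read_domain_pdb
from polydom.energy import AssemblyProblem
from polydom.restraints import read_restraints

domains = [read_domain_pdb(p, domain_id=k)
           for k, p in enumerate(["domain1.pdb", "domain2.pdb"])]
problem = AssemblyProblem(domains, infer_layout(domains),
                          read_restraints("restraints.txt"))
result = assemble(problem, AssemblyConfig(seed=7, n_starts=4))
print(result.best.energy_breakdown)
```

For map-guided assembly pass `--map density.map --resolution 8` to
`assemble`, or fit a single domain with `polydom fitmap`.

## Reproduction

All benchmarks are seeded and self-contained. `tests/test_acceptance.py`
holds one test per acceptance criterion (pose recovery rates, optimizer-
vs-grid oracle, metric oracles, template ranking, restraint calculus,
density pipeline, confidence sanity). `scripts/acceptance.py --seed 0
--out results.json` recomputes the headline quantities and writes them as
JSON; the run takes a few minutes on one CPU and needs no network access.

## Limitations

- Domains are strictly rigid; no flexible refinement of intra-domain
  geometry or linker torsions (linkers are rebuilt geometrically).
- Energies use Cα-only terms unless backbone atoms are present.
- The synthetic fixture folds are idealized (helix bundles, compact
  walks) and are a test harness, not a protein generator.
- eTM-score is a fixed-weight linear combination, not a trained
  predictor; treat it as a sanity signal rather than calibrated accuracy.

See `docs/methods.md` for assumptions, parameter tables and numerical
choices.
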