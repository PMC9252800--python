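# Methods notes

Assumptions, parameters and numerical choices behind `polydom`. Reader is
assumed to know the README; this documents the decisions, not the API.

## Coordinate model and poses

- A domain is a set of residues (one or more sequence segments) with Cα
  coordinates; backbone N/C atoms are optional and only enable the
  orientation term.
- A pose is 6 parameters: intrinsic Z-Y-X Euler angles and a translation,
  applied about the domain's *input* centroid. With this parameterization
  the moved centroid is `centroid + t` independent of the rotation, which
  decouples the rotational and translational blocks of the optimization
  and lets density-guided stages resample orientation without moving a
  domain off its density peak.
- Assemblies are indexed by residue id in ascending order everywhere
  (restraints, energies, metrics). Domain insertion (discontinuous
  topology) is therefore handled uniformly: the id-sorted order is the
  chain order.

## Energy terms and parameters

| constant | value | rationale |
|---|---|---|
| harmonic cap | 16 (i.e. 4 sd) | restraint wells go flat beyond 4 sd so a distant outlier cannot dominate; consequence: the landscape is locally informative only, hence multi-start |
| clash radius | 3.8 Å | Cα–Cα pairs from different domains closer than one bond step are penalized quadratically |
| contact cutoff | 18 Å | contact restraints pull pairs below the same cutoff used to derive contact probabilities from distograms |
| interface window | 4.5–8 Å | generic interface reward counts Cα pairs in this band, capped at ceil(3·√min(n_a, n_b)) pairs so it cannot outweigh restraints |
| linker span | 3.8 Å/residue | connectivity penalizes boundary gaps a linker of `gap+1` steps cannot bridge |
| FD step | 1e-4 | central finite differences; the energy is piecewise smooth and this step passes 1e-3 directional-derivative self-consistency |

Default weights: distance 1.0, contact 0.5, orientation 0.5, template 0.5,
clash 2.0, generic 0.1, connectivity 2.0, density 1.0. Clash and
connectivity are weighted above the data terms because they encode hard
physical feasibility; generic contact is an order of magnitude weaker
because it is a prior, not data.

Distograms are converted to energies as a cubic spline through
−log(p + 1e-4) at bin centers, clamped flat outside the binned range and
baselined at the last bin so "no information" scores zero.

## Metrics

- TM-score uses the standard d0(L) = 1.24·(L−15)^⅓ − 1.8 with a 0.5 Å
  floor for L ≤ 15 (the floor value itself applies whenever the formula
  drops below 0.5). The superposition search is fragment-seeded (all
  contiguous fragments of several lengths) followed by iterative
  kernel-weighted refitting; it matches a 60-start Nelder-Mead
  maximization of the kernel to 1e-3 on 20-residue toys.
- rTM-score fixes a single superposition (Kabsch on the best-scoring
  single domain) and sums the kernel over all residues, so inter-domain
  orientation errors cannot be absorbed by refitting. rTM ≤ TM by
  construction.
- TM-score_h is the harmonic mean of per-domain TM-scores with a 1e-3
  score floor so a failed per-domain alignment yields a defined (tiny)
  value instead of a division by zero.
- Structural alignment is iterative dynamic programming (gap penalty
  −0.6 in kernel units) over superpositions seeded from fragments.

## Template ranking

Stage 1 scores every library entry locally (each domain aligned
independently, overlap allowed) and keeps the top 500. Stage 2 re-scores
those globally: domains are threaded sequentially (N→C and C→N, better
direction kept) with already-claimed template residues masked, so two
domains cannot explain the same template region. A domain with
TM-score_d < 0.5 counts as uncovered; if the best global hit leaves a
domain uncovered, the template set is re-ranked for the two broken parts
independently and merged. Ties break on template id for determinism.

## Assembly

Multi-start L-BFGS over the concatenated 6·N_dom pose vector. Starts come
from top template hits when available, otherwise seeded "random tandem"
arrangements (first start unperturbed). Because the capped wells make
line searches occasionally end uphill, the *best iterate visited* is
kept, guaranteeing the result is never worse than the start. Final models
are ranked by energy and de-duplicated at pairwise rTM > 0.98.

## Density pipeline

- Simulated maps place an isotropic Gaussian per Cα with
  σ = 0.425·resolution (FWHM = resolution), voxel 2 Å, 10 Å padding.
- `density_correlation` (whole-model scoring) is a Pearson correlation
  over voxels where either map exceeds 1e-6 of its max.
- Fitting one domain into a map of the whole uses `local_correlation`,
  masked on the *model's* support only: the global mask rewards smearing
  a single domain between blobs (measured: smeared placement 0.738 vs
  true placement 0.698 under the global mask on a two-blob map), the
  model-support mask does not.
- Density-guided assembly: (1) per-domain multi-start fits against map
  peaks, (2) combination of per-domain fits (capped at 16 combos, overlap
  filtered at 3.8 Å, topped up with orientation-resampled copies), an
  uncapped-restraint pre-alignment so flipped domains are not stranded on
  the flat part of the capped wells, then full hybrid L-BFGS, (3) a final
  global rigid docking of each model into the map using candidates
  derived from the per-domain fits. Models are ranked by (density
  correlation, energy).

## Confidence (eTM-score / eRMSD)

eTM = 0.25·best TM-score_h + 0.25·restraint satisfaction +
0.20·multi-start convergence + 0.30·mean per-domain confidence.
Restraint satisfaction counts Gaussians within 2 sd and distogram
distances inside the smallest 90%-mass bin set; convergence is the mean
pairwise rTM of the top (≤5) final models. Weights favor the domain
quality (assembly cannot fix bad domains) and split the remainder between
evidence (template, restraints) and reproducibility. eRMSD inverts the
TM-score kernel at eTM with d0(L); it is a heuristic and is labelled as
such in reports. eTM = 1 forces eRMSD = 0 exactly.

## Synthetic fixtures: realism and limits

Generators produce Cα traces with 3.8 ± 0.2 Å consecutive steps and a
3.5 Å minimum separation for non-consecutive pairs. Folds: `helix-bundle`
(ideal helices, 1.5 Å rise, 100° twist, packed antiparallel) and
`compact-walk` (biased self-avoiding walk). Multi-domain fixtures
guarantee ≥ 10 interface Cα pairs below 8 Å and ≥ 4 Å inter-domain
clearance; topologies: tandem (continuous) and insertion
(discontinuous). These are test instruments: they have no side chains,
no secondary-structure diversity beyond the two folds, and mirror
symmetry is only weakly broken for helix bundles (which is why
mirror-discrimination tests use compact walks).

## Numerical choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds < 2^31; every public entry point that randomizes takes a seed.
- Kabsch uses `scipy.spatial.transform.Rotation.align_vectors`
  (≈1e-7 superposition accuracy; tests tolerate 1e-6).
- PDB I/O via gemmi; coordinates are written at 3 decimals, so round
  trips are exact to 2e-3 Å. CCP4 maps round-trip via gemmi with the
  origin carried in header words 50–52.
- Gradients are central finite differences; the evaluator caches the
  per-domain simulated maps so density gradients only re-simulate the
  perturbed domain.

## Open design decisions

- The eTM weighting is a documented stand-in, not fitted; a calibrated
  predictor would need a benchmark with known natives.
- Orientation restraints are implemented but unexercised by the synthetic
  restraint generator (which emits distances only); they are covered by
  unit oracles.
- The density-guided combo cap (16) and the per-domain fit count (top 2)
  trade breadth for runtime; larger maps or >4 domains may need both
  raised.
- Linker rebuilding is straight-line interpolation; a torsion-space
  closure would be more realistic but is out of scope for rigid-body
  assembly.
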