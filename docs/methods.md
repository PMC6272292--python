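# Methods

## Problem and models

`vinarf` predicts the binding strength of a protein–ligand co-crystal
complex, expressed as pK = −log₁₀ of the molar dissociation (Kd) or
inhibition (Ki) constant, from heavy-atom geometry alone.  Four scoring
functions are implemented, ordered by how much they learn from data:

1. **Vina composite** — the fixed-weight empirical score
   e = Σₖ wₖ·termₖ / (1 + w_rot·N_rot) in kcal/mol, reported as −e/1.3637
   (RT·ln 10 at ≈298 K) so predictions land on the pK scale.  No training.
2. **MLR::Vina** — ordinary least squares recalibration of the same six
   features on a training set.
3. **RF::Vina** — random-forest regression on the six Vina features.
4. **RF::VinaElem** — random-forest regression on 42 features: the six Vina
   features followed by 36 intermolecular element-pair occurrence counts.

### Descriptors

All descriptors are computed on heavy atoms only; hydrogens are stripped at
parse time (polar hydrogens are still used, before being discarded, to mark
N/O donors in PDBQT input).  Waters and, on the protein side, HETATM
cofactors are excluded so the atom lists describe the binary
protein–ligand interface.

The five Vina interaction terms are functions of the *surface distance*
d = r − Rᵢ − Rⱼ (Euclidean distance minus both van der Waals radii), summed
over all intermolecular pairs with d ≤ 8 Å:

| term | form | eligibility |
|------|------|-------------|
| gauss1 | exp(−(d/0.5)²) | all pairs |
| gauss2 | exp(−((d−3)/2)²) | all pairs |
| repulsion | d² if d < 0 else 0 | all pairs |
| hydrophobic | linear ramp 1→0 over d ∈ [0.5, 1.5] | hydrophobic C – hydrophobic C |
| hbond | linear ramp 1→0 over d ∈ [−0.7, 0] | donor–acceptor |

The sixth feature is N_rot, the ligand's active-torsion count taken from the
PDBQT torsion tree (REMARK count, falling back to BRANCH records).  The term
constants, the default weights (gauss1 −0.035579, gauss2 −0.005156,
repulsion 0.840245, hydrophobic −0.035069, hbond −0.587439, N_rot 0.05846),
the 8 Å cutoff, the vdW radius table (C 1.9, N 1.8, O 1.7, S 2.0, P 2.1,
F 1.5, Cl 1.8, Br 2.0, I 2.2, metals 1.2 Å) and the 1.3637 kcal/mol-per-pK
divisor are external conventions collected in `vinarf.config` and
overridable per call.

The 36 count features are the number of (protein atom, ligand atom) pairs
within 12 Å plain Euclidean distance, for protein elements {C,N,O,S} ×
ligand elements {C,N,O,F,P,S,Cl,Br,I}; pairs exactly at the cutoff are
included, other elements are ignored.  The feature order is frozen
(`gauss1, gauss2, repulsion, hydrophobic, hbond, nrot`, then `C.C … S.I`
protein-element-major) so serialized models stay portable.

Atom typing without connectivity: a carbon is hydrophobic when no N/O/S
heavy atom lies within 1.9 Å (a documented approximation of "bonded only to
C or H"); N/O are acceptors (or per the PDBQT NA/OA types when present);
donors are N/O with a polar hydrogen written within 1.3 Å.

### Training protocol

Random forests use bootstrap CART regression trees (scikit-learn's
`RandomForestRegressor`) with the library's regression defaults for tree
controls.  For each random seed the `mtry` parameter (features tried per
split) is chosen by the lowest RMSE of the forest's out-of-bag predictions
over a candidate grid, ties going to the smallest value (smallest variance
inflation, deterministic).  The package default is 500 trees with the full
grid (1..6 or 1..42) and ten seeds fixed to 1..10; a model comparison is
read off the componentwise median of the ten instances' test metrics.
Samples that never fall out of bag (only possible at pathologically small n)
are excluded from the OOB RMSE with a warning.

### Metrics

For predictions {p(n)} against measurements {y(n)} on N complexes:
RMSE = √(mean (y−p)²); (a, b) is the least-squares fit of y on p and
SD = √(Σ (y −(a+b·p))² / (N−1)), i.e. the residual spread about the
calibration line, insensitive to affine miscalibration; R_p is the Pearson
correlation and R_s the Pearson correlation of average-rank vectors
(= Spearman with tied-rank averaging).  The N−1 denominator is the
benchmark convention; `sd_ddof=0` switches to N.  Zero-variance inputs make
the correlations undefined; they are reported as missing, never as 0.

## Curation model

Index files follow the whitespace-column dialect (code, resolution or `NMR`,
year, p-affinity, affinity string like `Ki=400mM`; `#` comments, `//`
tails).  A measurement is *exact* iff its qualifier is `=`; `~ < > ≤ ≥`
mark approximate values.  The four general-set filters remove, in a fixed
order (so per-reason accounting is well defined): non-protein–ligand
complexes, conversion failures, approximate measurements, NMR structures.

*Refined quality* means: resolution ≤ 2.5 Å (database practice includes
2.50 Å; a strict `<` is available), crystal structure, exact Kd or Ki, and
no structural defect flag (covalent binding, uncommon element, ≥10-residue
peptide, ≥4-mer nucleotide, incomplete structure, multiple ligands).  Flags
that cannot be derived from an index line (covalency, completeness, …) are
carried as annotations — from a sidecar CSV for real data, directly from
the generator for synthetic data — because upstream databases curate them
from information the index does not contain.  Training tiers are cut by
resolution ceiling and/or Kd/Ki-only; blind test sets are code-set
differences between time-stamped releases, guaranteed disjoint from every
training set (asserted before any training).

## Synthetic data

`simdata` generates what the pipeline consumes, with no attempt at chemical
realism: the point is exercising descriptors, curation and learners at
scale with known ground truth.

* **Complexes** — ligand atoms uniform in a 4 Å pocket sphere, protein atoms
  in a 5–12 Å shell around it, rejection-sampled to ≥1.5 Å separation, so
  pair distances populate both the 8 Å surface-distance and 12 Å count
  cutoffs.  Default sizes 48 protein + 16 ligand atoms.  Element draws:
  protein {C .60, N .16, O .22, S .02}; ligand {C .70, N .12, O .13, S .02,
  F .01, P .005, Cl .01, Br .0025, I .0025} — arbitrary, fixed, chosen to
  populate all 36 count features at moderate n.  N/O are acceptors and
  donors with probability 0.5; hydrophobic carbons follow the same
  geometric rule as parsing.  N_rot ~ uniform{0..10}.
* **Labels** — linear: y = β₀ + β·x on raw features (so OLS recovery is
  exact at zero noise); nonlinear: β₀ plus pairwise products and thresholded
  terms of the standardised six Vina features — structure a linear model
  cannot represent but a forest can — plus Normal(0, σ²) noise, σ = 0.5 pK
  by default (a plausible inter-assay spread).
* **Degradation** — coordinate jitter (i.i.d. Normal per coordinate)
  emulates worse resolution via the mapping jitter s.d. = 0.1·r Å;
  label degradation draws one systematic bias per record from
  Normal(0, 0.5²) and adds extra noise of s.d. 0.5 pK, emulating (not
  estimating) IC50-vs-Kd heterogeneity.  Degraded records are annotated
  with the implied resolution and IC50 kind so curation tiers them
  correctly.
* **Index fixtures** — exact per-defect-class record counts, disjoint
  classes, deterministic shuffle, with the class→codes bookkeeping returned
  as the accounting oracle.

### The trend experiments

`vinarf.experiments` packages three study-condition presets:

* *RF vs MLR* — 2000 training / 400 test complexes, nonlinear labels,
  10 independent replicates; the forest's median RMSE should beat OLS.
* *Data volume* — nested training prefixes of 500/1000/2000/4000 from one
  pool; the forest's learning curve keeps falling while OLS flattens.
* *Low-quality benefit* — 800 clean + 2400 degraded training complexes.
  The degraded pool is a defect **mixture**: a structural fraction (28%)
  gets 0.30 Å jitter and a larger fraction (61%) gets IC50-style label
  degradation, some records both.  These fractions mirror the composition
  of a general-set complement of a refined set, where most low-quality
  complexes owe their status to the measurement kind rather than to poor
  resolution; degrading every record's coordinates would instead emulate a
  uniformly low-resolution database, which is not what a general set looks
  like.  Under the mixture, adding degraded data lowers the forest's test
  RMSE while the linear control shows no comparable gain.

The trend presets use 100-tree forests with mtry grid {1,2,3} on the
six-feature scheme (`experiments.TREND_RF_CONFIG`) rather than the 500-tree
full-grid default: the questions under study concern training data, not
ensemble size, and the lighter forests keep each preset at desk scale.
Replicate seeds are spawned from a single base seed via `SeedSequence`, so
every experiment is a pure function of that seed.

### What passing these experiments does and does not show

The generator draws training and test complexes i.i.d. from one
distribution, with noise levels chosen, not estimated.  Passing therefore
shows the machinery is correct and the qualitative data-volume/quality
trends are real *for data with this structure*; it does not certify
performance on real crystal structures, where protein families induce
train–test correlation, descriptors are far noisier proxies, and the
applicability-domain effect (low-quality data covering regions high-quality
data misses) adds a benefit mechanism the i.i.d. generator cannot produce.
Reproducing published benchmark numbers requires the licensed database
download; with those files in hand, the same `curation` → `featurize` →
`benchmark` path applies unchanged.

## Numerical choices and degenerate inputs

* OLS uses `numpy.linalg.lstsq`; rank-deficient designs fall back to the
  minimum-norm solution with a logged warning; n ≤ p is an error.
* Constant-target forests predict the constant; constant p or y makes the
  correlations missing (with warning), and the calibration slope b is set
  to 0 with a = mean(y) when p has zero variance.
* Feature CSVs are written with `%.17g` so re-reading is bit-exact;
  benchmark results CSVs pin `%.12g` and column order so identical runs are
  byte-identical.
* Rejection sampling raises after a retry cap with advice to enlarge the
  box; featurization failures inside `featurize_set` are collected in a
  rejects list, never silently dropped.
* PDB codes are normalised to lowercase before any set algebra.

## Known limitations

* No protonation, bond-order perception, structure repair, mmCIF, ΔSAS, or
  pose generation; scoring is on given crystal poses only.
* Connectivity-free hydrophobic/donor typing is approximate for plain PDB
  input without polar hydrogens.
* The MWT baseline omits hydrogens (heavy-atom masses only), which shifts
  its absolute value but not the ranking a size baseline exists to provide.
* Defect flags beyond resolution/NMR/measurement kind must be supplied as
  annotations; the package does not detect covalency or completeness from
  3-D structures.
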