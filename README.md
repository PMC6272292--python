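# vinarf

Machine-learning scoring functions for protein–ligand binding affinity
prediction, with the data-curation and benchmarking machinery needed to ask
a pointed question: **does low-quality training data hurt a scoring
function, or help it?**

`vinarf` is for computational chemists and method developers who rescore
crystal poses: it featurizes protein–ligand complexes, trains classical and
random-forest scoring functions, evaluates them with the standard
scoring-power metrics, and curates PDBbind-style index files into
quality-tiered, time-stamped blind benchmarks.  A synthetic-data module
generates complexes, labels and index fixtures with known ground truth, so
every stage — and the qualitative data-volume and data-quality trends — is
testable without any database download.

## The models

Given a complex's heavy atoms, two descriptor sets are computed:

* **vina6** — the five Vina interaction terms (two gaussians of the surface
  distance d = r − Rᵢ − Rⱼ, a steric repulsion d² for d < 0, and
  hydrophobic and hydrogen-bond linear ramps over eligible pairs), summed
  over intermolecular pairs with d ≤ 8 Å, plus the ligand's rotatable-bond
  count N_rot;
* **vinaelem42** — vina6 followed by 36 occurrence counts of protein
  {C,N,O,S} × ligand {C,N,O,F,P,S,Cl,Br,I} element pairs within 12 Å.

Four scoring functions operate on these features:

| model | features | fit |
|-------|----------|-----|
| Vina composite | vina6 | none — fixed published weights, −e/1.3637 → pK scale |
| MLR::Vina | vina6 | ordinary least squares |
| RF::Vina | vina6 | random forest, 500 trees |
| RF::VinaElem | vinaelem42 | random forest, 500 trees |

Each random forest selects its `mtry` (features tried per split) by the
lowest out-of-bag RMSE over a grid, per seed; ten seeded instances are
summarised by their componentwise median test metrics (RMSE, SD about the
calibration line, Pearson R_p, Spearman R_s).

## Worked example

```sh
python examples/train_and_evaluate.py
```

generates 600 synthetic complexes whose affinity surface is nonlinear in
the six Vina features (σ = 0.5 pK label noise), trains an OLS recalibration
and a 3-seed forest ensemble on 500, and evaluates both on the held-out
100:

```
model        RMSE     SD     Rp     Rs
MLR         1.276  1.251  0.687  0.654
RF median   0.936  0.917  0.846  0.825
selected mtry per seed: {1: 3, 2: 3, 3: 3}
```

The forest's lower RMSE/SD and higher correlations come from the feature
interactions OLS cannot represent; `selected_mtry` shows what the
out-of-bag curve chose for each seed.  Other examples: parsing and
featurizing a complex (`featurize_complex.py`), index curation into quality
tiers (`curate_index.py`), and the low-quality-data trend at small scale
(`low_quality_benefit.py`).

A thin CLI mirrors the shell-shaped steps:

```sh
vinarf featurize --protein rec.pdbqt --ligand lig.pdbqt --scheme vinaelem42 --out feats.csv
vinarf train --scheme vinaelem42 --train feats.csv --labels y.csv --out model/
vinarf predict --model model/ --in feats.csv --out preds.csv
vinarf evaluate --pred preds.csv --obs y.csv
vinarf curate --index INDEX.txt --tier "kdki,res<=2.5" --out codes.txt
vinarf simulate --preset low-quality --seed 7 --out runs/
```

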