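# deamipred

Structure-based prediction of asparagine (Asn) deamidation liability in
proteins.

Deamidation converts Asn to Asp/IsoAsp through a succinimide
intermediate and is a major chemical-stability concern for protein
therapeutics. The usual sequence rule — flag every NG motif — over-predicts
badly. `deamipred` instead extracts a 13-descriptor feature set from
X-ray crystal structures and trains classical machine-learning
classifiers to rank Asn sites by deamidation probability.

## What it does

- **Structure handling** — strict PDB parsing (fixed wwPDB columns,
  line-numbered errors), hydrogen/water/hetero filtering,
  highest-occupancy altloc resolution, most-complete-chain selection,
  and enumeration of candidate Asn sites with their flanking residues.
- **Descriptors** (per Asn site, fixed column order):
  penta-peptide deamidation half-life (user-supplied table with
  substitution rules for Pro/Gln/Asn neighbors), backbone φ/ψ and
  side-chain χ1/χ2 torsions, a 4-way secondary-structure code
  (helix=1, sheet=2, coil=3, turn=4), z-score-normalized B-factors at
  the C/Cα/Cβ/Cγ atoms, percent (side-chain) solvent accessibility by
  Shrake–Rupley sphere sampling, and the nucleophilic-attack C–N
  distance.
- **Models** — six families (RBF-SVM, random forest, Gaussian naive
  Bayes, KNN, single-hidden-layer ANN, PLS-DA) behind one protocol:
  center/scale preprocessing fitted inside each fold, stratified
  10-fold cross-validation with grid search, probability outputs, and
  recursive feature elimination for descriptor ranking.
- **Evaluation** — confusion-matrix metrics with unbalanced-data
  conventions (precision reported as `-` when no positives are
  predicted; MCC 0 on degenerate denominators), threshold-sweep
  ROC/AUC, and the NG-motif sequence baseline for comparison.
- **Fixtures** — a deterministic synthetic-data module: ideal-geometry
  peptide builder (prescribed torsions and B-factors, optional burial
  cage) and labeled feature tables with planted signal emulating the
  study-scale class imbalance (194/28 train, 81/5 test).

## Half-life table

Half-life values are experimental measurements not shipped with the
package. Generate a template and fill in the `half_life_days` column
(days, one row per Xxx/Yyy flanking-residue pair):

```bash
deamipred halflife-template --out halflife.csv
```

## CLI workflow

```bash
# 13-descriptor feature table from structures
deamipred extract protein.pdb --half-life-table halflife.csv --out features.csv

# synthetic benchmark tables (for demos/tests; no real data required)
deamipred make-benchmark --seed 20170721 --out bench/

# train with 10-fold CV + grid search, then rank a test set
deamipred train --features bench/train.csv --algorithm RANDOM_FOREST --out model/
deamipred predict --model model/model.joblib --features bench/test.csv --out predictions.csv

# metrics, ROC and the NG-motif baseline side by side
deamipred evaluate --predictions predictions.csv --baseline ng-motif --out eval/

# recursive feature elimination ranking
deamipred rank-features --features bench/train.csv --out ranking.csv
```

Exit codes: 0 success, 2 usage/config error, 3 data error. Each
train/evaluate run writes a `provenance.json` (version, seed, config
hash) next to its outputs.

## Layout

```
src/deamipred/
  structure.py    PDB model, chain selection, Asn site enumeration
  halflife.py     penta-peptide half-life table + substitution rules
  geometry.py     signed torsion angles
  sasa.py         Shrake–Rupley solvent accessibility
  secondary.py    reduced Kabsch–Sander secondary structure
  descriptors.py  the 13-descriptor feature vector
  models.py       classifier families, CV/grid search, RFE
  evaluation.py   confusion metrics, ROC/AUC, NG-motif baseline
  fixtures.py     synthetic peptides and feature tables
  cli.py          command-line interface
```
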