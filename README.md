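# sevc

Soft ensemble vote classifier (sEVC) for predicting the solubility of
chimeric protein constructs from sequence, together with the two
hill-climbing optimizers that improve it and a continuous-vote regression
extension for ammonium-sulfate precipitation concentrations.

The model works entirely from amino-acid composition: for each
hydrophobicity scale (a 20-value residue table), the feature of a sequence
is the sum of per-residue scale values. One one-level decision tree
("stump") is trained per scale by exhaustive Gini-impurity threshold
search; each stump votes with its leaf's majority-class probability,
signed by the class, and the ensemble prediction is the mean vote of the
`n` most important stumps (importance = training-set Matthews correlation
coefficient). Model sizes 1..k are screened by Monte Carlo
cross-validation (repeated random 1:1 splits of the training set).

Two optimizers sit on top:

- **Insertion-strategy optimizer** — hill-climbs a per-strategy additive
  offset on the continuous vote, driven by the strategy with the largest
  accumulated |FN − FP| imbalance in MC-CV validation predictions
  (step 0.01, acceptance margin 0.05, patience 50).
- **Scale optimizer / synthesizer** — hill-climbs a single 20-value scale
  (from a random initial for synthesis, or an existing scale for
  optimization), stepping it by a standardized modifier derived from the
  FN/FP group feature-value and composition gaps (rate 1% of unit variance
  for synthesis, 5% for optimization; acceptance margin 0.2, patience 50).

Because the experimental dataset this method was developed on is
confidential, the package ships a first-class synthetic generator
(`sevc.simulate`) that reproduces the experimental design — a backbone protein,
71 insert peptides × 8 parameterized insertion strategies = 568
constructs, labels driven by a hidden ground-truth scale plus per-strategy
offsets and noise, and a stratified 384/184 train/test split — so every
algorithm is testable for parameter recovery against known ground truth.

## Command line

```sh
sevc simulate --seed 1 --out run/            # synthetic grid + split
sevc crossval --runs 25 --seed 1 --scales scales.csv --data run/constructs.csv
sevc optimize-strategy --runs-per-iter 25 --step 0.01 --margin 0.05 \
     --patience 50 --seed 1 --scales scales.csv --data train.csv
sevc synth-scales --subsets 8 --mode random --rate 0.01 --seed 1 --data train.csv
sevc optimize-scales --rate 0.05 --seed 1 --scales scales.csv --data train.csv
sevc regress --strategy H --scales synth.csv --data constructs.csv --precip precip.csv
sevc scales validate|normalize|dedupe table.csv
sevc run --stages simulate,featurize,crossval,synth_scales,optimize_strategy,evaluate,regress \
     --seed 1 --out run/
```

`sevc run` chains the full pipeline on synthetic data and writes every
stage's artifacts (CSV/JSON/FASTA/YAML), a config snapshot, and a log into
the output directory; a single master seed fans out to per-stage seeds so
each stage is independently reproducible.

Scale tables are wide CSVs: a `residue` column of one-letter codes,
then one column per scale. Constructs travel as CSV
(`id,insert_id,strategy_id,sequence,label` with labels +1 soluble /
−1 insoluble).

## Package layout

| module | contents |
| --- | --- |
| `sevc.scales` | scale table type, wide-CSV I/O, normalization, reversal dedupe, random initials |
| `sevc.features` | insertion strategies, construct assembly, composition features, FASTA/CSV/YAML I/O |
| `sevc.core` | stump training, soft voting, MCC/accuracy, importance ranking, MC-CV, model-size selection |
| `sevc.strategy_opt` | modification vector, per-strategy contingency accumulation, hill climb |
| `sevc.scale_opt` | FN/FP composition statistics, scale stepping, synthesis/optimization loops |
| `sevc.evaluation` | final-model evaluation, percent-change metric, scale-table PCA |
| `sevc.regression` | mean continuous MC-CV predictions, OLS precipitation fit |
| `sevc.simulate` | synthetic grids with ground truth, stratified split, precipitation generator |
| `sevc.workflow` / `sevc.cli` | pipeline orchestration and the `sevc` CLI |
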