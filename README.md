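# protacable

Sequence-based prediction of whether a protein can be degraded through
CRBN-recruiting PROTACs, with residue-level interpretation.

PROTACs (proteolysis-targeting chimeras) are bifunctional molecules that
link a target-binding warhead to an E3-ligase-recruiting moiety; a
successful ternary complex routes the target into the ubiquitin–proteasome
system. Which proteins are *degradable* this way is known for only a few
hundred cases. `protacable` is for computational chemists and drug-discovery
scientists who want to (a) train and evaluate sequence-based degradability
classifiers on labeled protein sets, (b) scan a proteome for candidate
degradable proteins at a calibrated false-positive rate, and (c) ask *which
residues* drive a prediction.

## What's inside

- **Features.** Six classical descriptor families computed in-package (TPC,
  GTPC, CTriad, CTDD, Geary autocorrelation, quasi-sequence order), plus a
  pluggable embedder contract with three providers: a protein-language-model
  adapter (optional external weights), precomputed embedding tables, and a
  deterministic synthetic embedder. Contact-probability matrices
  (E3 x target) can be max-pooled into fixed-length features.
- **Models.** Random forest / gradient-boosted trees with the four
  regularising hyper-parameters tuned by 5-fold grid search; stratified
  5-fold cross-validation repeated twice; ROC-AUC, average precision
  AP = Σₙ (Rₙ − Rₙ₋₁) Pₙ, and FPR–threshold curves. The deployable model is
  the ten CV fold models soft-voting with equal weight; a consensus mode
  (positive only if all members agree) is available. Decision thresholds
  are calibrated to a target false-positive rate on the fold-averaged
  FPR–threshold curve.
- **Interpretation (eSHAP).** Embedding features are ranked by exact
  tree-Shapley attributions (in-package path-dependent TreeSHAP, numba
  accelerated); each residue is mutated to an opposite-property amino acid,
  the mutant is re-embedded, and positions are scored by
  `sqrt(Σₙ (fₙ_ref − fₙ_mut)²)` over the top-20 features. Top-ranked
  positions are the protein's key positions.
- **Synthetic benchmark.** A generator of labeled protein sets (201/234
  class balance) with a planted motif and a matching embedder, so the whole
  pipeline — classification and residue recovery — is testable end-to-end
  with no downloads.

## Worked example

```python
from protacable import SimulationConfig, benchmark_run

report = benchmark_run(SimulationConfig(seed=0))
for k in ("mean_roc_auc", "mean_ap", "threshold_at_target_fpr",
          "sensitivity_at_calibrated_threshold", "motif_enrichment"):
    print(k, round(report[k], 3))
```

prints

```
mean_roc_auc 0.933
mean_ap 0.924
threshold_at_target_fpr 0.88
sensitivity_at_calibrated_threshold 0.785
motif_enrichment 9.684
```

Reading: on the default synthetic conditions (435 proteins, 64-d
embeddings, planted 8-residue motif, 5% label noise) the tuned forest
reaches a cross-validated ROC-AUC of 0.933 and average precision of 0.924;
a decision threshold of 0.88 holds the fold-averaged false-positive rate at
or below 0.05 while still recalling 78.5% of positives out-of-fold; and the
residue scan ranks true motif positions into the top 10% of positions 9.7x
more often than chance — i.e. the pipeline recovers both the signal and
*where* the signal lives.

The same flow from the shell:

```
protacable simulate --out-fasta sim.fa --out-labels sim.tsv --out-truth truth.json
protacable featurize --fasta sim.fa --descriptor gtpc --out features.tsv
protacable cv --features features.tsv --labels sim.tsv --algo rf --out report.json
protacable train --features features.tsv --labels sim.tsv --out-bundle model/
protacable scan --bundle model/ --features features.tsv --out hits.tsv
```

## Layout

```
src/protacable/
  seq_io.py       FASTA / label / prediction I/O, canonical sequences
  descriptors.py  six descriptor families + concatenation
  aa_tables.py    shipped amino-acid tables (all overridable)
  embedding.py    Embedder contract, PLM adapter, contact pooling
  model_core.py   grid search, repeated stratified CV, metrics, ensembles
  _treeshap.py    exact path-dependent TreeSHAP
  eshap.py        feature selection, mutation scheme, residue scanning
  synthetic.py    planted-motif generator + synthetic embedder
  cli.py          `protacable` command-line interface
```
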