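# Methods

## Problem and model

`protacable` addresses a binary classification problem from targeted protein
degradation: given only a protein's amino-acid sequence, predict whether the
protein can be degraded through a CRBN-recruiting PROTAC (a bifunctional
molecule that bridges the target and the cereblon E3 ligase so the target is
ubiquitinated and degraded). Labeled data for this problem is scarce — a few
hundred proteins — so the package follows the design that works in that
regime: a fixed-length sequence representation feeding a tree ensemble
(random forest or gradient-boosted trees), with only the four
capacity-controlling hyper-parameters tuned (`max_depth`,
`min_samples_split`, `min_samples_leaf`, `n_estimators`; everything else at
library defaults) via 5-fold grid-search cross-validation on ROC-AUC.

Representations come from three interchangeable providers behind one
`Embedder` contract:

1. **Classical descriptors** — tripeptide composition (TPC, 8000-d), grouped
   tripeptide composition (GTPC, 125-d), conjoint triads (343-d), the
   distribution component of composition/transition/distribution (CTDD,
   195-d), Geary autocorrelation (8 property scales x 30 lags) and
   quasi-sequence order (2 x (20 + 30)). These are computed in-package from
   shipped, overridable amino-acid tables.
2. **Protein-language-model embeddings** — an adapter that mean-pools
   per-residue transformer representations (special tokens excluded) into
   one vector. The weights are an optional external resource; a reader for
   precomputed embedding TSVs is provided so featurisation can happen
   elsewhere.
3. **Contact-map pooling** — a supplied E3-ligase x target
   contact-probability matrix is max-pooled along the target axis, giving a
   fixed-length per-E3-residue feature regardless of target length.
   Predicting the contact map itself is out of scope; matrices are consumed
   from files.

## Evaluation and the deployable ensemble

Models are evaluated by stratified 5-fold cross-validation repeated twice
(distinct shuffle seeds per repeat), reporting ROC-AUC and average precision
AP = Σₙ (Rₙ − Rₙ₋₁) Pₙ over descending unique score thresholds, without
interpolation. The ten fold models are not discarded: the deployable
classifier is exactly those ten models voting softly with equal weight (a
full-data refit is available behind a flag but is not the default, since the
fold models are what the validation curves describe).

For proteome-scale screening the decision threshold is calibrated on the
false-positive-rate-versus-threshold curves of the validation folds: each
fold's step curve is evaluated right-continuously on a 0.00–1.00 grid (step
0.01, matching the two-decimal precision thresholds are quoted at),
averaged, and the smallest grid threshold whose averaged FPR meets the
target is returned. Ties at the threshold count as positive calls
everywhere in the package.

## Residue-level interpretation (eSHAP)

Tree-ensemble attributions are computed with an in-package implementation
of path-dependent TreeSHAP (the polynomial-time algorithm over
subset-permutation weights, jit-compiled with numba). It is exact: for
every sample, base value plus attribution sum equals the raw model output —
the positive-class probability for forests, the log-odds margin for
boosting (the scale on which boosting is additive). The test suite checks
this identity and, on trees of depth ≤ 2, equality with an exhaustive
subset-enumeration Shapley oracle to 1e-9.

The embedding features are ranked by mean absolute attribution over the
labeled training matrix, averaged across the ten ensemble members (the
members are equally valid fits; averaging removes fold-to-fold noise), and
the top 20 are selected. Each residue is then mutated, one at a time, to an
amino acid of the opposite physicochemical property, the full mutant
sequence is re-embedded with the same windowing policy as the wild type,
and the position is scored by the Euclidean distance between wild-type and
mutant embeddings restricted to the selected features. The top-ranked
positions (default: top 5% by ceiling) are the protein's key positions.

The opposite-property map is a package default shipped as an editable
table: K→E, R→E, H→D (positive→negative); D→K, E→K (negative→positive);
S,T,N,Q,Y→L and C→A (polar→hydrophobic); A→S, V→T, L,I,M,F,W→S and P↔G
(hydrophobic/special→polar or flexibility flip). Only the property classes
are constrained by the method; the specific partners are a documented
choice, and every report records the scheme used. One global scheme is used
for all proteins. When fewer or more than 20 features are selected, the
difference-score sum simply runs over the selected set and the output
metadata records k.

## Synthetic benchmark: what it emulates and what it does not

Real degradability labels and pretrained embeddings are external resources,
so the package ships a generator that emulates the *shape* of the problem:
201 positives vs 234 negatives (the class balance of the published kinome
degradation screen), sequence lengths uniform on 200–600, residues drawn
i.i.d. from natural amino-acid frequencies, and a planted 8-residue motif
(default `CWKHYDER`) overwritten at uniform non-overlapping positions in
every positive; negatives are guaranteed motif-free. Observed labels flip
with probability 0.05, a stand-in for assay ambiguity (e.g. proteins
degradable only through another E3 ligase being labeled negative).

The synthetic embedder is a pure function of (sequence, seed): signed
hashed 3-mer composition mapped to 64 coordinates, plus 0.25 x (motif 3-mer
count) on 8 designated signal coordinates, plus Gaussian noise (sd 0.1)
keyed to a hash of the sequence itself. Determinism therefore holds without
caching; any single-residue substitution re-keys the noise, so the
embedder is everywhere residue-sensitive, and substitutions inside the
motif additionally move the signal coordinates — which is what lets both
the classifier and the residue scan recover the planted structure. With
the signal coordinates disabled, the motif's residual trace in the hashed
composition is far below the noise floor, so classification collapses to
chance — the negative control.

Signal scale, noise and flip rate were fixed once at values giving a
clearly learnable but imperfect problem (CV ROC-AUC ≈ 0.93 at seed 0, not
1.0); they are configuration fields, not tuned quantities. What passing
tests show is that the pipeline recovers planted structure under these
conditions; they say nothing about accuracy on real degradation data,
which depends on real embeddings and labels. The generator does not
emulate kinase domain architecture, fold structure, homology between
proteins (folds are split randomly, not by family), or the CRBN/VHL
overlap statistics of real screens.

## Numerical and design choices

- **Sequence validation**: strict by default (any non-canonical letter is
  an error); opt-in mapping U→C, B→D, Z→E, O→K with X/gaps dropped.
  Residue indices are 1-based everywhere (residue 1 = N-terminus), and
  file headers say so.
- **Geary**: property scales are z-scored over the 20 amino acids
  (population sd) before use; zero-variance sequences return 0 rather than
  NaN so homopolymeric fixtures cannot poison matrices. The 8 default
  scales (hydropathy, hydrophilicity, residue mass, side-chain volume,
  polarity, isoelectric point, net charge, max ASA) are documented
  stand-ins — the descriptor literature does not pin a canonical set — and
  are swappable via `DescriptorParams.aa_properties`.
- **QSOrder**: the two default 20x20 distance matrices are derived at
  import from the shipped property scales (hydropathy/hydrophilicity/
  volume and polarity/charge/mass, z-scored, RMS difference), standing in
  for the classical literature matrices; both are overridable.
- **CTriad**: frequency normalisation count/(L−2) by default (keeps the
  sum-to-one invariant testable); min–max rescaling available via flag.
- **Minimum lengths**: descriptors needing length > n_lag raise instead of
  silently truncating.
- **Long sequences**: consecutive non-overlapping windows (default cap
  1022 residues), averaged with length-proportional weights; equals the
  plain embedding whenever the sequence fits one window.
- **Seeds**: one master seed; CV repeats use `seed + repeat_index`, fold
  models `seed + global_fold_index`; the synthetic noise is keyed to
  (sequence, seed). Full runs are bit-reproducible.
- **Grid-search tie-breaks**: equal mean AUC resolves to fewer trees, then
  shallower depth, then grid order.
- **Benchmark sizing**: the end-to-end benchmark uses a reduced 8-point
  forest grid (depth {10, ∞} x leaf {1, 3} x trees {100, 200}) and a fixed
  100-tree depth-3 boosting comparison; `grid_search` itself defaults to
  the full 108-point grid. The residue scan covers 20 positive proteins.

## Known limitations

- The contact-map and language-model providers consume external artifacts;
  the package validates and pools them but cannot produce them.
- Path-dependent TreeSHAP conditions on the trees' training covers; its
  attributions differ from interventional SHAP when features are strongly
  correlated.
- The precomputed-embedding provider cannot embed novel sequences, so it
  cannot drive the mutational scan (which re-embeds mutants); use the
  language-model adapter or the synthetic embedder for eSHAP.
- Threshold calibration assumes the validation folds' score distribution
  transfers to the screening population; a proteome with very different
  composition can realise a different FPR at the calibrated cutoff.
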