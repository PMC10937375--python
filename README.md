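# pdskit

Pathway-level tumor subtyping toolkit for bulk and single-cell expression
matrices:

- **Single-sample gene-set scoring** — ssGSEA (integrated weighted KS
  statistic, whole-matrix range normalization with stored extremes) and the
  kernel-CDF GSVA variant.
- **Unsupervised class discovery** — t-SNE embedding of the pathway score
  matrix, scaled k-means, and k selection by silhouette width, the elbow
  curve and bootstrap Jaccard cluster stability.
- **Feature selection** — subtype-specific gene sets (strict-max mean above
  the grand mean) with greedy correlation pruning (default |r| > 0.9).
- **Classification** — RBF-SVM with LOOCV-tuned hyperparameters and
  one-vs-one Platt-calibrated probabilities; new cohorts are scored with the
  stored training extremes and batch-corrected against the training cohort
  (reference-batch empirical-Bayes ComBat). Samples whose maximum class
  probability falls below the threshold (default 0.6; 0.8 = stringent) are
  called `mixed`.
- **Derived indices** — stem maturation index (SMI: PRC-target minus
  MYC-target ssGSEA score rescaled to [-1, 1] within a cohort),
  median-based proliferative index, summed-GSVA replication stress
  (bulk) / rescaled summed-ssGSEA (single cell), CBC/RSC stem scores, and
  tertile-based "targets-high" cell labels.
- **Synthetic cohorts** — a ground-truth generator (planted subtype
  programs, 50/50 "mixed" blends, batch shifts, latent differentiation
  axis) so the whole pipeline is testable without downloads.

SMI is rescaled within the supplied cohort, so SMI values are **not**
comparable across independently scored cohorts.

## CLI

All subcommands write plain TSV/JSON outputs plus a `<command>.run.json`
sidecar (version, parameters, seed, input sha256 checksums).

```sh
# synthetic cohort with ground truth
pdskit simulate --n-samples 150 --seed 1 --out-dir data/

# pathway score matrix (TSV + JSON sidecar with the stored range)
pdskit score --expression data/expression.tsv --gmt data/sets.gmt --out-dir scores/

# unsupervised class discovery (labels, diagnostics, embedding)
pdskit discover --expression data/expression.tsv --gmt data/sets.gmt \
    --seed 1 --out-dir discovery/

# subtype-specific, correlation-pruned features
pdskit select-features --scores scores/scores.tsv --labels data/labels.tsv \
    --out-dir features/

# train / predict
pdskit train --expression data/expression.tsv --labels data/labels.tsv \
    --gmt data/sets.gmt --seed 1 --out-dir model/
pdskit predict --model model/model.json --expression data/expression.tsv \
    --threshold 0.6 --out-dir calls/

# stem maturation index
pdskit smi --expression data/expression.tsv --gmt targets.gmt \
    --myc-set MYC_TARGETS --prc-set PRC_TARGETS --out-dir smi/

# proliferative index + replication stress
pdskit indices --expression data/expression.tsv --gmt stress.gmt \
    --pcna-set PCNA_SIG --mode bulk --out-dir indices/
```

Expression input is a genes x samples TSV/CSV (first column gene ids,
header sample ids) or a MatrixMarket triplet with `.genes`/`.samples`
sidecar files; values must already be log-scale/normalized (the loaders
never transform values, and missing values are an error). Gene sets use
the standard GMT format. Microarray probe matrices can be collapsed to one
row per gene with `pdskit.collapse_features` (highest mean probe wins).

Trained models persist as a single human-readable JSON archive embedding
the selected gene sets, the stored scaling extremes and the reference
score matrix, so prediction needs no other files.

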