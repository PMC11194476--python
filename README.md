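# omicsubtypes

Cancer subtype discovery from multi-omics data by **translating genomics
into protein space** and clustering the prediction with **deep subspace
contrastive clustering**.

Protein expression sits closer to phenotype than any genomics layer, but
in cohorts such as TCGA/TCPA only a subset of patients has reverse-phase
protein array data. `omicsubtypes` bridges that gap in two stages:

1. **Translation.** For each genomics view v (mRNA, miRNA, copy number,
   DNA methylation, ...) a patient similarity graph is built from cosine
   similarities: with η_i the K most similar other patients,

   A_ij = s(i,j)/Σ_{r∈η_i} s(i,r) · I(j∈η_i) + s(i,j)/Σ_{r∈η_j} s(r,j) · I(i∈η_j),

   and a two-layer graph convolutional network
   H_m = σ(D̂^{-1/2} Â D̂^{-1/2} H_{m-1} W_m), Â = A + I, maps X^(v) into
   protein space. The per-view outputs are averaged into P̂ and all GCNs
   are trained jointly on the masked loss ℓ_t = (1/n)‖P − P̂‖²_F over the
   n protein-observed patients only (transductive: the graphs always
   carry all N patients). The trained model then predicts protein
   expression for **every** patient.

2. **Clustering.** A GCN autoencoder embeds the predicted protein matrix
   as Z; a self-expression layer Ẑ = CZ (diag(C) = 0, no bias, no
   activation) re-expresses each patient as a linear combination of the
   others; training minimizes

   λ₁·(1/N)‖P − decode(Ẑ)‖²_F + λ₂·‖C‖²_F + λ₃·Σ_i ℓ_i,  (λ₁, λ₂, λ₃) = (0.01, 1, 1),

   where ℓ_i = −log [ exp s(z_i, ẑ_i) / Σ_{j≠i} exp s(z_i, ẑ_j) ] is a
   contrastive loss treating the embeddings of patient i before/after the
   self-expression layer as a positive pair. The coefficients are
   symmetrized into an affinity S = (|C| + |Cᵀ|)/2, and the k smallest
   eigenvectors of the normalized Laplacian L = I − D^{-1/2} S D^{-1/2}
   are k-means clustered into subtype labels.

Subtypes are evaluated by differential survival (multi-group log-rank
test, reported as −log₁₀ p) and by counting clinical parameters enriched
in the clustering (χ² for discrete, Kruskal–Wallis for continuous,
Benjamini–Hochberg adjusted p < 0.05). Robustness protocols — a
protein-missing-rate sweep, a contrastive-ablation comparison, and
ten-round 80% subsampling stability (ARI against the base labels) — are
built in, together with a seeded synthetic multi-omics generator so every
stage is testable without external cohorts.

## Worked example

Simulate a cohort of 150 patients in 3 latent subtypes (two genomics
views, 20 proteins, 20% of patients lacking protein data) and run the
full pipeline:

```bash
cat > config.yaml <<'YAML'
simulate:
  n_samples: 150
  n_subtypes: 3
  missing_rate: 0.2
data:
  views: [demo_data/view1.tsv, demo_data/view2.tsv]
  protein: demo_data/protein.tsv
  clinical: demo_data/clinical.tsv
  out_dir: demo_run
n_clusters: 3
seed: 5
YAML
omicsubtypes simulate --config config.yaml --seed 5 --out demo_data
omicsubtypes run --config config.yaml
cat demo_run/report.tsv
```

which prints:

```
simulated 150 samples (120 with protein) into demo_data
run complete: demo_run
metric	value
neglog10_logrank_p	7.261111843
n_enriched_clinical	1
```

The three recovered subtypes (`demo_run/labels.tsv`, 50/50/50 patients,
ARI = 1.0 against `demo_data/truth_labels.tsv`) separate survival
strongly (log-rank p ≈ 5.5·10⁻⁸, i.e. −log₁₀ p ≈ 7.26) and exactly one
clinical parameter is enriched: the subtype-linked discrete marker
(χ² adjusted p ≈ 4·10⁻⁵⁶) but not the independent continuous noise
covariate (Kruskal–Wallis adjusted p ≈ 0.76), as it should be.

Other subcommands: `translate` (stage 1 only), `cluster` (stage 2 on any
feature matrix), `evaluate` (statistics for existing labels),
`stability` (subsampling protocol) and `sweep-missing` (missing-rate
robustness). Every subcommand takes `--seed`; a `manifest.json` with the
resolved configuration and seed makes each run exactly reproducible.

## Layout

- `omicsubtypes.datamodel` — omics matrices, clinical tables, TSV/CSV I/O,
  z-score standardization, sample alignment across views
- `omicsubtypes.graph` — weighted KNN patient similarity graphs
- `omicsubtypes.nn` / `omicsubtypes.autodiff` — GCN layers and the
  autodiff/Adam machinery that trains them
- `omicsubtypes.translation` — per-view GCNs, fusion, masked training,
  protein prediction
- `omicsubtypes.subspace` — GCN autoencoder, contrastive self-expression,
  spectral clustering
- `omicsubtypes.evaluation` — log-rank, clinical enrichment, ARI,
  subsampling stability
- `omicsubtypes.synthetic` — seeded latent-factor multi-omics generator
- `omicsubtypes.pipeline` / `omicsubtypes.cli` — orchestration and the
  `omicsubtypes` command

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical design choices.
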