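# celldecon

Estimating the immune cell composition of complex tissues — tumor biopsies,
blood, any bulk sample — from its gene expression profile.  Laboratory
methods such as flow cytometry and immunohistochemistry resolve cell
fractions directly but cannot be applied retrospectively to the vast
archives of bulk transcriptomes; *in silico* deconvolution can.

celldecon implements linear gene-expression deconvolution end-to-end.  The
expression of gene *i* in mixture *j* is modeled as the proportion-weighted
sum over *r* cell types,

    M_ij = Σ_k S_ik F_kj        (M ≈ S F),

where *S* is a **signature matrix** (t discriminating genes × r cell types)
and *F* the cell fractions (non-negative, summing to 1 per sample).  The
package covers both halves of the problem:

* **Signature construction** from replicated reference profiles:
  quantile normalization; outlier screening (complete-linkage clustering
  plus a within-class Pearson rule, R < 0.85 in more than 2/3 of pairs);
  black-list removal of genes active in normal tissues (enrichment score
  > 0 in > 5% of tissues) or cancer cell lines (log2 > 7); pairwise Welch
  t-tests with per-pair Benjamini–Hochberg q < 0.3; top-G union lists
  ranked by |log2 fold change|; and selection of G (scanned 5–100) by
  minimizing the condition number κ = σ_max/σ_min of the candidate matrix.
* **Deconvolution** of mixtures by linear-kernel ν-support-vector
  regression with model selection over ν ∈ {0.25, 0.5, 0.75} (lowest
  reconstruction RMSE wins), negative-coefficient clipping and sum-to-one
  normalization.
* **Evaluation** against partially observed ground truth (subset
  rescaling, per-cell-type and per-sample Pearson r and RMSE) and a
  **synthetic-data generator** with known mixing proportions so every
  stage is testable without external data.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Simulate a small reference panel and mixtures, build a signature, estimate
fractions, and score them against the known truth:

```sh
$ cat spec.yaml
n_classes: 4
n_genes: 300
markers_per_class: 5
replicates_per_class: 3
n_mixtures: 8
seed: 11

$ celldecon simulate --spec spec.yaml --out-dir sim
wrote sim/{refs,classes,mixtures}.tsv truth.csv

$ celldecon build-signature --refs sim/refs.tsv --classes sim/classes.tsv \
      --g-min 2 --g-max 30 --out sig.tsv
G=6 kappa=2.175 genes=14 -> sig.tsv

$ celldecon deconvolve --mixtures sim/mixtures.tsv --signature sig.tsv \
      --out proportions.csv
deconvolved 8 sample(s) -> proportions.csv

$ celldecon evaluate --est proportions.csv --truth sim/truth.csv \
      --out benchmark.json
overall r=0.9985 rmse=0.0147 -> benchmark.json

$ head -3 proportions.csv
sample,class_01,class_02,class_03,class_04,chosen_nu,reconstruction_rmse,reconstruction_correlation
mix_001,0.0646956267391,0.206728514534,0.254724925241,0.473850933486,0.5,0.029869049242,0.999540525045
mix_002,0.855908666323,0,0.132513689228,0.0115776444483,0.5,0.0791756074116,0.996993247769
```

Reading the output: the signature scan settled on G = 6 genes per class
pair (14 genes after the union, condition number 2.175, well conditioned);
mixture 1 is estimated as 6.5% type 1, 20.7% type 2, 25.5% type 3, 47.4%
type 4, fitted at ν = 0.5 with an expression-space reconstruction RMSE of
0.030 (standardized units); pooled over all 8 samples × 4 types the
estimated fractions correlate with the simulated truth at r = 0.9985 with
RMSE 0.0147 in proportion units.  There is also a `qc` subcommand that
writes the outlier report and sample dendrogram for a reference panel.
Every subcommand writes a `*.provenance.json` sidecar (input checksums,
configuration, version) for auditability.

The same pipeline is available as a library:

```python
from celldecon import (GeneratorSpec, generate_references, generate_mixtures,
                       construct_signature, deconvolve)

spec = GeneratorSpec(seed=11)
refs, classes = generate_references(spec)
mixtures, truth = generate_mixtures(refs, classes, spec)
signature, selection, deg = construct_signature(refs, classes)
fractions = deconvolve(mixtures, signature)
```

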