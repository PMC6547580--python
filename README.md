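# pam50kit

Intrinsic subtyping of breast tumors and cross-platform concordance
analysis for paired digital multiplexed (NanoString-style) and RNA-Seq
expression data.

Gene-expression signatures such as PAM50 assign breast tumors to five
intrinsic subtypes — Basal-like, HER2-enriched, Luminal A, Luminal B,
Normal-like — by correlating a sample's 50-gene log2 profile with five
prototype centroids, and summarize prognosis as a risk-of-recurrence (ROR)
score. Laboratories increasingly run the same assay on two very different
platforms (digital probe counts vs RNA-Seq), and the practical question is
whether the calls and scores agree well enough to use the platforms
interchangeably. `pam50kit` is a tested implementation of that whole
workflow for analysts who need it end to end:

* **normalization** — digital counts: negative-probe background
  subtraction (mean − 2·SD), flooring, housekeeper geometric-mean scaling,
  log2; RNA-Seq: fixed upper-quartile scaling (75th percentile → 1000),
  log2(x+1), reference-median centering;
* **classification** — per-sample Spearman correlation to each centroid
  ρ_k, call = argmax_k ρ_k, with an ambiguity flag when the top-two gap is
  ≤ 0.10, a confidence margin, the Proliferation Score (mean log2 of 11
  proliferation genes), and ROR-S / ROR+PS = rescale(Σ w_k ρ_k [+ w_p P])
  with low/med/high risk groups;
* **concordance** — raw and ambiguity-adjusted call agreement, Cohen's
  kappa, per-gene Spearman rho and two-way single-measures ICC (consistency
  and absolute agreement, F-based 95% CI), Bland-Altman limits of
  agreement, risk-group discordance, and cohort summary statistics;
* **synthetic data** — a paired-platform cohort generator with known
  ground truth (subtype mixture, platform noise, housekeepers, negative
  probes, injectable cross-platform discordance) so the full pipeline is
  testable without patient data.

See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.

## Worked example

Everything is available as a library (`import pam50kit`) and as a CLI. A
complete round trip on a simulated 96-sample cohort:

```sh
pam50kit simulate --n 96 --seed 7 --out fixtures
pam50kit normalize-nanostring --counts fixtures/probe_counts.tsv \
    --housekeepers ACTB,MRPL19,PSMC4,RPLP0,SF3A1 --out ns.tsv
pam50kit normalize-rnaseq --counts fixtures/rnaseq_counts.tsv \
    --ref-medians fixtures/reference_medians.tsv --out rs.tsv
pam50kit classify --expr ns.tsv --platform nanostring \
    --centroids fixtures/centroids.tsv --out calls_ns.tsv
pam50kit classify --expr rs.tsv --platform rnaseq \
    --centroids fixtures/centroids.tsv --out calls_rs.tsv
pam50kit concord --calls-a calls_ns.tsv --calls-b calls_rs.tsv \
    --expr-a ns.tsv --expr-b rs.tsv --out-dir report
pam50kit report --summary report/summary.json
```

The `classify` step prints the subtype frequency table, here identical on
both platforms:

```
        count    percent
Basal      77  80.208333
Her2       15  15.625000
LumA        3   3.125000
LumB        1   1.041667
Normal      0   0.000000
```

and `report` digests the agreement statistics:

```
samples: 96
raw concordance: 100.0%  adjusted: 100.0%  kappa: 1.000
ror_s: rho 0.652, ICC 0.937 [0.907-0.958]
ror_ps: rho 0.794, ICC 0.935 [0.904-0.956]
per-gene: median ICC 0.901, 92% of genes rho > 0.8
```

Reading: every sample received the same subtype call on both platforms
(raw concordance 100%, chance-corrected kappa 1.0); the continuous ROR
scores track each other closely in absolute terms (ICC ≈ 0.94 with its 95%
CI), with the rank correlation lower than the ICC because most samples are
Basal-like and cluster in a narrow score range; and gene-level expression
agrees strongly (median ICC 0.90, 92% of genes with rho > 0.8). Detailed
tables (cross-table, per-gene statistics, discordance records, Bland-Altman
pairs) are written under `report/`.

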