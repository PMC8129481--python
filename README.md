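# lipoproteome

Tools for comparing the protein cargo of lipoprotein(a) and LDL particles and
for screening the causal influence of lifelong Lp(a)/LDL-cholesterol exposure
on the plasma proteome:

* **`lipoproteome.lfq`** — label-free differential enrichment of paired
  LPA/LDL protein-intensity matrices: per-sample median normalization,
  first-percentile noise imputation of missing values, a quantifiability
  filter (replicate presence in ≥ 2/3 of one fraction's replicates, ≥ 2
  peptides), paired t-testing on log2 intensities, empirical-Bayes variance
  moderation, Benjamini–Hochberg FDR control, and a cross-phase replication
  rule.
* **`lipoproteome.prm`** — targeted PRM absolute quantification against
  heavy-peptide spikes: injection averaging, internal-standard
  normalization, standard-curve linearity QC, fmol/µg concentrations, molar
  ratios, and Welch comparison of fractions.
* **`lipoproteome.mr`** — two-sample Mendelian randomization: instrument
  selection (P < 5×10⁻⁸), greedy LD clumping (r² < 0.1), allele
  harmonization, Wald ratios, fixed-effect IVW meta-analysis, and Bonferroni
  screening over a protein panel.
* **`lipoproteome.simulate`** — seeded generators for all three stages
  (paired intensity matrices with intensity-dependent missingness, PRM
  dilution series, two-sample MR summary statistics with allele flips).
* **`lipoproteome.io` / `lipoproteome.report`** — TSV formats for every
  artifact, PCA sample diagnostics, volcano tables, YAML run configuration.

Two small published reference tables ship with the package
(`lipoproteome/data/`) and back the replay-style validation tests.

## CLI

A single `lipoproteome` entry point with one group per stage:

```sh
# synthetic inputs
lipoproteome simulate lfq --seed 1 --n-proteins 2000 --n-enriched 20 \
    --out-matrix matrix.tsv --out-samples samples.tsv --out-truth truth.tsv
lipoproteome simulate prm --seed 1 --out-calibration cal.tsv --out-samples prm_samples.tsv
lipoproteome simulate mr  --seed 1 --n-instruments 54 --n-null 100 --out-dir mr_sim/

# analyses
lipoproteome lfq-diff run --matrix matrix.tsv --samples samples.tsv \
    --alpha 0.05 --q-discovery 1e-4 --out diff.tsv
lipoproteome prm-quant run --calibration cal.tsv --samples prm_samples.tsv --out prm.tsv
lipoproteome mr-screen run --exposure mr_sim/exposure.tsv --panel-dir mr_sim/panel \
    --alpha 0.05 --m 3283 --out mr.tsv

# diagnostics / figure tables
lipoproteome report pca --matrix matrix.tsv --samples samples.tsv --k 2 --out pca.tsv
lipoproteome report volcano --results diff.tsv --effect-col ratio --p-col q_mod \
    --ratio --out volcano.tsv
```

`lfq-diff run` accepts `--no-log` to run the paired test on raw rather than
log2 intensities, and `--frac` / `--min-peptides` to change the
quantifiability rule. `mr-screen run` takes an optional `--ld LD.tsv`
(square r² matrix keyed by variant id) to clump instruments before the
screen.

## File formats

All artifacts are tab-separated text. Intensity matrices carry
`protein_id`, `peptide_count`, then one column per sample, with missing
cells empty or `NA`; a companion sample sheet maps `sample_id` to
`condition` (`LPA`/`LDL`) and `pair_id`. GWAS summary statistics use
`variant_id effect_allele other_allele beta se [pvalue] [eaf]`. Floats are
written with 17 significant digits so write→read round-trips are exact.
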