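# dgecompare

Tools for benchmarking **3′-end digital gene expression (3′-DGE)** — tag-based
mRNA-seq quantified by counting unique molecular identifiers (UMIs) — against
**conventional random-primed mRNA-seq** quantified by read counts, on count
matrices from the same RNA samples measured both ways.

The two library strategies differ in ways that matter for every downstream
analysis: random priming yields read counts that scale with transcript length
and retain PCR duplication bias, while 3′-DGE yields length-independent UMI
counts at the price of reduced effective depth (each UMI is backed by several
PCR-duplicated reads) and some lost sensitivity for low-copy transcripts.
`dgecompare` implements the complete comparison pipeline for this setting, plus
a synthetic-data generator with known ground truth for validating every stage:

- **Depth matching** by in-silico read removal: uniform removal of individual
  reads is one multivariate hypergeometric draw per sample
  (`downsample.downsample_sample`), with UMI counts removed in lockstep with
  probability *u/c* per removed read (`downsample_paired`), and a
  `fixed_probability` variant that freezes removal probabilities at their
  initial proportions.
- **Detection saturation**: genes count as detected at ≥ 4 counts; detected
  genes vs depth follows a saturating curve fit by the Michaelis–Menten form
  *G(d) = V*<sub>max</sub>·*d* / (*K*<sub>m</sub> + *d*), where
  *V*<sub>max</sub> is the asymptotic detectable-gene count and
  *K*<sub>m</sub> the half-saturation depth (`detection`).
- **Quantitative concordance**: transcript-length normalization (counts per kb)
  of the conventional side, CPM-style unit scaling, log2(x+1) transform,
  replicate and cross-method Pearson correlations, and an x = y band of
  ±*k*·SD flagging method-biased genes (`concordance`).
- **Differential expression**: a self-contained edgeR-classic stack — TMM
  normalization, quantile adjustment to a common library size, conditional
  maximum-likelihood NB dispersion (common + shrunken tagwise), the
  conditional negative-binomial exact test, Benjamini–Hochberg FDR — plus
  DEG-count-versus-depth curves (`diffexp`).
- **Rank–rank hypergeometric overlap (RRHO)**: genes ranked by signed
  −log10 *p*; a stepped grid of rank-cutoff pairs scored by one-tailed
  Fisher/hypergeometric tests, signed by enrichment vs depletion (`rrho`).
- **GO power analysis**: Monte-Carlo power of the two-sided Fisher exact test
  to detect a biological process's differential detectability between the two
  methods' detected gene sets (`gopower`).

## Worked example

```python
from dgecompare.simulate import SimulationConfig, simulate_paired_experiment, generate_gene_table
from dgecompare.downsample import downsample_to_common_depth
from dgecompare.detection import count_detected
from dgecompare.concordance import cross_method_concordance
from dgecompare.diffexp import run_de

cfg = SimulationConfig(n_genes=8000, n_control=8, n_treated=4,
                       library_size_mean=1.5e6, n_de_genes=1500, seed=1)
conv_reads, dge_reads, dge_umis, truth = simulate_paired_experiment(cfg)
print("reads per UMI:", round(dge_reads.counts.sum() / dge_umis.counts.sum(), 2))

conv_ds, umi_ds = [r.counts_at_depth for r in
                   downsample_to_common_depth([conv_reads, dge_umis], seed=1)]
print("genes detected (conv):", count_detected(conv_ds.counts[:, 0]))
print("genes detected (dge): ", count_detected(umi_ds.counts[:, 0]))

table, _ = generate_gene_table(cfg)
pairs = cross_method_concordance(conv_reads, dge_umis, table)
print("mean r raw / length-normalized: %.2f / %.2f"
      % (pairs.r_raw.mean(), pairs.r_length_norm.mean()))

res = run_de(conv_reads, ("TRT", "CTRL"))
print("DEGs at FDR<0.1:", res.n_deg_at_cutoff, "of", len(res.table), "tested")
```

Output:

```
reads per UMI: 2.49
genes detected (conv): 6334
genes detected (dge):  5960
mean r raw / length-normalized: 0.75 / 0.81
DEGs at FDR<0.1: 806 of 7980 tested
```

Read: the DGE arm carries ~2.5 reads per UMI (PCR duplication), detects ~6%
fewer genes than the conventional arm at matched depth in this simulation
(the per-gene dropout of low-copy transcripts), and cross-method agreement
improves from r = 0.75 to 0.81 once conventional counts are divided by
transcript length — UMI counts need no such correction.

## Command line

Every stage is also exposed as a subcommand of the `dgecompare` CLI:

```bash
dgecompare --seed 1 --out-dir out simulate --n-genes 8000
dgecompare --out-dir out downsample --counts out/conv_reads.tsv \
    --sample-sheet out/sample_sheet.tsv --target-depth common
dgecompare --out-dir out de --counts out/conv_reads.tsv \
    --sample-sheet out/sample_sheet.tsv --treatment TRT --control CTRL
dgecompare --out-dir out rrho --a out/de_TRT_vs_CTRL.tsv --b other_de.tsv
```

Inputs are plain TSV (count matrix, sample sheet, gene-length table) and GMT
gene sets; thresholds live in a YAML config (`--config`), defaulting to the
standard values (detection ≥ 4 counts, FDR < 0.1, RRHO step 10, bias band
k = 2).

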