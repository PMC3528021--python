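# lincnv

Paired tumor-normal SNP-array copy-number / LOH analysis with an
intergenic-lincRNA focus, exercised end-to-end on a synthetic-cohort
generator.

The pipeline takes per-probe LRR/BAF signal tables for matched tumor-normal
pairs, conditions them (Y-chromosome and no-call filtering, replicate
averaging, linear GC-wave correction, matched-pair subtraction), partitions
the paired signals by recursive binary segmentation with a t-statistic
stopping rule, classifies segments into gain / loss / homozygous loss /
allelic-imbalance (copy-neutral LOH) calls, dissects every aberration into
genic, lincRNA and non-lincRNA-intergenic base pairs, aggregates
cross-sample frequencies into Circos-ready text tracks, and runs the
inferential layer (exact two-tailed Wilcoxon signed-rank test, OLS
regression, fold ratios). A qPCR module implements standard-curve
quantification, dual-reference tumor/normal copy ratios with a
deviation-from-unity cutoff, and the 2^-ddCt comparator. Because no real
array data ships with the package, a first-class simulator produces toy
genomes, annotation tracks, paired probe signals with planted events under
a purity-mixture signal model, and qPCR Ct tables with dilution-series
standards — all with exact ground truth for recovery testing.

## Command line

```sh
lincnv simulate  --config cfg.yaml            # synthetic cohort -> outdir
lincnv call      --config cfg.yaml            # filter/combine/correct/pair/segment
lincnv summarize --config cfg.yaml            # associations, compartments, stats, Circos
lincnv qpcr      --config cfg.yaml            # standard curves + copy ratios
lincnv all       --config cfg.yaml            # everything, in order
```

All stages are deterministic given the configured seed; `--seed` and
`--outdir` override the config. A minimal configuration:

```yaml
outdir: run1
simulation:
  seed: 7
  n_pairs: 7            # matched tumor-normal pairs
  spacing: 700          # mean inter-probe gap (bp)
  purity: 1.0
  lrr_noise_sd: 0.15
calling:
  t_threshold: 5.0      # segmentation stopping rule
  min_call_probes: 5    # non-neutral calls below this are demoted
summarize:
  bin_size: 1000000     # aggregation bin for frequency tracks
qpcr:
  cutoff: 0.2           # loss if mean tumor/normal ratio < 1 - cutoff
```

Unknown keys are rejected; every tunable has a documented default
(`lincnv/config.py`, `lincnv/simulate.py`, `lincnv/segmentation.py`).

Key outputs under `outdir/`: probe signal TSVs (1-based positions on
disk), BED tracks, `truth.tsv`, per-sample SEG-style call tables (1-based
inclusive on disk, 0-based half-open in memory), `associations.tsv`
(per-lincRNA overlap bp and percent of gene length), `compartments.tsv`
(per-sample shares summing to 100), `cohort_stats.tsv` (Wilcoxon W/p,
genic-vs-lincRNA fold ratio, regression R^2), `circos_gains.txt` /
`circos_losses.txt` (`chrom start end value`), and qPCR ratio calls with
truth concordance.

## Notes

- Coordinates are 0-based half-open everywhere in memory; file formats use
  their native conventions and are converted on read/write.
- Segment boundaries are probe-resolution: a segment spans first probe
  position to last probe position + 1.
- Classification thresholds (LRR +/-0.25, homozygous -1.1, mirrored-BAF
  deviation 0.15) assume high tumor purity; at purity 0.5 the expected
  paired LRR of a single-copy loss shrinks to log2(0.75) ~ -0.415 and of a
  single-copy gain to log2(1.25) ~ 0.322, so low-purity cohorts need the
  thresholds lowered accordingly (they are configuration).
- The pipeline's GC correction uses a robust Theil-Sen slope; the plain
  OLS variant of `gc_correct` is available and is the documented default
  of the API function.
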