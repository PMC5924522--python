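# allochrony

Tools for quantifying temporal (time-of-day) reproductive isolation between
two strains of a nocturnal insect from timed mating trials, and for running a
simple time-course differential-expression analysis over a 2-strain ×
3-timepoint RNA-seq design. A pair of simulators generates both kinds of data
with known ground truth, so the whole pipeline is testable offline.

## What it does

**Mating-trial analysis** (`trial_stats`, `isolation`)

- Loads trial tables (`trial_id,strain,mated,time_h`) where mating times are
  quantized to a check schedule (default: every 20 min over a 7-h dark
  period). Times are kept as exact rationals.
- Per-strain summaries (mating proportion, median/mean mating time), a
  two-sided Fisher's exact test on mated/unmated counts and a tie-corrected
  Wilcoxon rank-sum test on mating times.
- The isolation statistic: matings are binned into one-hour windows; within
  each window the expected numbers of inter-strain (`2·p·q·n`) and
  intra-strain (`(p²+q²)·n`) pairings under random mating are accumulated,
  and `RI = 1 − Σhybrid / Σpure` (0 = random mating, 1 = complete temporal
  isolation). A stratified percentile bootstrap supplies a confidence
  interval, and sequentially acting barriers combine as
  `1 − Π(1 − strength_k)`.

**Expression analysis** (`expression`)

- CPM normalization, a weak-expression filter (default: ≥ 1 CPM in ≥ 7
  libraries), nine contrasts (between strains at each timepoint; between
  timepoint pairs within each strain) with log2 fold changes, Welch t-tests
  on log2(CPM + 0.5) and Benjamini–Hochberg q-values per contrast.
- Strain × timepoint mean profiles (6 points per transcript), pairwise
  Pearson correlations with t-distribution p-values (4 df), and a capped
  (±2) logFC heatmap with significance asterisks.
- Note: the significance computation is a deliberately simple surrogate for
  a negative-binomial GLM; it preserves the contrast structure and the FDR
  procedure, not any particular tool's p-values.

**Simulators** (`synthetic_data`)

- Mating trials: Bernoulli mating propensity plus a truncated-normal or
  gamma latent mating-time law, censored to the check grid.
- Counts: negative-binomial matrices (var = μ + φμ²) over the full design
  with per-library depth factors, optional dropped replicate, configurable
  per-transcript log2 effects and an optional correlated transcript module;
  ground truth is returned alongside the counts.

## Command line

```sh
# simulate a trial table and analyze it end to end
allochrony simulate-trials --n-trials 200 --seed 1 --out trials.csv
allochrony analyze-trials --trials trials.csv --n-boot 1000 --seed 1 \
    --seasonal-strength 0.66 --out report.json

# isolation statistic from a pre-binned window table (window, n_Z, n_E)
allochrony isolation --windows windows.tsv --out iso.json

# simulate counts and run the expression stage
allochrony simulate-counts --n-transcripts 2000 --seed 1 \
    --out-counts counts.tsv --out-meta meta.csv --out-truth truth.json
allochrony analyze-expression --counts counts.tsv --meta meta.csv --outdir out/
```

Options can also be supplied via `--config config.yaml`; explicit flags win.
Every JSON report embeds the tool version, the effective configuration and
its hash. Exit codes: 0 success, 2 validation error, 3 computation error.

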