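# m6acall

Window-based peak calling for MeRIP/m⁶A-seq on spliced-transcript
coordinates, plus the surrounding desk-scale analyses of an
epitranscriptomic target-discovery study: multi-dataset differential-
expression triage, mRNA/protein decay half-life fits, ΔΔCq qPCR relative
expression, caliper tumor volumes, and Spearman rank correlations.  A
seeded synthetic-data generator with known ground truth makes every stage
testable without downloads.

## Who this is for

Groups analyzing m⁶A immunoprecipitation sequencing (MeRIP-seq / m⁶A-seq):
an antibody-enriched IP library is sequenced alongside a matched input
library, and methylated regions show IP-over-input enrichment.  The
package calls enriched windows per gene, merges them into peaks, compares
peak sets between conditions (condition-unique peaks), profiles peak
positions along a normalized 5′UTR/CDS/3′UTR metagene axis, and intersects
the resulting gene lists with external differential-expression evidence to
nominate candidate target genes.

## The method

For each gene, the longest isoform is the analysis frame.  Aligned reads
are extended to the mean fragment size (150 bp) and projected from genome
to isoform coordinates, so windows never straddle introns.  Each
transcript is scanned with a 100-nt window sliding in 10-nt steps.
Windows below 1/20 of the gene's top window in **both** IP and input are
excluded.  Counts are normalized by the gene's median window count, and
each window's enrichment score is

```
ES = (a × d) / (b × c)
```

where `a`/`c` are the window's IP/input counts and `b`/`d` the gene-median
IP/input window counts.  Each window is tested with a two-sided Fisher
exact test on the 2×2 table `[[a, A − a], [c, C − c]]` (window vs rest of
the gene, IP vs input; `A`, `C` are the gene's fragment totals), p-values
are Benjamini–Hochberg adjusted across all retained windows, and windows
with FDR < 0.01 and log₂ ES ≥ 1 are positive.  Overlapping positive
windows are merged into peaks whose ES is recomputed on the merged
interval.

Around the peak caller: four-set triage applies the study cutoffs
(p < 0.05 with |log₂FC| > 0.5 for the two cuSCC comparisons, |log₂ TPM
difference| > 0.5 for the cell-line comparison, membership for the
unique-peak list) and intersects with direction agreement; half-lives are
t₁/₂ = ln 2 / k from an OLS fit of ln y on t; qPCR expression is
2^(−ΔΔCq); tumor volume is d²·D/2.

## Worked example

```python
import m6acall as m

cfg = m.SimulationConfig(seed=1, n_genes=5, shared_down=0, shared_up=0)
models, truth = m.simulate_gene_models(cfg)
ip, inp = m.simulate_fragments(models, truth, cfg)
res = m.call_peaks({g.gene_id: g for g in models}, ip, inp)
print(res.peaks[["gene_id", "start", "end", "n_windows", "es", "log2_es", "min_fdr"]]
      .round(3).to_string(index=False))
```

```
gene_id  start  end  n_windows    es  log2_es  min_fdr
  G0000    420  820         31 2.580    1.367      0.0
  G0001   1300 1720         33 2.978    1.574      0.0
  G0002    270  680         32 2.772    1.471      0.0
  G0003    110  520         32 2.898    1.535      0.0
  G0004    300  720         33 2.825    1.498      0.0
```

One peak per gene, each overlapping its planted 150-nt interval (for
example G0000's planted peak spans isoform positions 462–612).  The merged
peaks are wider than the planted interval because every 100-nt window
overlapping the enriched region by a window-step or more can reach
significance; the enrichment-score maximum, not the peak edge, localizes
the methylated site.  `min_fdr` is the smallest window FDR inside the
peak.

The decay model reads like a statsmodels fit:

```python
fit = m.fit_half_life(m.simulate_decay(4.0, cv=0.05, seed=2))
print(fit.summary())
```

```
Exponential decay fit
  method        : ols (n = 6)
  k (1/h)       : 0.1649
  t_1/2 (h)     : 4.204
  s.e.(t_1/2)   : 0.1731
  R^2 (log)     : 0.9933
  decaying      : True
```

A 4-hour half-life simulated with 5% noise over six timepoints is
recovered at 4.2 h with R² ≈ 0.99 on the log scale.

## Command line

`m6acall` exposes the pipeline as subcommands, each writing TSV outputs
plus a JSON run manifest (parameters, input digests, seed, version):

```
m6acall simulate  --seed 1 --out-dir data/
m6acall callpeaks --annotation data/models.bed --ip data/ip.bed \
                  --input data/input.bed --out-dir peaks/
m6acall diffpeaks --peaks-a peaksA/peaks.tsv --peaks-b peaksB/peaks.tsv --out-dir diff/
m6acall metagene  --peaks peaks/peaks.tsv --annotation data/models.bed --out-dir meta/
m6acall triage    --table unique_m6a=... --table rnaseq_ast_vs_control=... \
                  --table rnaseq_mouse_cuSCC=... --table rnaseq_human_cuSCC=... --out-dir triage/
m6acall halflife  --input decay.tsv --out-dir fits/
m6acall qpcr      --input cq.tsv --control ctl --out-dir rel/
```

All thresholds default to the study's printed values (window 100, step 10,
1/20 low-count filter, FDR 0.01, log₂ES 1, p 0.05, |log₂FC| 0.5).

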