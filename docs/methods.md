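# Methods

## Coordinate frame

All coordinates are 0-based, half-open.  GTF input (1-based, closed) is
converted on read; BED is native.  Peak calling happens entirely on
isoform (spliced-transcript) coordinates: position 0 is the transcript 5′
end, so minus-strand genes run antiparallel to the genome axis.  Per gene,
the longest isoform is the analysis frame; length ties break to the
lexicographically smallest transcript id (logged), so builds are
deterministic.  Projection is exact and bijective on exonic bases:
`project_to_genome(project_to_isoform(p), …)` returns `p` for every exonic
genome position, which the test suite checks on randomized multi-exon
models.

Libraries are assumed stranded (fr-firststrand).  A fragment is
represented by its strand-aware genomic 5′ base; extension to the library
fragment size (default 150 nt) happens in transcript space after
projection, so extended fragments follow splice junctions.  Fragments on
the opposite strand, or with intronic/off-transcript 5′ ends, are dropped;
`stranded=False` (CLI `--unstranded`) disables the strand check.

## Window pipeline

* **Grid** — 100-nt windows, 10-nt steps, starting at 0 while
  `start + window ≤ length`.  If the grid does not reach the 3′ end, one
  extra right-anchored window ending at the transcript end is appended;
  transcripts shorter than one window get a single full-length window.
  (The source procedure does not specify terminal-window handling; the
  right-anchored variant keeps every window at full width whenever the
  transcript allows it.)
* **Counting** — a fragment counts in every window its isoform interval
  overlaps by ≥ 1 nt (the source procedure extends reads to 150 bp but
  does not state the assignment rule; ≥ 1-nt overlap is the weaker
  assumption).  A midpoint rule is available behind
  ``count_rule="midpoint"`` (CLI ``--count-rule``); on simulated data at
  default depths both rules recover every planted peak, which the test
  suite asserts.
* **Low-count filter** — a window is excluded iff its count is below
  1/20 of the gene's top window in *both* libraries (configurable
  `min_frac`).  Exclusion removes the window from normalization medians,
  testing, and the FDR multiplicity.  A gene with zero counts in both
  libraries has every window excluded.
* **Normalization** — per gene, counts divide by the median count over
  retained windows (even count: mean of the middle pair).  A zero median
  falls back to the +1 pseudocount rule below.
* **Enrichment score** — ES = (a·d)/(b·c) with a/c the window IP/input
  counts and b/d the gene medians.  If either product is zero, all four
  terms get +1 before the ratio, keeping log₂ ES finite; the rule is
  pinned by unit tests.
* **Fisher test** — two-sided Fisher exact p for
  `[[a, A − a], [c, C − c]]`, where A and C are the gene's unique-fragment
  totals over retained windows (each fragment counted once).  The
  two-sided p sums hypergeometric probabilities ≤ the observed table's —
  the same rule `scipy.stats.fisher_exact` applies — evaluated in batch
  via `scipy.stats.hypergeom.logpmf`.  The test suite checks equivalence
  against both `fisher_exact` and an exact integer-arithmetic enumeration
  oracle.  An alternative table built from the rounded medians
  (`fisher_table="medians"`) is available for sensitivity analysis; the
  default uses gene totals because they are well-defined integer margins.
  Whether the original analysis tested raw or median-normalized counts is
  not documented; this implementation tests raw counts.
* **FDR** — Benjamini–Hochberg across all retained windows transcriptome-
  wide (`scipy.stats.false_discovery_control`), checked against the
  sort/p·m/rank/cummin definition.  Positive windows require FDR < 0.01
  and log₂ ES ≥ 1.
* **Merging** — overlapping (≥ 1 nt) positive windows merge per gene.  A
  peak's ES is recomputed from the merged interval's counts against the
  same gene medians (not the max of window ESs); `min_fdr` over member
  windows is reported for ranking.  Peaks project back to genome blocks
  for BED output.

Condition comparison: a peak is *shared* iff a peak on the same gene in
the other condition overlaps it by ≥ 1 nt in isoform coordinates,
otherwise *condition-unique*; gene-level unique lists feed the triage.

Metagene profile: each coding-gene peak contributes its isoform midpoint,
rescaled within its region to a 30/40/30-bin 5′UTR/CDS/3′UTR axis;
densities sum to 1 and non-coding peaks are counted and skipped.

## Target triage

Cutoffs are strict inequalities as printed in the source analyses:
p < 0.05 together with |log₂ fold change| > 0.5 for the two cuSCC
comparisons, |log₂ TPM difference| > 0.5 (no p rule) for the cell-line
comparison, and plain membership for the unique-peak list.  p is treated
as the upstream tool's adjusted p and is not re-adjusted.  A gene is
called shared_up/shared_down when it passes all four sets and the three
expression directions agree; all-four members with discordant directions
are reported separately.  Gene symbols are matched case-insensitively
after whitespace stripping; cross-species ortholog mapping is deliberately
out of scope and must be done upstream.

## Synthetic data

The generator's defaults are the package's study conditions: 50 genes,
1–6 exons, 800–3000-nt transcripts with a 10%/60%/30% UTR/CDS/UTR split,
input coverage of 50 expected fragment 5′ starts per 100 nt, negative-
binomial dispersion r = 10 (variance = μ + μ²/r), one planted 150-nt
8-fold-enriched interval per gene, 150-nt fragments, equal IP/input depth.
Desk-scale sizes (tens of genes, ~10⁵ fragments) are the package's own
choice for a fully testable surface; real libraries are hundreds of times
deeper, with correspondingly different absolute counts but the same
IP:input structure.

Per 100-nt tile, a Gamma(r, 1/r) rate multiplier (mean 1) is drawn once
and shared between IP and input; counts are Poisson given the multiplier,
hence marginally negative binomial.  Sharing the multiplier emulates
transcript-abundance and mappability bumps that hit both libraries of a
paired MeRIP experiment alike, and keeps the IP:input ratio clean under
the null — with independent per-library overdispersion, a window-vs-gene
Fisher test would reject spuriously at rates far above its nominal level,
which paired real libraries do not show.  Fragment 5′ starts are sampled
in isoform space with per-nucleotide rates (enrichment fold applied inside
planted intervals) and projected to the genome, so splice junctions are
exercised end to end.  What the simulation does **not** model: GC and
antibody-specificity biases, positional fragmentation bias, multimapping,
isoform mixtures, and exon-level expression heterogeneity finer than the
100-nt tile — so passing recovery tests demonstrate algorithmic
correctness under the stated generative model, not robustness to every
artifact of real libraries.

DEG tables are generated so that exactly the planted shared genes (default
10 down + 3 up) pass all four cutoffs with concordant directions, and each
non-planted gene fails at least one randomly chosen set.  Decay curves
follow y(t) = 2^(−t/t½) with multiplicative lognormal noise (log-sd = cv)
and renormalization to y(0) = 1; default timepoints 0, 1, 2, 4, 8, 12 h.

## Quantitative models

Half-life: OLS of ln y on t with free intercept; k = −slope, t½ = ln 2/k,
R² on the log scale, s.e.(t½) by the delta method (ln 2/k² · s.e.(k)).  A
non-decaying series (slope ≥ 0) reports t½ = ∞ with a flag rather than
raising.  A nonlinear single-exponential fit (`method="nls"`,
`scipy.optimize.curve_fit`) is available and agrees with OLS as noise → 0;
OLS is the default because it is closed-form and robust at the 4–7
timepoints typical of blockade time courses.  Tables with replicate/group
columns are fitted per replicate and summarized, since per-replicate
fitting propagates between-replicate variability into the half-life
spread.

ddCq (Livak): ΔCq = Cq_target − Cq_ref, ΔΔCq subtracts the control-
condition mean ΔCq, expression = 2^(−ΔΔCq); the control mean maps to
exactly 1 by construction.

Spearman: mid-ranks for ties, then Pearson on ranks.  For n ≤ 9 the
two-sided p enumerates all n! permutations exactly; above that, the normal
approximation z = ρ√(n−1).  Constant vectors return NaN with a warning.
Group comparisons (t-tests, Mann–Whitney, log-rank) are deliberately left
to scipy/statsmodels/lifelines — they are standard machinery, not part of
this package's contribution.

## Numerical choices and degenerate inputs

* Fisher two-sided tie rule: probabilities within a 1e-7 relative epsilon
  of the observed table count as ties (scipy's convention).
* ES pseudocount (+1 to all four terms) triggers only when a·d = 0 or
  b·c = 0.
* Empty fragment sets, all-zero genes, empty peak lists, and empty p-value
  vectors all return well-defined empty/zero results rather than raising.
* Every stochastic path takes a seed or `numpy.random.Generator`;
  fixed-seed panels (seeds 1–5) back the recovery and null checks.

## Known limitations

* The peak caller consumes fragment BED intervals, not BAM; alignment and
  adapter handling are upstream.  BED12/GTF readers cover the exon/CDS
  subset of those formats used by gene-model annotations.
* One isoform per gene: isoform switching between conditions will
  misattribute coverage, as in any longest-isoform analysis.
* The Fisher test treats fragments as independent draws; overlapping
  windows share fragments, so neighboring windows' p-values are
  correlated.  BH across windows is the field's pragmatic choice, not an
  exact error-rate guarantee at peak level.
* Triage requires pre-harmonized gene symbols across species.
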