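"""Window-based m6A peak calling from IP/input fragment coverage.

The procedure, on each gene's analysis isoform:

1. Slide a 100-nt window in 10-nt steps along the spliced transcript and
   count IP and input fragments overlapping each window by >= 1 nt.
2. Exclude windows whose counts fall below 1/20 of the gene's top window in
   BOTH libraries (guards against annotation/isoform inaccuracies).
3. Normalize counts by the gene's median window count per library and form
   the enrichment score ES = (a*d)/(b*c), with a/c the window IP/input
   counts and b/d the gene median IP/input counts.
4. Test each window with a two-sided Fisher exact test of the window
   against the rest of the gene (IP vs input), adjust p-values with
   Benjamini-Hochberg across all retained windows transcriptome-wide, and
   flag windows with FDR < 0.01 and log2(ES) >= 1 as positive.
5. Merge overlapping positive windows into peaks, recompute the merged
   interval's ES with the same four-number formula, and project peaks back
   to genome coordinates.

Condition comparison (`unique_peaks`) and the 5'UTR/CDS/3'UTR metagene
profile (`metagene_distribution`) operate on the called peaks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import hypergeom

from .annotation import GeneModel, fragments_to_isoform
from .exceptions import InputError

log = logging.getLogger(__name__)

WINDOW_COLUMNS = [
    "gene_id", "start", "end", "ip_count", "input_count", "retained",
    "ip_median", "input_median", "norm_ip", "norm_input",
    "es", "log2_es", "p", "fdr", "positive",
]


# ---------------------------------------------------------------------- #
# window grid and counting
# ---------------------------------------------------------------------- #
def window_grid(mrna_length: int, window: int = 100, step: int = 10) -> np.ndarray:
    """Sliding-window starts/ends over [0, mrna_length).

    Windows start at 0, step, 2*step, ... while start + window <= length; if
    the grid does not reach the transcript 3' end, one extra right-anchored
    window ending at mrna_length is appended.  Transcripts shorter than the
    window get a single full-length window.
    """
    if mrna_length <= 0:
        raise ValueError("mrna_length must be positive")
    if mrna_length < window:
        return np.array([[0, mrna_length]], dtype=np.int64)
    n = (mrna_length - window) // step + 1
    starts = np.arange(n, dtype=np.int64) * step
    if starts[-1] + window < mrna_length:
        starts = np.append(starts, mrna_length - window)
    return np.column_stack([starts, starts + window])


def count_in_windows(
    intervals: np.ndarray, grid: np.ndarray, rule: str = "overlap"
) -> np.ndarray:
    """Count fragments assigned to each window.

    ``intervals`` is (n, 2) half-open; ``grid`` is (m, 2).  Under the
    default ``rule="overlap"`` an interval [s, e) counts in window
    [ws, we) iff s < we and e > ws (>= 1-nt overlap); ``rule="midpoint"``
    counts a fragment only in windows containing its midpoint.
    """
    if intervals.shape[0] == 0:
        return np.zeros(grid.shape[0], dtype=np.int64)
    if rule == "midpoint":
        mids = np.sort((intervals[:, 0] + intervals[:, 1]) // 2)
        before = np.searchsorted(mids, grid[:, 0], side="left")
        upto = np.searchsorted(mids, grid[:, 1], side="left")
        return upto - before
    if rule != "overlap":
        raise ValueError(f"unknown counting rule {rule!r}")
    starts = np.sort(intervals[:, 0])
    ends = np.sort(intervals[:, 1])
    n = starts.size
    # overlapping = n - (#ends <= ws) - (#starts >= we)
    ends_before = np.searchsorted(ends, grid[:, 0], side="right")
    starts_after = n - np.searchsorted(starts, grid[:, 1], side="left")
    return n - ends_before - starts_after


def count_windows(
    model: GeneModel,
    ip_intervals: np.ndarray,
    input_intervals: np.ndarray,
    window: int = 100,
    step: int = 10,
    count_rule: str = "overlap",
) -> pd.DataFrame:
    """Per-window raw IP/input fragment counts for one gene (counts only)."""
    grid = window_grid(model.mrna_length, window, step)
    return pd.DataFrame(
        {
            "gene_id": model.gene_id,
            "start": grid[:, 0],
            "end": grid[:, 1],
            "ip_count": count_in_windows(ip_intervals, grid, count_rule),
            "input_count": count_in_windows(input_intervals, grid, count_rule),
        }
    )


def filter_low_windows(records: pd.DataFrame, min_frac: float = 0.05) -> pd.DataFrame:
    """Flag windows below ``min_frac`` of the gene's top window in BOTH libraries.

    A window is excluded iff ip_count < min_frac * max(ip_count) AND
    input_count < min_frac * max(input_count), per gene.  Genes with zero
    counts in both libraries have every window excluded.  Excluded windows
    take no part in normalization medians, testing, or FDR multiplicity.
    """
    out = records.copy()
    max_ip = out.groupby("gene_id")["ip_count"].transform("max")
    max_input = out.groupby("gene_id")["input_count"].transform("max")
    low = (out["ip_count"] < min_frac * max_ip) & (
        out["input_count"] < min_frac * max_input
    )
    all_zero = (max_ip == 0) & (max_input == 0)
    out["retained"] = ~(low | all_zero)
    return out


def normalize_by_gene_median(records: pd.DataFrame) -> pd.DataFrame:
    """Attach gene-median counts (retained windows only) and normalized counts.

    The median of an even number of windows is the mean of the middle pair.
    A zero median is handled by the +1 pseudocount rule so normalized values
    stay finite.
    """
    out = records.copy()
    retained = out[out["retained"]]
    med = retained.groupby("gene_id")[["ip_count", "input_count"]].median()
    med.columns = ["ip_median", "input_median"]
    out = out.merge(med, on="gene_id", how="left")
    out[["ip_median", "input_median"]] = out[["ip_median", "input_median"]].fillna(0.0)
    b = out["ip_median"].to_numpy(float)
    d = out["input_median"].to_numpy(float)
    a = out["ip_count"].to_numpy(float)
    c = out["input_count"].to_numpy(float)
    out["norm_ip"] = np.where(b > 0, a / np.where(b > 0, b, 1.0), (a + 1.0) / (b + 1.0))
    out["norm_input"] = np.where(d > 0, c / np.where(d > 0, d, 1.0), (c + 1.0) / (d + 1.0))
    return out


# ---------------------------------------------------------------------- #
# enrichment score and tests
# ---------------------------------------------------------------------- #
def enrichment_score(a, b, c, d):
    """ES = (a*d)/(b*c) with a +1-to-all-terms pseudocount when a product is 0.

    a, c: window IP/input counts; b, d: gene-median IP/input window counts.
    Accepts scalars or arrays; negative input raises ValueError.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(a < 0) or np.any(b < 0) or np.any(c < 0) or np.any(d < 0):
        raise ValueError("enrichment_score: counts must be non-negative")
    degenerate = (a * d == 0) | (b * c == 0)
    num = np.where(degenerate, (a + 1) * (d + 1), a * d)
    den = np.where(degenerate, (b + 1) * (c + 1), b * c)
    es = num / den
    return float(es) if es.ndim == 0 else es


def fisher_window_test(a, A, c, C):
    """Two-sided Fisher exact p for the table [[a, A-a], [c, C-c]].

    a/c are the window IP/input counts and A/C the gene's total IP/input
    counts, so the test compares the window against the rest of the gene,
    IP vs input.  Accepts scalars or equal-length arrays (A, C may be
    scalars); two-sided p sums hypergeometric probabilities <= the observed
    table's, the same rule `scipy.stats.fisher_exact` applies.  A = C = 0
    returns p = 1 by convention.
    """
    scalar = np.ndim(a) == 0
    a = np.atleast_1d(np.asarray(a, dtype=np.int64))
    c = np.atleast_1d(np.asarray(c, dtype=np.int64))
    A = np.broadcast_to(np.asarray(A, dtype=np.int64), a.shape)
    C = np.broadcast_to(np.asarray(C, dtype=np.int64), a.shape)
    if np.any(a > A) or np.any(c > C) or np.any(a < 0) or np.any(c < 0):
        raise ValueError("fisher_window_test: require 0 <= a <= A and 0 <= c <= C")
    N = A + C          # grand total
    K = a + c          # column margin of the window column
    lo = np.maximum(0, K - C)
    hi = np.minimum(A, K)
    sizes = (hi - lo + 1).astype(np.int64)
    offsets = np.concatenate(([0], np.cumsum(sizes)))
    total = int(offsets[-1])
    # flat support: k values for every table, segment i at offsets[i]:offsets[i+1]
    k_flat = np.arange(total, dtype=np.int64) - np.repeat(offsets[:-1], sizes) + np.repeat(lo, sizes)
    with np.errstate(divide="ignore"):
        logpmf = hypergeom.logpmf(
            k_flat, np.repeat(N, sizes), np.repeat(K, sizes), np.repeat(A, sizes)
        )
    obs_log = logpmf[offsets[:-1] + (a - lo)]
    # two-sided: sum pmf(k) over k with pmf(k) <= pmf(a) * (1 + eps)
    keep = logpmf <= np.repeat(obs_log, sizes) + 1e-7
    seg = np.zeros(total, dtype=np.float64)
    seg[keep] = np.exp(logpmf[keep])
    p = np.add.reduceat(seg, offsets[:-1])
    p = np.minimum(p, 1.0)
    p[(A == 0) & (C == 0)] = 1.0
    return float(p[0]) if scalar else p


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return stats.false_discovery_control(p, method="bh")


# ---------------------------------------------------------------------- #
# peak assembly
# ---------------------------------------------------------------------- #
@dataclass
class PeakCallParams:
    """Tunable thresholds of the peak caller (defaults: the study's values)."""

    window: int = 100
    step: int = 10
    min_frac: float = 0.05          # the 1/20 low-count filter
    fdr_threshold: float = 0.01
    log2es_threshold: float = 1.0
    fragment_length: int = 150
    stranded: bool = True
    fisher_table: str = "gene-totals"   # or "medians" (sensitivity variant)
    count_rule: str = "overlap"         # or "midpoint"

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "window", "step", "min_frac", "fdr_threshold", "log2es_threshold",
            "fragment_length", "stranded", "fisher_table", "count_rule")}


@dataclass
class PeakCallResult:
    """Windows table, peaks table and the parameters that produced them."""

    windows: pd.DataFrame
    peaks: pd.DataFrame
    params: PeakCallParams
    n_genes: int = 0
    notes: dict = field(default_factory=dict)


def _merge_runs(starts: np.ndarray, ends: np.ndarray) -> list[tuple[int, int, list[int]]]:
    """Merge intervals overlapping by >= 1 nt; returns (start, end, member idx)."""
    order = np.argsort(starts, kind="stable")
    merged: list[tuple[int, int, list[int]]] = []
    for i in order:
        s, e = int(starts[i]), int(ends[i])
        if merged and s < merged[-1][1]:
            ps, pe, members = merged[-1]
            merged[-1] = (ps, max(pe, e), members + [int(i)])
        else:
            merged.append((s, e, [int(i)]))
    return merged


def call_and_merge(
    records: pd.DataFrame,
    ip_intervals: dict[str, np.ndarray],
    input_intervals: dict[str, np.ndarray],
    models: dict[str, GeneModel],
    fdr_threshold: float = 0.01,
    log2es_threshold: float = 1.0,
    count_rule: str = "overlap",
) -> pd.DataFrame:
    """Merge overlapping positive windows into peaks.

    Positive windows (fdr < threshold AND log2 ES >= threshold) are merged
    per gene when their isoform intervals overlap by >= 1 nt.  Each peak's
    ES is recomputed on the merged interval with the same four-number
    formula (merged-interval counts vs gene medians); min_fdr is the minimum
    over constituent windows.  Genome intervals come from the gene model.
    """
    rec = records.copy()
    rec["positive"] = (
        rec["retained"]
        & (rec["fdr"] < fdr_threshold)
        & (rec["log2_es"] >= log2es_threshold)
    )
    rows = []
    for gene_id, sub in rec[rec["positive"]].groupby("gene_id", sort=True):
        model = models[gene_id]
        b = float(sub["ip_median"].iloc[0])
        d = float(sub["input_median"].iloc[0])
        ipi = ip_intervals.get(gene_id, np.empty((0, 2), dtype=np.int64))
        inpi = input_intervals.get(gene_id, np.empty((0, 2), dtype=np.int64))
        for s, e, members in _merge_runs(sub["start"].to_numpy(), sub["end"].to_numpy()):
            grid = np.array([[s, e]], dtype=np.int64)
            a = int(count_in_windows(ipi, grid, count_rule)[0])
            c = int(count_in_windows(inpi, grid, count_rule)[0])
            es = enrichment_score(a, b, c, d)
            blocks = model.project_to_genome(s, e)
            rows.append(
                {
                    "gene_id": gene_id,
                    "start": s,
                    "end": e,
                    "n_windows": len(members),
                    "ip_count": a,
                    "input_count": c,
                    "es": es,
                    "log2_es": float(np.log2(es)),
                    "min_fdr": float(sub["fdr"].to_numpy()[members].min()),
                    "chrom": model.chrom,
                    "strand": model.strand,
                    "genome_blocks": ";".join(f"{gs}-{ge}" for gs, ge in blocks),
                }
            )
    return pd.DataFrame(rows, columns=[
        "gene_id", "start", "end", "n_windows", "ip_count", "input_count",
        "es", "log2_es", "min_fdr", "chrom", "strand", "genome_blocks",
    ])


def call_peaks(
    models: dict[str, GeneModel],
    ip_fragments: pd.DataFrame,
    input_fragments: pd.DataFrame,
    params: PeakCallParams | None = None,
) -> PeakCallResult:
    """Run the full window pipeline over a transcriptome.

    ``models`` maps gene_id to the analysis isoform; fragment tables are as
    produced by :func:`m6acall.annotation.load_fragments_bed`.
    """
    params = params or PeakCallParams()
    window_frames = []
    ip_by_gene: dict[str, np.ndarray] = {}
    input_by_gene: dict[str, np.ndarray] = {}
    for gene_id in sorted(models):
        model = models[gene_id]
        ipi = fragments_to_isoform(model, ip_fragments, params.fragment_length, params.stranded)
        inpi = fragments_to_isoform(model, input_fragments, params.fragment_length, params.stranded)
        ip_by_gene[gene_id] = ipi
        input_by_gene[gene_id] = inpi
        window_frames.append(
            count_windows(model, ipi, inpi, params.window, params.step, params.count_rule)
        )
    records = pd.concat(window_frames, ignore_index=True)
    records = filter_low_windows(records, params.min_frac)
    records = normalize_by_gene_median(records)
    records["es"] = enrichment_score(
        records["ip_count"], records["ip_median"],
        records["input_count"], records["input_median"],
    )
    records["log2_es"] = np.log2(records["es"])
    # Fisher test per gene on retained windows
    records["p"] = np.nan
    for gene_id, sub in records.groupby("gene_id", sort=False):
        idx = sub.index[sub["retained"]]
        if idx.size == 0:
            continue
        a = records.loc[idx, "ip_count"].to_numpy(np.int64)
        c = records.loc[idx, "input_count"].to_numpy(np.int64)
        if params.fisher_table == "medians":
            b = np.rint(records.loc[idx, "ip_median"].to_numpy(float)).astype(np.int64)
            d = np.rint(records.loc[idx, "input_median"].to_numpy(float)).astype(np.int64)
            records.loc[idx, "p"] = fisher_window_test(a, a + b, c, c + d)
        else:
            A, C = _gene_totals(
                ip_by_gene[gene_id], input_by_gene[gene_id],
                records.loc[idx, ["start", "end"]].to_numpy(np.int64),
            )
            records.loc[idx, "p"] = fisher_window_test(a, A, c, C)
    retained_mask = records["retained"] & records["p"].notna()
    records["fdr"] = np.nan
    records.loc[retained_mask, "fdr"] = adjust_fdr(
        records.loc[retained_mask, "p"].to_numpy(float)
    )
    peaks = call_and_merge(
        records, ip_by_gene, input_by_gene, models,
        params.fdr_threshold, params.log2es_threshold, params.count_rule,
    )
    records["positive"] = (
        records["retained"]
        & (records["fdr"] < params.fdr_threshold)
        & (records["log2_es"] >= params.log2es_threshold)
    )
    return PeakCallResult(
        windows=records, peaks=peaks, params=params, n_genes=len(models)
    )


def _gene_totals(ip_intervals, input_intervals, retained_windows) -> tuple[int, int]:
    """Unique-fragment totals over the gene's retained windows."""
    def total(intervals):
        if intervals.shape[0] == 0 or retained_windows.shape[0] == 0:
            return 0
        # fragment overlaps any retained window?  windows tile the transcript,
        # so test against the union of retained windows
        runs = _merge_runs(retained_windows[:, 0], retained_windows[:, 1])
        hit = np.zeros(intervals.shape[0], dtype=bool)
        for s, e, _ in runs:
            hit |= (intervals[:, 0] < e) & (intervals[:, 1] > s)
        return int(hit.sum())

    return total(ip_intervals), total(input_intervals)


# ---------------------------------------------------------------------- #
# condition comparison and metagene profile
# ---------------------------------------------------------------------- #
def unique_peaks(
    peaks_a: pd.DataFrame,
    peaks_b: pd.DataFrame,
    models: dict[str, GeneModel] | None = None,
):
    """Split two peak sets into condition-unique and shared peaks.

    A peak is shared iff some peak on the same gene in the other set
    overlaps it by >= 1 nt in isoform coordinates.  Returns
    (unique_a, unique_b, shared) where ``shared`` stacks shared peaks from
    both sets with a ``peak_set`` column in {"a", "b"}.
    """
    if models is not None:
        known = set(models)
        for df, label in ((peaks_a, "a"), (peaks_b, "b")):
            missing = set(df["gene_id"]) - known
            if missing:
                raise InputError(
                    f"peak set {label} references genes absent from the annotation: "
                    + ", ".join(sorted(missing)[:5])
                )

    def shared_mask(df, other):
        other_by_gene = {g: s[["start", "end"]].to_numpy() for g, s in other.groupby("gene_id")}
        mask = np.zeros(len(df), dtype=bool)
        for i, (_, row) in enumerate(df.iterrows()):
            o = other_by_gene.get(row["gene_id"])
            if o is None:
                continue
            mask[i] = bool(np.any((o[:, 0] < row["end"]) & (o[:, 1] > row["start"])))
        return mask

    mask_a = shared_mask(peaks_a, peaks_b)
    mask_b = shared_mask(peaks_b, peaks_a)
    shared = pd.concat(
        [peaks_a[mask_a].assign(peak_set="a"), peaks_b[mask_b].assign(peak_set="b")],
        ignore_index=True,
    )
    return peaks_a[~mask_a].reset_index(drop=True), peaks_b[~mask_b].reset_index(drop=True), shared


def unique_peak_genes(unique_df: pd.DataFrame) -> list[str]:
    """Genes carrying at least one condition-unique peak."""
    return sorted(set(unique_df["gene_id"]))


def metagene_distribution(
    peaks: pd.DataFrame,
    models: dict[str, GeneModel],
    bins_per_region: tuple[int, int, int] = (30, 40, 30),
):
    """Density of peak midpoints over a normalized 5'UTR/CDS/3'UTR axis.

    Each coding-gene peak contributes its isoform midpoint, rescaled within
    its region to that region's bin block.  Returns (density, skipped) where
    ``density`` sums to 1 (all-zero with a warning if no coding peak exists)
    and ``skipped`` counts peaks on non-coding genes.
    """
    n5, nc, n3 = bins_per_region
    nbins = n5 + nc + n3
    counts = np.zeros(nbins, dtype=float)
    skipped = 0
    for _, row in peaks.iterrows():
        model = models.get(row["gene_id"])
        if model is None or not model.is_coding:
            skipped += 1
            continue
        mid = (row["start"] + row["end"]) / 2.0
        L, cs, ce = model.mrna_length, model.cds_start, model.cds_end
        if mid < cs:
            rel = mid / cs
            b = int(min(n5 - 1, rel * n5))
        elif mid < ce:
            rel = (mid - cs) / (ce - cs)
            b = n5 + int(min(nc - 1, rel * nc))
        else:
            rel = (mid - ce) / max(L - ce, 1)
            b = n5 + nc + int(min(n3 - 1, rel * n3))
        counts[b] += 1
    total = counts.sum()
    if total == 0:
        warnings.warn("metagene_distribution: no coding-gene peaks; density is all zero")
        return counts, skipped
    return counts / total, skipped
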