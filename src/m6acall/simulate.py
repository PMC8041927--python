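"""Synthetic MeRIP-seq data with known ground truth.

Generates multi-exon gene models, paired IP/input fragment libraries with
planted enriched windows, DEG-style evidence tables with planted concordant
genes, and exponential-decay time courses — so every downstream stage of
the pipeline can be exercised and scored without external downloads.

Generative model for fragment coverage
--------------------------------------
Each transcript is divided into 100-nt tiles.  A Gamma(dispersion,
1/dispersion) rate multiplier (mean 1) is drawn per tile and SHARED between
the IP and input libraries: marginally each tile's input count is negative
binomial with mean ``background_mean`` (per 100 nt of fragment 5' starts)
and the given dispersion, while the IP:input rate ratio within a tile is
exactly ``library_ratio`` outside planted intervals and ``library_ratio *
planted_enrichment`` inside them.  Sharing the multiplier mimics
transcript-abundance and mappability bumps that affect both libraries of a
paired MeRIP experiment alike, and it preserves a clean null when
``planted_enrichment == 1``.  Fragment 5' starts are sampled in isoform
space and projected to the genome, so splice junctions are exercised
automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, write_fragments_bed6, write_gene_models_bed12
from .exceptions import ConfigError
from .quant import DecaySeries

TRIAGE_LABELS = (
    "unique_m6a",
    "rnaseq_ast_vs_control",
    "rnaseq_mouse_cuSCC",
    "rnaseq_human_cuSCC",
)


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the package's study conditions.

    ``background_mean`` is the expected number of fragment 5' starts per
    100 nt of transcript in the input library; ``dispersion`` is the
    negative-binomial size parameter r (variance = mu + mu^2/r).
    """

    seed: int = 1
    n_genes: int = 50
    exon_count_range: tuple[int, int] = (1, 6)
    mrna_length_range: tuple[int, int] = (800, 3000)
    background_mean: float = 50.0
    dispersion: float = 10.0
    peak_width: int = 150
    planted_enrichment: float = 8.0
    peaks_per_gene: int = 1
    fragment_length: int = 150
    library_ratio: float = 1.0
    shared_down: int = 10
    shared_up: int = 3
    utr_cds_split: tuple[float, float, float] = (0.10, 0.60, 0.30)

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.exon_count_range[0] < 1 or self.exon_count_range[0] > self.exon_count_range[1]:
            raise ConfigError("exon_count_range must be an increasing range >= 1")
        lo, hi = self.mrna_length_range
        if lo <= 0 or lo > hi:
            raise ConfigError("mrna_length_range must be an increasing positive range")
        for name in ("background_mean", "dispersion", "peak_width",
                     "planted_enrichment", "fragment_length", "library_ratio"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.planted_enrichment < 1:
            raise ConfigError("planted_enrichment must be >= 1")
        if self.peaks_per_gene < 0:
            raise ConfigError("peaks_per_gene must be >= 0")
        if self.peaks_per_gene * self.peak_width > lo:
            raise ConfigError(
                f"peaks_per_gene * peak_width = {self.peaks_per_gene * self.peak_width} "
                f"exceeds the minimum transcript length {lo}"
            )
        if self.exon_count_range[1] > lo:
            raise ConfigError("more exons than nucleotides in the shortest transcript")
        if abs(sum(self.utr_cds_split) - 1.0) > 1e-9:
            raise ConfigError("utr_cds_split must sum to 1")
        if self.shared_down < 0 or self.shared_up < 0:
            raise ConfigError("planted shared gene counts must be >= 0")
        if self.shared_down + self.shared_up > self.n_genes:
            raise ConfigError("shared_down + shared_up exceeds n_genes")


@dataclass
class GroundTruth:
    """Planted signal: per-gene peak intervals and shared DEG gene sets."""

    peaks: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)
    shared_down: list[str] = field(default_factory=list)
    shared_up: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return sorted(self.peaks)


# ---------------------------------------------------------------------- #
# gene models
# ---------------------------------------------------------------------- #
def simulate_gene_models(config: SimulationConfig):
    """Random multi-exon gene models plus planted ground truth.

    Reproducible given ``config.seed``.  UTR/CDS boundaries follow the
    configured 5'UTR/CDS/3'UTR split (default 10%/60%/30%).  Planted peak
    intervals are non-overlapping and lie within [0, mrna_length).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    models: list[GeneModel] = []
    truth = GroundTruth()
    cursor = 1000
    for i in range(config.n_genes):
        gene_id = f"G{i:04d}"
        tx_id = f"T{i:04d}.1"
        L = int(rng.integers(config.mrna_length_range[0], config.mrna_length_range[1] + 1))
        n_exons = int(rng.integers(config.exon_count_range[0], config.exon_count_range[1] + 1))
        if n_exons > 1:
            cuts = np.sort(rng.choice(np.arange(1, L), size=n_exons - 1, replace=False))
            sizes = np.diff(np.concatenate(([0], cuts, [L])))
        else:
            sizes = np.array([L], dtype=np.int64)
        introns = rng.integers(60, 500, size=n_exons - 1) if n_exons > 1 else np.array([], dtype=np.int64)
        starts = np.empty(n_exons, dtype=np.int64)
        ends = np.empty(n_exons, dtype=np.int64)
        pos = cursor
        for j, size in enumerate(sizes):
            starts[j] = pos
            ends[j] = pos + int(size)
            pos = ends[j] + (int(introns[j]) if j < n_exons - 1 else 0)
        cursor = pos + 1000
        strand = "+" if rng.random() < 0.5 else "-"
        f5, fc, _ = config.utr_cds_split
        cds_start = int(round(f5 * L))
        cds_end = int(round((f5 + fc) * L))
        cds_start = max(0, min(cds_start, L - 2))
        cds_end = max(cds_start + 1, min(cds_end, L))
        models.append(GeneModel(gene_id, tx_id, "chrS", strand, starts, ends,
                                cds_start, cds_end))
        truth.peaks[gene_id] = _plant_peaks(rng, L, config)
    n_shared = config.shared_down + config.shared_up
    chosen = rng.choice(truth.genes, size=n_shared, replace=False)
    truth.shared_down = sorted(chosen[: config.shared_down])
    truth.shared_up = sorted(chosen[config.shared_down:])
    return models, truth


def _plant_peaks(rng, L, config) -> list[tuple[int, int, float]]:
    w = config.peak_width
    placed: list[tuple[int, int, float]] = []
    attempts = 0
    while len(placed) < config.peaks_per_gene and attempts < 1000:
        attempts += 1
        s = int(rng.integers(0, L - w + 1))
        if all(s + w <= ps or s >= pe for ps, pe, _ in placed):
            placed.append((s, s + w, config.planted_enrichment))
    if len(placed) < config.peaks_per_gene:
        raise ConfigError("could not place non-overlapping planted peaks")
    return sorted(placed)


# ---------------------------------------------------------------------- #
# fragments
# ---------------------------------------------------------------------- #
def simulate_fragments(models, truth: GroundTruth, config: SimulationConfig):
    """Paired IP and input fragment tables in genome coordinates.

    Returns (ip_df, input_df) in the schema of
    :func:`m6acall.annotation.load_fragments_bed` (chrom, start, end,
    strand, five_prime); the emitted genomic interval is the fragment's
    first exonic block from its 5' start.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    ip_rows, input_rows = [], []
    for model in models:
        L = model.mrna_length
        n_tiles = (L + 99) // 100
        g = rng.gamma(shape=config.dispersion, scale=1.0 / config.dispersion, size=n_tiles)
        per_nt = np.repeat(g, 100)[:L] * (config.background_mean / 100.0)
        enrich = np.ones(L)
        for s, e, fold in truth.peaks.get(model.gene_id, []):
            enrich[s:e] = fold
        w_input = per_nt
        w_ip = per_nt * config.library_ratio * enrich
        for weights, rows in ((w_ip, ip_rows), (w_input, input_rows)):
            tot = weights.sum()
            n = int(rng.poisson(tot))
            if n == 0:
                continue
            starts_iso = rng.choice(L, size=n, p=weights / tot)
            rows.extend(_iso_starts_to_genome(model, starts_iso, config.fragment_length))
    cols = ["chrom", "start", "end", "strand"]
    ip_df = pd.DataFrame(ip_rows, columns=cols)
    input_df = pd.DataFrame(input_rows, columns=cols)
    for df in (ip_df, input_df):
        df["five_prime"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return ip_df, input_df


def _iso_starts_to_genome(model: GeneModel, starts_iso, fragment_length):
    """Map isoform 5' starts to first-block genomic footprints."""
    rows = []
    for t in np.sort(starts_iso):
        end_iso = min(int(t) + fragment_length, model.mrna_length)
        blocks = model.project_to_genome(int(t), end_iso)
        if model.strand == "+":
            s, e = blocks[0]
        else:
            s, e = blocks[-1]  # 5'-most block of a minus-strand fragment
        rows.append((model.chrom, int(s), int(e), model.strand))
    return rows


# ---------------------------------------------------------------------- #
# DEG evidence tables
# ---------------------------------------------------------------------- #
def simulate_deg_tables(truth: GroundTruth, config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Four evidence tables in which exactly the planted genes pass all cutoffs.

    Emits three DEG-style tables (gene, effect, p where applicable) and one
    unique-peak gene list.  Planted shared genes pass every table with a
    concordant direction; every non-planted gene is constructed to fail at
    least one table's cutoff.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    genes = truth.genes
    planted = {g: -1 for g in truth.shared_down}
    planted.update({g: +1 for g in truth.shared_up})
    expr_labels = [lbl for lbl in TRIAGE_LABELS if lbl != "unique_m6a"]
    rows = {lbl: [] for lbl in expr_labels}
    unique_m6a: list[str] = []

    for g in genes:
        if g in planted:
            sign = planted[g]
            unique_m6a.append(g)
            for lbl in expr_labels:
                effect = sign * rng.uniform(0.8, 2.5)
                p = rng.uniform(1e-6, 0.04)
                rows[lbl].append((g, effect, p))
        else:
            # pick >= 1 table in which this gene fails its cutoff
            fail = set(rng.choice(4, size=int(rng.integers(1, 5)), replace=False))
            if 0 not in fail:
                unique_m6a.append(g)
            for k, lbl in enumerate(expr_labels, start=1):
                if k in fail:
                    if lbl != "rnaseq_ast_vs_control" and rng.random() < 0.5:
                        effect = rng.choice([-1, 1]) * rng.uniform(0.8, 2.5)
                        p = rng.uniform(0.06, 0.9)       # fails on p
                    else:
                        effect = rng.choice([-1, 1]) * rng.uniform(0.0, 0.5)
                        p = rng.uniform(1e-6, 0.04)      # fails on effect size
                else:
                    effect = rng.choice([-1, 1]) * rng.uniform(0.8, 2.5)
                    p = rng.uniform(1e-6, 0.04)
                rows[lbl].append((g, effect, p))

    tables = {
        "unique_m6a": pd.DataFrame({"gene": unique_m6a}),
        "rnaseq_ast_vs_control": pd.DataFrame(
            rows["rnaseq_ast_vs_control"], columns=["gene", "effect", "p"]
        )[["gene", "effect"]],
    }
    for lbl in ("rnaseq_mouse_cuSCC", "rnaseq_human_cuSCC"):
        tables[lbl] = pd.DataFrame(rows[lbl], columns=["gene", "effect", "p"])
    return tables


# ---------------------------------------------------------------------- #
# decay time courses
# ---------------------------------------------------------------------- #
DEFAULT_TIMEPOINTS = (0.0, 1.0, 2.0, 4.0, 8.0, 12.0)  # hours


def simulate_decay(
    t_half: float,
    timepoints=DEFAULT_TIMEPOINTS,
    cv: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    replicate: str = "rep1",
) -> DecaySeries:
    """Exponential decay y(t) = 2^(-t/t_half) with multiplicative lognormal noise.

    ``cv`` is the log-scale standard deviation of the noise (~ coefficient
    of variation for small cv).  The series is renormalized so y(0) = 1.
    """
    if t_half <= 0:
        raise ValueError("t_half must be positive")
    t = np.asarray(timepoints, dtype=float)
    if t[0] != 0:
        raise ValueError("timepoints must include 0 first")
    y = np.power(2.0, -t / t_half)
    if cv > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        y = y * np.exp(rng.normal(0.0, cv, size=t.size))
        y = y / y[0]
    return DecaySeries(t, y, replicate)


# ---------------------------------------------------------------------- #
# on-disk dataset
# ---------------------------------------------------------------------- #
def write_dataset(outdir, models, truth, ip_df, input_df, tables) -> dict[str, str]:
    """Write a complete simulated dataset (plain-text formats only).

    models.bed (BED12), ip.bed / input.bed (BED6), deg_<label>.tsv,
    truth_peaks.tsv and truth_genes.tsv sidecars.  Returns {name: path}.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _save(name, writer):
        p = outdir / name
        writer(p)
        paths[name] = str(p)

    _save("models.bed", lambda p: write_gene_models_bed12(models, p))
    _save("ip.bed", lambda p: write_fragments_bed6(ip_df, p))
    _save("input.bed", lambda p: write_fragments_bed6(input_df, p))
    for label, df in tables.items():
        _save(f"deg_{label}.tsv", lambda p, df=df: df.to_csv(p, sep="\t", index=False))
    peak_rows = [
        {"gene_id": g, "start": s, "end": e, "fold": f}
        for g, plist in sorted(truth.peaks.items())
        for s, e, f in plist
    ]
    _save("truth_peaks.tsv",
          lambda p: pd.DataFrame(peak_rows, columns=["gene_id", "start", "end", "fold"])
          .to_csv(p, sep="\t", index=False))
    gene_rows = [{"gene_id": g, "planted": "down"} for g in truth.shared_down] + [
        {"gene_id": g, "planted": "up"} for g in truth.shared_up
    ]
    _save("truth_genes.tsv",
          lambda p: pd.DataFrame(gene_rows, columns=["gene_id", "planted"])
          .to_csv(p, sep="\t", index=False))
    return paths


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
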