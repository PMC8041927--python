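"""Gene models and genome <-> transcript coordinate projection.

MeRIP/m6A-seq enrichment windows are defined on spliced-transcript
("isoform") coordinates so that a window never straddles an intron.  This
module reads gene models from BED12 or GTF, selects one analysis isoform
per gene (the longest mRNA), and provides exact bidirectional projection
between genome and isoform coordinates.

Conventions
-----------
* All coordinates are 0-based half-open internally.  GTF input (1-based,
  closed intervals) is converted on read; BED is native.
* Isoform coordinate 0 is the transcript 5' end: for minus-strand genes the
  isoform axis runs antiparallel to the genome axis.
* Sequencing libraries are assumed stranded (fr-firststrand); fragments on
  the strand opposite to the gene are discarded during projection unless
  ``stranded=False`` is requested.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import AnnotationError, InputError

log = logging.getLogger(__name__)

OUTSIDE = -1  # sentinel returned by project_to_isoform for non-exonic positions


@dataclass
class GeneModel:
    """One gene's chosen isoform: exon structure plus UTR/CDS boundaries.

    Exons are genome intervals, 0-based half-open, non-overlapping and
    sorted by genome position regardless of strand.  ``cds_start``/
    ``cds_end`` are isoform coordinates (None for non-coding transcripts).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exon_starts: np.ndarray
    exon_ends: np.ndarray
    cds_start: int | None = None
    cds_end: int | None = None
    # cumulative exonic length *before* each exon, in genome (plus-frame) order
    _cum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.exon_starts = np.asarray(self.exon_starts, dtype=np.int64)
        self.exon_ends = np.asarray(self.exon_ends, dtype=np.int64)
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.exon_starts.size == 0:
            raise AnnotationError(f"{self.transcript_id}: transcript has zero exons")
        if self.exon_starts.size != self.exon_ends.size:
            raise AnnotationError(f"{self.transcript_id}: exon start/end mismatch")
        lengths = self.exon_ends - self.exon_starts
        if np.any(lengths <= 0):
            raise AnnotationError(f"{self.transcript_id}: empty or inverted exon")
        if np.any(self.exon_starts[1:] < self.exon_ends[:-1]):
            raise AnnotationError(
                f"{self.transcript_id}: exons overlap or are unsorted"
            )
        self._cum = np.concatenate(([0], np.cumsum(lengths)))
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationError(
                f"{self.transcript_id}: cds_start/cds_end must both be set or absent"
            )
        if self.cds_start is not None:
            if not (0 <= self.cds_start < self.cds_end <= self.mrna_length):
                raise AnnotationError(
                    f"{self.transcript_id}: CDS [{self.cds_start},{self.cds_end}) "
                    f"outside [0,{self.mrna_length})"
                )

    @property
    def mrna_length(self) -> int:
        return int(self._cum[-1])

    @property
    def n_exons(self) -> int:
        return int(self.exon_starts.size)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint [start, end) of the transcript."""
        return int(self.exon_starts[0]), int(self.exon_ends[-1])

    # ------------------------------------------------------------------ #
    # projection
    # ------------------------------------------------------------------ #
    def exonic_offset(self, pos) -> np.ndarray:
        """Number of exonic nucleotides strictly before genome position(s)."""
        pos = np.asarray(pos, dtype=np.int64)
        idx = np.searchsorted(self.exon_starts, pos, side="right") - 1
        idx_c = np.clip(idx, 0, self.n_exons - 1)
        within = np.where(
            idx < 0,
            0,
            np.minimum(pos - self.exon_starts[idx_c], self.exon_ends[idx_c] - self.exon_starts[idx_c]),
        )
        return self._cum[np.maximum(idx, 0)] + np.where(idx < 0, 0, within)

    def project_to_isoform(self, pos):
        """Genome position(s) -> isoform coordinate(s); OUTSIDE (-1) if non-exonic.

        Isoform coordinates count from the transcript 5' end, so minus-strand
        models reverse the plus-frame offset.
        """
        pos_arr = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        idx = np.searchsorted(self.exon_starts, pos_arr, side="right") - 1
        idx_c = np.clip(idx, 0, self.n_exons - 1)
        inside = (idx >= 0) & (pos_arr < self.exon_ends[idx_c])
        plus = self._cum[idx_c] + (pos_arr - self.exon_starts[idx_c])
        iso = np.where(self.strand == "+", plus, self.mrna_length - 1 - plus)
        out = np.where(inside, iso, OUTSIDE).astype(np.int64)
        return int(out[0]) if np.isscalar(pos) or np.ndim(pos) == 0 else out

    def project_to_genome(self, start: int, end: int) -> list[tuple[int, int]]:
        """Isoform interval [start, end) -> ordered genome intervals.

        Returned blocks are ascending in genome coordinates; their union maps
        back exactly under :meth:`project_to_isoform` (round-trip identity).
        A zero-length interval yields an empty list.
        """
        if not (0 <= start <= end <= self.mrna_length):
            raise ValueError(
                f"isoform interval [{start},{end}) outside [0,{self.mrna_length}]"
            )
        if start == end:
            return []
        if self.strand == "-":
            start, end = self.mrna_length - end, self.mrna_length - start
        blocks: list[tuple[int, int]] = []
        # exons whose plus-frame isoform range intersects [start, end)
        first = int(np.searchsorted(self._cum, start, side="right") - 1)
        for i in range(first, self.n_exons):
            lo, hi = int(self._cum[i]), int(self._cum[i + 1])
            if lo >= end:
                break
            s = max(start, lo) - lo + int(self.exon_starts[i])
            e = min(end, hi) - lo + int(self.exon_starts[i])
            blocks.append((s, e))
        return blocks


# ---------------------------------------------------------------------- #
# fragments
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class FragmentInterval:
    """An aligned fragment represented by its strand-aware genomic 5' start.

    ``length`` is the extended fragment size (the library's average fragment
    size, 150 nt by default); extension happens in transcript space during
    projection so that fragments follow splice junctions.
    """

    chrom: str
    start: int  # genomic 5'-most base of the fragment (strand-aware)
    strand: str
    length: int = 150

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("fragment length must be positive")
        if self.start < 0:
            raise ValueError("fragment start must be non-negative")


def load_fragments_bed(path) -> pd.DataFrame:
    """Read aligned-fragment intervals from BED (>= 3 columns, strand in col 6).

    Returns a DataFrame with columns chrom, start, end, strand, five_prime,
    where five_prime is the strand-aware genomic 5' base (start for '+',
    end-1 for '-').  Missing strand defaults to '+'.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"fragment BED not found: {path}")
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{ln}: BED line has fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise InputError(f"{path}:{ln}: non-integer coordinates") from exc
            strand = fields[5] if len(fields) >= 6 else "+"
            rows.append((fields[0], start, end, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    df["five_prime"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return df


def fragments_to_isoform(
    model: GeneModel,
    fragments: pd.DataFrame,
    fragment_length: int = 150,
    stranded: bool = True,
) -> np.ndarray:
    """Project fragments onto a gene's isoform axis.

    Each fragment's strand-aware 5' genomic base is projected; fragments with
    intronic or off-transcript 5' ends are dropped, as are fragments on the
    opposite strand when ``stranded``.  The result is an (n, 2) array of
    isoform intervals [t, min(t + fragment_length, mrna_length)).
    """
    sel = fragments["chrom"].to_numpy() == model.chrom
    if stranded:
        sel &= fragments["strand"].to_numpy() == model.strand
    five = fragments.loc[sel, "five_prime"].to_numpy(dtype=np.int64)
    if five.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    iso = model.project_to_isoform(five)
    iso = np.atleast_1d(iso)
    iso = iso[iso != OUTSIDE]
    starts = iso
    ends = np.minimum(iso + fragment_length, model.mrna_length)
    return np.column_stack([starts, ends])


# ---------------------------------------------------------------------- #
# readers
# ---------------------------------------------------------------------- #
def load_gene_models(path, dialect: str | None = None) -> list[GeneModel]:
    """Read gene models from BED12 or GTF.

    ``dialect`` is "bed12" or "gtf"; if None it is inferred from the file
    extension.  One GeneModel per transcript; duplicate transcript ids raise
    :class:`AnnotationError` naming the id.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    if dialect is None:
        suffix = path.suffix.lower()
        dialect = "gtf" if suffix in (".gtf", ".gff") else "bed12"
    if dialect == "bed12":
        models = _read_bed12(path)
    elif dialect == "gtf":
        models = _read_gtf(path)
    else:
        raise ValueError(f"unknown annotation dialect: {dialect!r}")
    seen: dict[str, int] = {}
    for m in models:
        if m.transcript_id in seen:
            raise AnnotationError(
                f"duplicate transcript_id {m.transcript_id!r} in {path}"
            )
        seen[m.transcript_id] = 1
    return models


def _split_name(name: str) -> tuple[str, str]:
    """BED12 name field: 'transcript|gene' or a bare id used for both."""
    if "|" in name:
        tx, gene = name.split("|", 1)
        return tx, gene
    return name, name


def _read_bed12(path: Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise AnnotationError(f"{path}:{ln}: BED12 line has {len(f)} columns (< 12)")
            try:
                chrom_start = int(f[1])
                thick_start, thick_end = int(f[6]), int(f[7])
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{ln}: malformed numeric field") from exc
            if n_blocks == 0 or len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise AnnotationError(
                    f"{path}:{ln}: blockCount={n_blocks} inconsistent with block lists"
                )
            starts = chrom_start + np.asarray(offsets, dtype=np.int64)
            ends = starts + np.asarray(sizes, dtype=np.int64)
            tx, gene = _split_name(f[3])
            strand = f[5]
            cds_start = cds_end = None
            if thick_end > thick_start:
                cds_start, cds_end = _genome_cds_to_isoform(
                    starts, ends, strand, thick_start, thick_end
                )
            try:
                models.append(
                    GeneModel(gene, tx, f[0], strand, starts, ends, cds_start, cds_end)
                )
            except AnnotationError as exc:
                raise AnnotationError(f"{path}:{ln}: {exc}") from exc
    return models


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _read_gtf(path: Path) -> list[GeneModel]:
    exons: dict[str, dict] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise AnnotationError(f"{path}:{ln}: GTF line has {len(f)} columns (< 9)")
            feature = f[2]
            if feature not in ("exon", "CDS"):
                continue
            try:
                # GTF is 1-based closed; convert to 0-based half-open
                start, end = int(f[3]) - 1, int(f[4])
            except ValueError as exc:
                raise AnnotationError(f"{path}:{ln}: non-integer coordinates") from exc
            attrs = dict(_GTF_ATTR.findall(f[8]))
            if "transcript_id" not in attrs:
                raise AnnotationError(f"{path}:{ln}: missing transcript_id attribute")
            tx = attrs["transcript_id"]
            if feature == "exon":
                rec = exons.setdefault(
                    tx,
                    {
                        "gene": attrs.get("gene_id", tx),
                        "chrom": f[0],
                        "strand": f[6],
                        "blocks": [],
                        "line": ln,
                    },
                )
                if rec["chrom"] != f[0] or rec["strand"] != f[6]:
                    raise AnnotationError(
                        f"{path}:{ln}: transcript {tx!r} spans chromosomes/strands"
                    )
                rec["blocks"].append((start, end))
            else:
                cds.setdefault(tx, []).append((start, end))
    models = []
    for tx, rec in exons.items():
        blocks = sorted(rec["blocks"])
        starts = np.asarray([b[0] for b in blocks], dtype=np.int64)
        ends = np.asarray([b[1] for b in blocks], dtype=np.int64)
        cds_start = cds_end = None
        if tx in cds:
            g_lo = min(s for s, _ in cds[tx])
            g_hi = max(e for _, e in cds[tx])
            cds_start, cds_end = _genome_cds_to_isoform(
                starts, ends, rec["strand"], g_lo, g_hi
            )
        try:
            models.append(
                GeneModel(rec["gene"], tx, rec["chrom"], rec["strand"], starts, ends,
                          cds_start, cds_end)
            )
        except AnnotationError as exc:
            raise AnnotationError(f"{path}:{rec['line']}: {exc}") from exc
    return models


def _genome_cds_to_isoform(starts, ends, strand, g_lo, g_hi):
    """Convert a genomic CDS span to isoform [cds_start, cds_end)."""
    cum = np.concatenate(([0], np.cumsum(ends - starts)))
    total = int(cum[-1])

    def offset(g):
        idx = int(np.searchsorted(starts, g, side="right") - 1)
        if idx < 0:
            return 0
        return int(cum[idx] + min(g - starts[idx], ends[idx] - starts[idx]))

    lo, hi = offset(g_lo), offset(g_hi)
    if strand == "-":
        lo, hi = total - hi, total - lo
    if hi <= lo:
        return None, None
    return lo, hi


def select_longest_isoform(models) -> dict[str, GeneModel]:
    """Pick one analysis isoform per gene: the longest mRNA.

    Length ties break to the lexicographically smallest transcript_id and
    are logged, so builds are deterministic.
    """
    models = list(models)
    if not models:
        raise ValueError("select_longest_isoform: empty model set")
    best: dict[str, GeneModel] = {}
    for m in sorted(models, key=lambda m: (m.gene_id, -m.mrna_length, m.transcript_id)):
        if m.gene_id not in best:
            best[m.gene_id] = m
        elif m.mrna_length == best[m.gene_id].mrna_length:
            log.info(
                "gene %s: isoform length tie (%d nt), kept %s over %s",
                m.gene_id, m.mrna_length, best[m.gene_id].transcript_id, m.transcript_id,
            )
    return best


# ---------------------------------------------------------------------- #
# writers (BED12 for models, BED6 for fragments) — used by the simulator
# ---------------------------------------------------------------------- #
def write_gene_models_bed12(models, path) -> None:
    with open(path, "w") as fh:
        for m in models:
            start, end = m.span
            if m.is_coding:
                blocks = m.project_to_genome(m.cds_start, m.cds_end)
                thick_start, thick_end = blocks[0][0], blocks[-1][1]
            else:
                thick_start = thick_end = start
            sizes = ",".join(str(int(e - s)) for s, e in zip(m.exon_starts, m.exon_ends))
            offs = ",".join(str(int(s - start)) for s in m.exon_starts)
            fh.write(
                "\t".join(
                    [
                        m.chrom, str(start), str(end),
                        f"{m.transcript_id}|{m.gene_id}", "0", m.strand,
                        str(thick_start), str(thick_end), "0",
                        str(m.n_exons), sizes, offs,
                    ]
                )
                + "\n"
            )


def write_fragments_bed6(fragments: pd.DataFrame, path) -> None:
    """Write fragments as BED6.

    The emitted interval is the fragment's first genomic block (the aligned
    read footprint); only the strand-aware 5' coordinate is meaningful to the
    pipeline reader.
    """
    cols = ["chrom", "start", "end"]
    df = fragments.copy()
    df["name"] = [f"frag{i}" for i in range(len(df))]
    df["score"] = 0
    df[cols + ["name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )
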