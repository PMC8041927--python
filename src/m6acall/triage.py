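"""Four-dataset target triage: cutoffs, intersection, direction calls.

Candidate m6A target genes are nominated by intersecting four evidence
sets: genes with a condition-unique m6A peak, and three differential-
expression tables (tumorigenic-vs-control cells, mouse cuSCC-vs-chronic
skin, human cuSCC-vs-normal skin).  Cutoffs per table:

* ``unique_m6a`` — membership as given (no effect/p rule);
* ``rnaseq_ast_vs_control`` — |log2 TPM difference| > 0.5, no p rule;
* ``rnaseq_mouse_cuSCC`` / ``rnaseq_human_cuSCC`` — p < 0.05 AND
  |log2 fold change| > 0.5.

All inequalities are strict.  p is the adjusted p-value the upstream DEG
tool provides; no re-adjustment happens here.  Gene symbols are matched
case-insensitively after whitespace stripping; cross-species symbol
harmonization is the caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .exceptions import InputError

LABELS = (
    "unique_m6a",
    "rnaseq_ast_vs_control",
    "rnaseq_mouse_cuSCC",
    "rnaseq_human_cuSCC",
)
EXPRESSION_LABELS = LABELS[1:]
_P_REQUIRED = {"rnaseq_mouse_cuSCC", "rnaseq_human_cuSCC"}


@dataclass
class EvidenceTable:
    """One labeled evidence table: gene, effect (log2), optional p."""

    label: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise InputError(
                f"unknown evidence label {self.label!r}; expected one of {LABELS}"
            )
        df = self.data.copy()
        if "gene" not in df.columns:
            raise InputError(f"table {self.label!r}: missing 'gene' column")
        df["gene"] = df["gene"].astype(str).str.strip().str.upper()
        if df["gene"].duplicated().any():
            dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
            raise InputError(f"table {self.label!r}: duplicate gene_id {dup!r}")
        if self.label != "unique_m6a":
            if "effect" not in df.columns:
                raise InputError(f"table {self.label!r}: missing 'effect' column")
            if not df["effect"].map(lambda v: v == v and abs(v) != float("inf")).all():
                raise InputError(f"table {self.label!r}: non-finite effect")
        if self.label in _P_REQUIRED and "p" not in df.columns:
            raise InputError(f"table {self.label!r}: missing required 'p' column")
        self.data = df


def apply_cutoffs(
    table: EvidenceTable, effect_cutoff: float = 0.5, p_cutoff: float = 0.05
) -> dict[str, int]:
    """Genes passing the table's cutoff, mapped to direction (+1/-1, 0 for
    the membership-only unique-peak list).  Strict inequalities throughout."""
    df = table.data
    if table.label == "unique_m6a":
        return {g: 0 for g in df["gene"]}
    if table.label == "rnaseq_ast_vs_control":
        passing = df[df["effect"].abs() > effect_cutoff]
    else:
        passing = df[(df["p"] < p_cutoff) & (df["effect"].abs() > effect_cutoff)]
    return {
        row.gene: (1 if row.effect > 0 else -1) for row in passing.itertuples()
    }


def intersect_four(
    tables: list[EvidenceTable], effect_cutoff: float = 0.5, p_cutoff: float = 0.05
) -> pd.DataFrame:
    """TriageResult: per-gene membership across the four sets and the call.

    A gene is called shared_up/shared_down when it is a member of all four
    sets and the three expression directions agree; members of all four with
    discordant directions are kept with call = "discordant".  Everything
    else gets call = "none".  The result is invariant to table input order.
    """
    labels = [t.label for t in tables]
    if len(tables) != 4 or set(labels) != set(LABELS):
        dup = [l for l in labels if labels.count(l) > 1]
        if dup:
            raise InputError(f"duplicate table label {dup[0]!r}")
        raise InputError(f"need exactly the four labels {LABELS}, got {labels}")
    passing = {t.label: apply_cutoffs(t, effect_cutoff, p_cutoff) for t in tables}
    all_genes = sorted(set().union(*[set(p) for p in passing.values()]))
    rows = []
    for g in all_genes:
        member = {lbl: g in passing[lbl] for lbl in LABELS}
        dirs = {lbl: passing[lbl].get(g) for lbl in EXPRESSION_LABELS}
        if all(member.values()):
            uniq = {d for d in dirs.values()}
            if uniq == {1}:
                call = "shared_up"
            elif uniq == {-1}:
                call = "shared_down"
            else:
                call = "discordant"
        else:
            call = "none"
        rows.append({
            "gene": g,
            **{f"in_{lbl}": member[lbl] for lbl in LABELS},
            **{f"dir_{lbl}": dirs[lbl] for lbl in EXPRESSION_LABELS},
            "call": call,
        })
    return pd.DataFrame(rows)


def shared_genes(result: pd.DataFrame) -> tuple[list[str], list[str]]:
    """(shared_down genes, shared_up genes) from a triage result."""
    down = sorted(result.loc[result["call"] == "shared_down", "gene"])
    up = sorted(result.loc[result["call"] == "shared_up", "gene"])
    return down, up


def venn_counts(tables: list[EvidenceTable]) -> pd.DataFrame:
    """Counts of all 15 non-empty membership regions of the 4-set Venn diagram."""
    passing = {t.label: set(apply_cutoffs(t)) for t in tables}
    rows = []
    for r in range(1, 5):
        for combo in combinations(LABELS, r):
            inside = set.intersection(*[passing[l] for l in combo])
            outside = set().union(*[passing[l] for l in LABELS if l not in combo]) if r < 4 else set()
            rows.append({
                "region": "&".join(combo),
                "n_exclusive": len(inside - outside),
                "n_total": len(inside),
            })
    return pd.DataFrame(rows)


def load_evidence_table(label: str, path) -> EvidenceTable:
    """Read one evidence TSV (columns gene[, effect[, p]])."""
    try:
        df = pd.read_csv(path, sep="\t")
    except FileNotFoundError as exc:
        raise InputError(f"evidence table not found: {path}") from exc
    return EvidenceTable(label, df)
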