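"""Summary artifacts: consequence-class tallies of significant SNPs,
Manhattan-plot data export, and per-gene hit lists.

Functional annotation is consumed, never computed: callers supply a TSV of
per-SNP consequence classes (intron / intergenic / regulatory / coding /
other, with a coding subclass of synonymous / missense / other) such as a
collapsed Variant Effect Predictor output. Percentages follow the two-level
convention used for reporting WGS association results: class percentages
over all significant annotated SNPs, subclass percentages over coding SNPs
only, both to two decimals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AssociationResult

CONSEQUENCE_CLASSES = ("intron", "intergenic", "regulatory", "coding", "other")
CODING_SUBCLASSES = ("synonymous", "missense", "other")

ANNOTATION_COLUMNS = [
    "snp_id", "consequence_class", "coding_subclass", "gene_id", "gene_name",
]


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str).fillna("n/a")
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns: {sorted(missing)}")
    return ann


def validate_annotation(ann: pd.DataFrame) -> None:
    if ann["snp_id"].duplicated().any():
        raise ValueError("duplicate snp_id in annotation table")
    bad = set(ann["consequence_class"]) - set(CONSEQUENCE_CLASSES)
    if bad:
        raise ValueError(f"unknown consequence class(es): {sorted(bad)}")
    coding = ann["consequence_class"] == "coding"
    if (ann.loc[coding, "coding_subclass"] == "n/a").any():
        raise ValueError("coding SNPs must carry a coding subclass")
    if (ann.loc[~coding, "coding_subclass"] != "n/a").any():
        raise ValueError("non-coding SNPs must have coding_subclass 'n/a'")


@dataclass
class ConsequenceSummary:
    class_counts: pd.Series  # indexed by consequence class (+ 'unannotated')
    class_percent: pd.Series
    subclass_counts: pd.Series  # among coding SNPs
    subclass_percent: pd.Series
    n_significant: int


def consequence_summary(
    result: AssociationResult, ann: pd.DataFrame
) -> ConsequenceSummary:
    """Tally consequence classes among Bonferroni-significant SNPs.

    Significant SNPs absent from the annotation are reported under the
    ``unannotated`` class. Percentages are over annotated significant SNPs
    at the class level and over coding SNPs at the subclass level.
    """
    validate_annotation(ann)
    sig = result.table.loc[result.table["significant"], ["snp_id"]]
    if sig.empty:
        warnings.warn("no significant SNPs: consequence summary is empty")
        empty = pd.Series(dtype=int)
        return ConsequenceSummary(empty, pd.Series(dtype=float), empty,
                                  pd.Series(dtype=float), 0)
    merged = sig.merge(ann, on="snp_id", how="left")
    annotated = merged["consequence_class"].notna()
    class_counts = (
        merged.loc[annotated, "consequence_class"].value_counts().sort_index()
    )
    n_unann = int((~annotated).sum())
    if n_unann:
        class_counts = pd.concat(
            [class_counts, pd.Series({"unannotated": n_unann})]
        )
    denom = class_counts.drop("unannotated", errors="ignore").sum()
    if denom > 0:
        class_percent = (
            class_counts.drop("unannotated", errors="ignore") / denom * 100.0
        ).round(2)
    else:
        class_percent = pd.Series({"unannotated": 100.0})
    coding = merged.loc[
        annotated & (merged["consequence_class"] == "coding"), "coding_subclass"
    ]
    subclass_counts = coding.value_counts().sort_index()
    subclass_percent = (
        (subclass_counts / subclass_counts.sum() * 100.0).round(2)
        if len(coding)
        else pd.Series(dtype=float)
    )
    return ConsequenceSummary(
        class_counts=class_counts,
        class_percent=class_percent,
        subclass_counts=subclass_counts,
        subclass_percent=subclass_percent,
        n_significant=int(len(sig)),
    )


def manhattan_export(
    result: AssociationResult, ann: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Plot-ready table: (chrom, pos, -log10 p, cumulative genome coordinate,
    significance flag, and an exon/coding flag when annotation is given).

    Chromosomes are laid end to end in their sorted order (numeric where
    possible); rows are ordered by (chrom, pos).
    """
    if result.table.empty:
        raise ValueError("empty association result")
    tab = result.table.copy()

    def _chrom_key(c: str):
        s = str(c).removeprefix("chr")
        return (0, int(s)) if s.isdigit() else (1, s)

    chroms = sorted(tab["chrom"].unique(), key=_chrom_key)
    tab["__ck"] = tab["chrom"].map({c: i for i, c in enumerate(chroms)})
    tab = tab.sort_values(["__ck", "pos"], kind="mergesort").reset_index(drop=True)
    offsets = {}
    running = 0
    for c in chroms:
        offsets[c] = running
        running += int(tab.loc[tab["chrom"] == c, "pos"].max())
    tab["cum_pos"] = tab["pos"] + tab["chrom"].map(offsets)
    tab["neg_log10_p"] = -np.log10(tab["p"])
    out_cols = ["snp_id", "chrom", "pos", "cum_pos", "neg_log10_p", "significant"]
    if ann is not None:
        coding_ids = set(ann.loc[ann["consequence_class"] == "coding", "snp_id"])
        tab["exon"] = tab["snp_id"].isin(coding_ids)
        out_cols.append("exon")
    return tab[out_cols]


def gene_hit_list(result: AssociationResult, ann: pd.DataFrame) -> pd.DataFrame:
    """Per-gene table of significant SNPs: count, minimum p, classes present;
    sorted by ascending minimum p. SNPs annotated to several genes count once
    per gene."""
    validate_annotation(ann)
    sig = result.table.loc[result.table["significant"], ["snp_id", "p"]]
    merged = sig.merge(ann, on="snp_id", how="inner")
    merged = merged.loc[merged["gene_id"].ne("n/a") & merged["gene_id"].ne("")]
    if merged.empty:
        return pd.DataFrame(
            columns=["gene_id", "gene_name", "n_significant", "min_p", "classes"]
        )
    grouped = (
        merged.groupby(["gene_id", "gene_name"], sort=False)
        .agg(
            n_significant=("snp_id", "nunique"),
            min_p=("p", "min"),
            classes=("consequence_class", lambda s: ",".join(sorted(set(s)))),
        )
        .reset_index()
        .sort_values(["min_p", "gene_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return grouped


def simulate_annotation(
    snp_ids: list[str],
    seed: int = 0,
    class_probs: tuple[float, ...] = (0.55, 0.33, 0.05, 0.01, 0.06),
    subclass_probs: tuple[float, ...] = (0.6, 0.35, 0.05),
    n_genes: int | None = None,
) -> pd.DataFrame:
    """Synthetic annotation fixture with configurable class proportions
    (defaults echo typical WGS consequence shares: mostly intronic and
    intergenic, coding below 1%)."""
    rng = np.random.default_rng(seed)
    m = len(snp_ids)
    classes = rng.choice(CONSEQUENCE_CLASSES, size=m, p=class_probs)
    sub = np.where(
        classes == "coding",
        rng.choice(CODING_SUBCLASSES, size=m, p=subclass_probs),
        "n/a",
    )
    if n_genes is None:
        n_genes = max(1, m // 20)
    gene_idx = rng.integers(0, n_genes, size=m)
    genic = np.isin(classes, ("intron", "coding", "regulatory"))
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "consequence_class": classes,
            "coding_subclass": sub,
            "gene_id": np.where(genic, [f"ENSG{g:08d}" for g in gene_idx], "n/a"),
            "gene_name": np.where(genic, [f"GENE{g}" for g in gene_idx], "n/a"),
        }
    )
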