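"""Genomic annotation of TFEs against gene models.

Each TFE is classified by its summit against same-strand gene models into
nine mutually exclusive categories (coding upstream/5'-UTR/CDS/3'-UTR,
noncoding upstream/first exon/other exon, intron, unannotated), which are
then merged into the six display categories.  Overlapping-gene ambiguity is
resolved by a fixed priority toward the most promoter-like label.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import CountMatrix, GeneModel, SampleSheet

CODING_5UTR = "Coding5UTR"
CODING_UPSTREAM = "CodingUpstream"
CODING_CDS = "CodingCDS"
CODING_3UTR = "Coding3UTR"
NONCODING_1ST_EXON = "Noncoding1stExon"
NONCODING_UPSTREAM = "NoncodingUpstream"
NONCODING_OTHER_EXON = "NoncodingOtherExon"
INTRON = "Intron"
UNANNOTATED = "Unannotated"

#: Highest priority first: promoter-like labels win over gene-body labels.
CATEGORY_PRIORITY = (
    CODING_5UTR,
    CODING_UPSTREAM,
    CODING_CDS,
    CODING_3UTR,
    NONCODING_1ST_EXON,
    NONCODING_UPSTREAM,
    NONCODING_OTHER_EXON,
    INTRON,
    UNANNOTATED,
)

MERGED_UPSTREAM_5UTR_CODING = "UpstreamAnd5UTRCoding"
MERGED_CDS_3UTR_CODING = "CDSAnd3UTRCoding"
MERGED_UPSTREAM_1ST_EXON_NONCODING = "UpstreamAnd1stExonNoncoding"
MERGED_OTHER_EXONS_NONCODING = "OtherExonsNoncoding"

MERGED_CATEGORIES = (
    MERGED_UPSTREAM_5UTR_CODING,
    MERGED_CDS_3UTR_CODING,
    MERGED_UPSTREAM_1ST_EXON_NONCODING,
    MERGED_OTHER_EXONS_NONCODING,
    INTRON,
    UNANNOTATED,
)

MERGE_MAP = {
    CODING_5UTR: MERGED_UPSTREAM_5UTR_CODING,
    CODING_UPSTREAM: MERGED_UPSTREAM_5UTR_CODING,
    CODING_CDS: MERGED_CDS_3UTR_CODING,
    CODING_3UTR: MERGED_CDS_3UTR_CODING,
    NONCODING_1ST_EXON: MERGED_UPSTREAM_1ST_EXON_NONCODING,
    NONCODING_UPSTREAM: MERGED_UPSTREAM_1ST_EXON_NONCODING,
    NONCODING_OTHER_EXON: MERGED_OTHER_EXONS_NONCODING,
    INTRON: INTRON,
    UNANNOTATED: UNANNOTATED,
}


def merge_category(category: str) -> str:
    """Apply the fixed 9 -> 6 category merge."""
    try:
        return MERGE_MAP[category]
    except KeyError:
        raise ValueError(f"unknown annotation category {category!r}") from None


def _gene_category(gene: GeneModel, pos: int, upstream_bp: int) -> str | None:
    """Category of ``pos`` with respect to one same-strand gene, or None."""
    # strand-aware upstream window: within upstream_bp 5' of the TSS
    if gene.strand == "+":
        upstream = gene.tss - upstream_bp <= pos < gene.tss
    else:
        upstream = gene.tss < pos <= gene.tss + upstream_bp
    if upstream:
        return CODING_UPSTREAM if gene.biotype == "coding" else NONCODING_UPSTREAM
    if not (gene.start <= pos < gene.end):
        return None
    if not gene.exonic(pos):
        return INTRON
    if gene.biotype == "coding":
        cs, ce = gene.cds
        if gene.strand == "+":
            if pos < cs:
                return CODING_5UTR
            if pos >= ce:
                return CODING_3UTR
        else:
            if pos >= ce:
                return CODING_5UTR
            if pos < cs:
                return CODING_3UTR
        return CODING_CDS
    fs, fe = gene.first_exon
    return NONCODING_1ST_EXON if fs <= pos < fe else NONCODING_OTHER_EXON


class Annotator:
    """Summit-based TFE classifier over a gene-model collection."""

    def __init__(self, models: list[GeneModel], upstream_bp: int = 500) -> None:
        if upstream_bp <= 0:
            raise ValueError("upstream_bp must be > 0")
        self.upstream_bp = upstream_bp
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for gene in models:
            tree = self._trees.setdefault((gene.chrom, gene.strand), IntervalTree())
            # extend the span by the upstream window on both sides; exact
            # strand-aware upstream membership is re-checked per gene
            tree[gene.start - upstream_bp : gene.end + upstream_bp] = gene

    def classify(self, chrom: str, strand: str, summit: int) -> str:
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return UNANNOTATED
        best = len(CATEGORY_PRIORITY) - 1
        for hit in tree[summit]:
            cat = _gene_category(hit.data, summit, self.upstream_bp)
            if cat is not None:
                best = min(best, CATEGORY_PRIORITY.index(cat))
        return CATEGORY_PRIORITY[best]


def classify_tfe(
    region: pd.Series, models: list[GeneModel], upstream_bp: int = 500
) -> str:
    """Classify a single TFE region row (needs chrom/strand/summit)."""
    ann = Annotator(models, upstream_bp=upstream_bp)
    return ann.classify(region["chrom"], region["strand"], int(region["summit"]))


def annotate_regions(
    regions: pd.DataFrame, models: list[GeneModel], upstream_bp: int = 500
) -> pd.Series:
    """Nine-way category per non-spike-in TFE region (by summit)."""
    ann = Annotator(models, upstream_bp=upstream_bp)
    sub = regions.loc[~regions["is_spikein"].astype(bool)]
    cats = [
        ann.classify(row.chrom, row.strand, int(row.summit))
        for row in sub.itertuples()
    ]
    return pd.Series(cats, index=sub.index, name="category")


def annotation_proportions(
    matrix: CountMatrix,
    categories: pd.Series,
    sheet: SampleSheet,
) -> pd.DataFrame:
    """Stage-averaged percentages of counts per merged category.

    Per sample, counts of non-spike-in TFEs are summed by merged category
    and divided by the sample's total (x100); those per-sample percentages
    are then averaged over each stage's samples (mean of percentages, not
    pooled counts).  Rows are stages in developmental order, columns the
    six merged categories; every row sums to 100.
    """
    endo = matrix.endogenous()
    missing = endo.index.difference(categories.index)
    if len(missing):
        raise ValueError(f"unclassified TFEs: {list(missing[:5])}...")
    merged = categories.loc[endo.index].map(merge_category)

    per_sample = endo.groupby(merged).sum()
    per_sample = per_sample.reindex(list(MERGED_CATEGORIES), fill_value=0)
    totals = per_sample.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample with zero total counts: {zero.index[0]}")
    pct = per_sample / totals * 100.0

    stage_of = pd.Series({s: sheet.stage_of(s) for s in endo.columns})
    out = pct.T.groupby(stage_of).mean()
    out = out.reindex(sheet.stages_used())
    out.index.name = "stage"
    return out
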