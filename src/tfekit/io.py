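"""Readers and writers for the external formats the pipeline touches.

Conventions fixed here once and for all:

* GTF is 1-based closed on disk and converted to 0-based half-open on read.
* BED6 and all internal tables are 0-based half-open.
* FASTA output is wrapped at 60 columns.
* Alignment events travel either as a 7-column TSV
  (chrom, pos, strand, umi, sample, is_spikein, read_id) or as SAM records
  carrying the UMI in the ``RX`` tag and the sample id in the ``RG`` tag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import pysam

from .core import CountMatrix, GeneModel, SampleSheet

log = logging.getLogger(__name__)

EVENT_COLUMNS = ["chrom", "pos", "strand", "umi", "sample", "is_spikein", "read_id"]

DEFAULT_SPIKEIN_PREFIX = "spike_"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# gene models (GTF)
# ---------------------------------------------------------------------------

def read_gene_models(gtf_path: str | Path) -> list[GeneModel]:
    """Read a GTF into one :class:`GeneModel` per gene.

    When a gene has several transcripts, the one with the largest summed
    exon length wins; ties break toward the lexicographically smallest
    transcript_id.  Models whose CDS falls outside their exons, or whose
    strand is missing, are rejected with a logged identifier rather than
    raising.
    """
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    # transcript_id -> (gene_id, strand, chrom, exons, cds parts)
    tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        gid = feat.attributes.get("gene_id", [None])[0]
        if tid is None or gid is None:
            log.warning("skipping %s feature without gene/transcript id", feat.featuretype)
            continue
        entry = tx.setdefault(
            tid,
            {
                "gene_id": gid,
                "chrom": feat.seqid,
                "strand": feat.strand,
                "biotype": (feat.attributes.get("gene_biotype", ["protein_coding"])[0]),
                "exons": [],
                "cds": [],
            },
        )
        # GTF 1-based closed -> 0-based half-open
        iv = (feat.start - 1, feat.end)
        if feat.featuretype == "exon":
            entry["exons"].append(iv)
        else:
            entry["cds"].append(iv)

    by_gene: dict[str, list[tuple[str, dict]]] = {}
    for tid, entry in tx.items():
        by_gene.setdefault(entry["gene_id"], []).append((tid, entry))

    models: list[GeneModel] = []
    for gid in sorted(by_gene):
        candidates = sorted(
            by_gene[gid],
            key=lambda it: (-sum(e - s for s, e in it[1]["exons"]), it[0]),
        )
        tid, entry = candidates[0]
        if entry["strand"] not in ("+", "-"):
            log.warning("rejecting gene %s: missing strand", gid)
            continue
        biotype = "coding" if entry["cds"] else "noncoding"
        cds = None
        if entry["cds"]:
            cds = (min(s for s, _ in entry["cds"]), max(e for _, e in entry["cds"]))
        try:
            models.append(
                GeneModel(
                    gene_id=gid,
                    chrom=entry["chrom"],
                    strand=entry["strand"],
                    biotype=biotype,
                    exons=sorted(entry["exons"]),
                    cds=cds,
                )
            )
        except ValueError as exc:
            log.warning("rejecting gene %s: %s", gid, exc)
    return models


def write_gtf(models: list[GeneModel], path: str | Path, source: str = "tfekit") -> None:
    """Write gene models as GTF (1-based closed), one transcript per gene."""
    with open(path, "w") as fh:
        for m in models:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}.t1"; '
                f'gene_biotype "{"protein_coding" if m.biotype == "coding" else "lncRNA"}";'
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            if m.cds is not None:
                cs, ce = m.cds
                for s, e in m.exons:
                    os_, oe = max(s, cs), min(e, ce)
                    if os_ < oe:
                        fh.write(
                            f"{m.chrom}\t{source}\tCDS\t{os_ + 1}\t{oe}\t.\t{m.strand}\t.\t{attrs}\n"
                        )


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

@dataclass
class ReadLog:
    """Bookkeeping from an event reader."""

    n_kept: int = 0
    n_skipped: int = 0


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False, columns=EVENT_COLUMNS)


def read_events(
    path: str | Path,
    spikein_prefix: str = DEFAULT_SPIKEIN_PREFIX,
) -> tuple[pd.DataFrame, ReadLog]:
    """Read a coordinate-sorted 7-column event TSV.

    The spike-in flag is (re)derived from the reference-name prefix.  Raises
    on unsorted input (naming the first offending record) and on missing
    UMIs.
    """
    df = pd.read_csv(
        str(path),
        sep="\t",
        dtype={
            "chrom": str,
            "pos": np.int64,
            "strand": str,
            "umi": str,
            "sample": str,
            "read_id": str,
        },
    )
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    if df["umi"].isna().any():
        i = int(df["umi"].isna().idxmax())
        raise ValueError(f"missing UMI at record {i} ({df.loc[i, 'read_id']})")
    _check_sorted(df)
    df = df[EVENT_COLUMNS].copy()
    df["is_spikein"] = df["chrom"].str.startswith(spikein_prefix)
    return df, ReadLog(n_kept=len(df), n_skipped=0)


def _check_sorted(df: pd.DataFrame) -> None:
    """Require coordinate sorting: positions nondecreasing within each
    contiguous chromosome block, and each chromosome appearing in one block."""
    chroms = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    if len(df) <= 1:
        return
    new_block = np.r_[True, chroms[1:] != chroms[:-1]]
    seen: set[str] = set()
    for i in np.flatnonzero(new_block):
        c = chroms[i]
        if c in seen:
            raise ValueError(f"input not coordinate-sorted: chromosome {c} "
                             f"re-appears at record {i}")
        seen.add(c)
    bad = np.flatnonzero((pos[1:] < pos[:-1]) & ~new_block[1:])
    if bad.size:
        i = int(bad[0]) + 1
        raise ValueError(
            f"input not coordinate-sorted: record {i} "
            f"({chroms[i]}:{pos[i]}) before {chroms[i - 1]}:{pos[i - 1]}"
        )


def read_events_sam(
    path: str | Path,
    spikein_prefix: str = DEFAULT_SPIKEIN_PREFIX,
) -> tuple[pd.DataFrame, ReadLog]:
    """Read 5'-end events from SAM/BAM records.

    UMI from the ``RX`` tag, sample id from the ``RG`` tag.  Unmapped,
    secondary and supplementary records are skipped and counted.
    """
    from .quant import extract_five_prime

    rows = []
    rlog = ReadLog()
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                rlog.n_skipped += 1
                continue
            if not rec.has_tag("RX"):
                raise ValueError(f"record {rec.query_name} has no RX (UMI) tag")
            strand = "-" if rec.is_reverse else "+"
            pos = extract_five_prime(rec.get_blocks(), strand)
            rows.append(
                (
                    rec.reference_name,
                    pos,
                    strand,
                    rec.get_tag("RX"),
                    rec.get_tag("RG") if rec.has_tag("RG") else "sample",
                    str(rec.reference_name).startswith(spikein_prefix),
                    rec.query_name,
                )
            )
            rlog.n_kept += 1
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return df, rlog


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    out = pd.concat(
        [matrix.regions[list(CountMatrix.REGION_COLUMNS)], matrix.counts], axis=1
    )
    out.to_csv(path, sep="\t", index=True, index_label="tfe_id")


def read_count_matrix(path: str | Path) -> CountMatrix:
    df = pd.read_csv(str(path), sep="\t", index_col="tfe_id")
    if df.empty:
        raise ValueError("empty count matrix")
    region_cols = list(CountMatrix.REGION_COLUMNS)
    sample_cols = [c for c in df.columns if c not in region_cols]
    if not sample_cols:
        raise ValueError("count matrix has no sample columns")
    counts = df[sample_cols]
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or not np.allclose(vals, np.round(vals)):
        raise ValueError("counts must be integers")
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")
    regions = df[region_cols].copy()
    regions["is_spikein"] = regions["is_spikein"].astype(bool)
    return CountMatrix(counts=counts.astype(np.int64), regions=regions)


# ---------------------------------------------------------------------------
# BED / FASTA
# ---------------------------------------------------------------------------

def write_bed(intervals: pd.DataFrame, path: str | Path,
              chrom_sizes: dict[str, int] | None = None) -> None:
    """Write BED6 from a frame with chrom/start/end/strand columns and a
    name index (score column optional, default 0)."""
    with open(path, "w") as fh:
        for name, row in intervals.iterrows():
            if chrom_sizes is not None:
                size = chrom_sizes.get(row["chrom"])
                if size is not None and row["end"] > size:
                    raise ValueError(
                        f"{name}: interval end {row['end']} beyond chromosome "
                        f"{row['chrom']} length {size}"
                    )
            score = row.get("score", 0)
            fh.write(
                f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t"
                f"{name}\t{score}\t{row['strand']}\n"
            )


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        str(path),
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "name": str},
    )
    return df.set_index("name")


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.to_frame().to_csv(path, sep="\t", index=False)


def read_sample_sheet(
    path: str | Path, stage_order: tuple[str, ...] | None = None
) -> SampleSheet:
    df = pd.read_csv(str(path), sep="\t", dtype=str)
    if not {"sample_id", "stage"} <= set(df.columns):
        raise ValueError("sample sheet needs sample_id and stage columns")
    samples = dict(zip(df["sample_id"], df["stage"]))
    if stage_order is None:
        from .core import DEFAULT_STAGES

        known = set(df["stage"])
        if known <= set(DEFAULT_STAGES):
            stage_order = DEFAULT_STAGES
        else:  # preserve file order of first appearance
            stage_order = tuple(dict.fromkeys(df["stage"]))
    return SampleSheet(samples=samples, stage_order=tuple(stage_order))
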