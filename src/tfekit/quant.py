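"""Deduplication of 5'-end events, TFE region calling, and counting.

A TFE (transcript far 5'-end) is a strand-specific genomic region of
clustered, UMI-deduplicated read 5' ends; one TFE approximates one active
TSS region.  Calling is strand-specific single-linkage clustering of
deduplicated positions pooled over all samples (one TFE catalogue per
experiment), with a minimum pooled-count filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CountMatrix, SampleSheet

DEDUP_KEY = ["sample", "chrom", "strand", "pos", "umi"]


@dataclass(frozen=True)
class FivePrimeEvent:
    """A single deduplicated read 5'-end."""

    chrom: str
    strand: str
    pos: int
    umi: str
    sample_id: str
    is_spikein: bool = False

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("pos must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


def extract_five_prime(blocks: list[tuple[int, int]], strand: str) -> int:
    """Reference position of a read's 5' end from its aligned blocks.

    Plus strand: leftmost aligned base; minus strand: rightmost aligned
    base.  Spliced alignments are respected (blocks need not be adjacent).
    """
    blocks = sorted(blocks)
    if not blocks or all(e <= s for s, e in blocks):
        raise ValueError("zero-length alignment")
    if strand == "+":
        return blocks[0][0]
    if strand == "-":
        return blocks[-1][1] - 1
    raise ValueError(f"bad strand {strand!r}")


def dedup_events(events: pd.DataFrame) -> pd.DataFrame:
    """Collapse PCR duplicates: one event per distinct
    (sample, chrom, strand, pos, umi) tuple.

    Order-independent: the output is canonically sorted by
    (chrom, pos, strand, sample, umi).
    """
    out = events.drop_duplicates(subset=DEDUP_KEY)
    return out.sort_values(
        ["chrom", "pos", "strand", "sample", "umi"], kind="mergesort"
    ).reset_index(drop=True)


def call_tfes(
    events: pd.DataFrame, min_count: int = 2, max_gap: int = 60
) -> pd.DataFrame:
    """Call TFE regions from deduplicated events pooled over samples.

    Per (chrom, strand), event positions are single-linkage clustered with
    gap <= ``max_gap``; clusters whose pooled event count is below
    ``min_count`` are discarded.  A region spans [min pos, max pos + 1);
    its summit is the modal position, ties broken toward the farthest-5'
    base (leftmost mode on "+", rightmost on "-").

    Returns a region table indexed by tfe_id, ordered by
    (chrom, start, strand).
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    cols = ["chrom", "start", "end", "strand", "summit", "is_spikein", "count"]
    if len(events) == 0:
        return pd.DataFrame(columns=cols, index=pd.Index([], name="tfe_id"))

    rows = []
    for (chrom, strand), grp in events.groupby(["chrom", "strand"], sort=True):
        positions, counts = np.unique(grp["pos"].to_numpy(), return_counts=True)
        is_spike = bool(grp["is_spikein"].iloc[0])
        breaks = np.flatnonzero(np.diff(positions) > max_gap) + 1
        for pos_c, cnt_c in zip(np.split(positions, breaks), np.split(counts, breaks)):
            total = int(cnt_c.sum())
            if total < min_count:
                continue
            if strand == "+":
                summit = int(pos_c[np.argmax(cnt_c)])
            else:
                rev = cnt_c[::-1]
                summit = int(pos_c[len(cnt_c) - 1 - int(np.argmax(rev))])
            rows.append(
                (chrom, int(pos_c[0]), int(pos_c[-1]) + 1, strand, summit,
                 is_spike, total)
            )
    regions = pd.DataFrame(rows, columns=cols)
    regions = regions.sort_values(["chrom", "start", "strand"], kind="mergesort")
    regions.index = pd.Index(
        [f"TFE{i + 1}" for i in range(len(regions))], name="tfe_id"
    )
    return regions


def build_count_matrix(
    regions: pd.DataFrame, events: pd.DataFrame, sheet: SampleSheet
) -> tuple[CountMatrix, int]:
    """Count deduplicated events per (TFE, sample).

    An event counts toward a region when chrom and strand match and its
    position falls in the half-open region interval.  Events outside every
    region are tallied into the returned unassigned counter.  An event
    sample missing from the sheet is an error.
    """
    known = set(sheet.samples)
    seen = set(events["sample"].unique())
    unknown = seen - known
    if unknown:
        raise ValueError(f"samples absent from sample sheet: {sorted(unknown)}")

    sample_ids = sheet.sample_ids
    sample_code = {s: i for i, s in enumerate(sample_ids)}
    counts = np.zeros((len(regions), len(sample_ids)), dtype=np.int64)
    row_of = {tid: i for i, tid in enumerate(regions.index)}
    unassigned = 0

    ev_groups = dict(tuple(events.groupby(["chrom", "strand"], sort=False)))
    for (chrom, strand), reg in regions.groupby(["chrom", "strand"], sort=False):
        grp = ev_groups.pop((chrom, strand), None)
        if grp is None:
            continue
        reg = reg.sort_values("start")
        starts = reg["start"].to_numpy()
        ends = reg["end"].to_numpy()
        pos = grp["pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        unassigned += int((~inside).sum())
        if inside.any():
            rows = np.array([row_of[t] for t in reg.index])[idx[inside]]
            cols = grp["sample"].map(sample_code).to_numpy()[inside]
            np.add.at(counts, (rows, cols), 1)
    # events on (chrom, strand) pairs without any region
    unassigned += sum(len(g) for g in ev_groups.values())

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=regions.index.copy(), columns=sample_ids),
        regions=regions[list(CountMatrix.REGION_COLUMNS)].copy(),
    )
    return matrix, unassigned


def quantify(
    events: pd.DataFrame,
    sheet: SampleSheet,
    min_count: int = 2,
    max_gap: int = 60,
) -> tuple[CountMatrix, int]:
    """dedup -> call -> count in one step."""
    deduped = dedup_events(events)
    regions = call_tfes(deduped, min_count=min_count, max_gap=max_gap)
    return build_count_matrix(regions, deduped, sheet)
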