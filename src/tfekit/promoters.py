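"""Strand-aware promoter window extraction around TFE summits.

Windows default to 400 bp upstream and 100 bp downstream of the TFE
anchor (the summit, the representative 5' base); "downstream" includes the
anchor base itself, so an unclipped window has length exactly up + down.
Minus-strand sequences are emitted as reverse complements, ready for
external motif-discovery suites.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import GenomicInterval
from .io import reverse_complement


@dataclass
class PromoterWindow:
    tfe_id: str
    interval: GenomicInterval
    anchor: int
    up: int
    down: int
    clipped: bool

    def __post_init__(self) -> None:
        if not self.interval.contains(self.anchor):
            raise ValueError(f"{self.tfe_id}: anchor outside window")
        if not self.clipped and len(self.interval) != self.up + self.down:
            raise ValueError(f"{self.tfe_id}: unclipped window has wrong length")


def promoter_window(
    region: pd.Series,
    up: int = 400,
    down: int = 100,
    chrom_length: int | None = None,
    tfe_id: str = "",
) -> PromoterWindow:
    """Window of ``up`` bp 5' and ``down`` bp from the summit (inclusive).

    With summit p: plus strand -> [p-up, p+down); minus strand ->
    [p-down+1, p+up+1).  The window is clipped to [0, chrom_length) with
    the clipped flag set; a window entirely outside the chromosome is an
    error.
    """
    if up < 0 or down < 1:
        raise ValueError("require up >= 0 and down >= 1")
    p = int(region["summit"])
    strand = region["strand"]
    if strand == "+":
        start, end = p - up, p + down
    elif strand == "-":
        start, end = p - down + 1, p + up + 1
    else:
        raise ValueError(f"bad strand {strand!r}")
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if chrom_length is not None and end > chrom_length:
        end, clipped = chrom_length, True
    if end <= start or (chrom_length is not None and start >= chrom_length):
        raise ValueError(f"window entirely outside chromosome for summit {p}")
    return PromoterWindow(
        tfe_id=tfe_id or str(region.name),
        interval=GenomicInterval(region["chrom"], start, end, strand),
        anchor=p,
        up=up,
        down=down,
        clipped=clipped,
    )


def promoter_windows(
    regions: pd.DataFrame,
    up: int = 400,
    down: int = 100,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Vector version over a TFE region table; returns a BED-like frame."""
    rows = []
    for tfe_id, region in regions.iterrows():
        size = chrom_sizes.get(region["chrom"]) if chrom_sizes else None
        w = promoter_window(region, up=up, down=down, chrom_length=size,
                            tfe_id=str(tfe_id))
        rows.append(
            (tfe_id, w.interval.chrom, w.interval.start, w.interval.end,
             w.interval.strand, w.anchor, w.clipped)
        )
    out = pd.DataFrame(
        rows,
        columns=["tfe_id", "chrom", "start", "end", "strand", "anchor", "clipped"],
    ).set_index("tfe_id")
    return out


def extract_promoter_sequences(
    windows: pd.DataFrame, genome: dict[str, str]
) -> dict[str, str]:
    """Strand-aware sequences for promoter windows.

    Minus-strand windows yield the reverse complement of the plus-strand
    slice.  Sequence names carry the TFE id and window coordinates.
    """
    out: dict[str, str] = {}
    for tfe_id, row in windows.iterrows():
        chrom = row["chrom"]
        if chrom not in genome:
            raise ValueError(f"chromosome {chrom} missing from genome")
        seq = genome[chrom][int(row["start"]) : int(row["end"])]
        if row["strand"] == "-":
            seq = reverse_complement(seq)
        name = f"{tfe_id}::{chrom}:{int(row['start'])}-{int(row['end'])}({row['strand']})"
        out[name] = seq
    return out
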