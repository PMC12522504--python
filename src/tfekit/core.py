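"""Core value types shared across the package.

All genomic coordinates are 0-based half-open ``[start, end)`` internally.
GTF input (1-based closed) is converted on read and never stored 1-based.
Strand is always ``"+"`` or ``"-"``; every quantity that depends on
transcription direction (TSS, upstream windows, promoter windows) is
computed strand-aware from these types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STRANDS = ("+", "-")

#: Ordered developmental stages of the bovine oocyte-to-blastocyst series:
#: germinal-vesicle oocyte, metaphase-II oocyte, cleavage stages, blastocyst.
DEFAULT_STAGES = ("GV", "MII", "2c", "4c", "8c", "16c", "Blc")

#: Sentinel for "no signal" in log2-normalized matrices: below any finite
#: expression threshold and absorbing under medians.
SENTINEL = float("-inf")


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class GeneModel:
    """A gene-level transcript model: ordered disjoint exons plus an
    optional CDS span (present iff the gene is coding).

    ``cds`` is the genomic span from the first to the last coding base;
    both endpoints must fall inside exons.  The TSS is the strand-aware
    first transcribed base: leftmost exon start on ``+``, rightmost exon
    end minus one on ``-``.
    """

    gene_id: str
    chrom: str
    strand: str
    biotype: str  # "coding" | "noncoding"
    exons: list[tuple[int, int]]
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.biotype not in ("coding", "noncoding"):
            raise ValueError(f"{self.gene_id}: bad biotype {self.biotype!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: no exons")
        exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        for s, e in exons:
            if not (0 <= s < e):
                raise ValueError(f"{self.gene_id}: empty or negative exon [{s},{e})")
        self.exons = exons
        if (self.cds is None) != (self.biotype == "noncoding"):
            raise ValueError(
                f"{self.gene_id}: CDS must be present iff the gene is coding"
            )
        if self.cds is not None:
            cs, ce = self.cds
            if not (self.start <= cs < ce <= self.end):
                raise ValueError(f"{self.gene_id}: CDS outside exon span")
            if not (self.exonic(cs) and self.exonic(ce - 1)):
                raise ValueError(f"{self.gene_id}: CDS endpoint not exonic")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Strand-aware first transcribed base."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1

    @property
    def first_exon(self) -> tuple[int, int]:
        """The first *transcribed* exon (strand-aware)."""
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    def exonic(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class SampleSheet:
    """Maps sample ids to ordered developmental stages."""

    samples: dict[str, str]  # sample_id -> stage label
    stage_order: tuple[str, ...] = DEFAULT_STAGES

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("sample sheet is empty")
        if not self.stage_order:
            raise ValueError("stage order is empty")
        unknown = set(self.samples.values()) - set(self.stage_order)
        if unknown:
            raise ValueError(f"samples reference unknown stages: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list[str]:
        """Samples in stage order, then insertion order within a stage."""
        return [
            s
            for stage in self.stage_order
            for s, st in self.samples.items()
            if st == stage
        ]

    def stages_used(self) -> list[str]:
        present = set(self.samples.values())
        return [s for s in self.stage_order if s in present]

    def stage_index(self, stage: str) -> int:
        return self.stage_order.index(stage)

    def stage_of(self, sample_id: str) -> str:
        return self.samples[sample_id]

    def samples_for(self, stage: str) -> list[str]:
        return [s for s, st in self.samples.items() if st == stage]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(self.samples), "stage": list(self.samples.values())}
        )


@dataclass
class CountMatrix:
    """TFE x sample UMI count matrix with per-TFE region metadata.

    ``counts`` is indexed by tfe_id with one integer column per sample;
    ``regions`` shares the index and carries chrom/start/end/strand/summit
    and the spike-in flag.
    """

    counts: pd.DataFrame
    regions: pd.DataFrame

    REGION_COLUMNS = ("chrom", "start", "end", "strand", "summit", "is_spikein")

    def __post_init__(self) -> None:
        if self.counts.empty:
            raise ValueError("count matrix is empty")
        if not self.counts.index.equals(self.regions.index):
            raise ValueError("counts and regions must share an index")
        missing = set(self.REGION_COLUMNS) - set(self.regions.columns)
        if missing:
            raise ValueError(f"regions missing columns: {sorted(missing)}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def spike_mask(self) -> pd.Series:
        return self.regions["is_spikein"].astype(bool)

    def endogenous(self) -> pd.DataFrame:
        return self.counts.loc[~self.spike_mask]

    def spikeins(self) -> pd.DataFrame:
        return self.counts.loc[self.spike_mask]
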