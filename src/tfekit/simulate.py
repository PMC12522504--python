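"""Synthetic maternal-to-zygotic-transition (MZT) study generator.

Emulates the structure of a 5'-end single-oocyte/embryo RNA-seq experiment:

* a miniature multi-chromosome genome carrying non-overlapping coding and
  noncoding gene models (coding genes with 5'-UTR / CDS / 3'-UTR and >= 2
  exons) plus dedicated spike-in reference sequences;
* stage-ordered samples (GV, MII, 2c, 4c, 8c, 16c, Blc by default) whose
  expression programs encode maternal transcript decay with two major
  degradation waves (post-fertilization and at the 16-cell stage), a
  zygotic transcription burst at the 16-cell stage, housekeeping genes and
  stage-exclusive marker genes;
* molecule counts drawn negative-binomially around stage means, thinned by
  capture efficiency, jittered around the true TSS, tagged with UMIs and
  replicated by PCR at a configurable rate;
* a fraction of genes whose TSSs are withheld from the annotation
  ("unannotated" TSSs) while still producing reads.

Every output is a deterministic function of the config seed.  Ground-truth
tables (gene classes, per-stage mean molecules, content ratios, spike-in
inputs) are returned for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import DEFAULT_STAGES, GeneModel, SampleSheet
from .io import EVENT_COLUMNS

#: Default per-stage multiplicative decay on maternal means: steady through
#: oocyte maturation, a large post-fertilization wave at 2c, a second wave
#: at 16c.  Applied cumulatively along the stage axis.
DEFAULT_MATERNAL_DECAY = (1.0, 1.0, 0.35, 0.9, 0.9, 0.5, 1.0)

#: Default per-stage scalars on total molecules, mimicking the observed
#: decline of poly(A) content through cleavage and its recovery at the
#: blastocyst (qualitative shape only).
DEFAULT_CONTENT_MULTIPLIER = (1.0, 1.0, 0.8, 0.65, 0.55, 0.35, 0.75)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study conditions for the synthetic MZT experiment.

    ``spikein_molecules_per_sample`` is the total spike-in molecule input M
    per sample (default 9216, so a log2 normalized value of -10 maps to
    exactly nine copies); ``capture_efficiency`` is the per-molecule
    probability eta of yielding a sequenced event; ``overdispersion`` is
    the biological CV^2 of molecule counts around stage means.
    """

    seed: int = 0
    n_chromosomes: int = 6
    chromosome_length: int = 1_000_000
    n_coding_genes: int = 1200
    n_noncoding_genes: int = 300
    n_spikeins: int = 50
    spikein_molecules_per_sample: int = 9216
    stages: tuple[str, ...] = DEFAULT_STAGES
    samples_per_stage: int = 6
    capture_efficiency: float = 0.15
    pcr_duplicate_rate: float = 0.5
    tss_jitter_sd: float = 4.0
    maternal_fraction: float = 0.45
    zygotic_fraction: float = 0.25
    housekeeping_fraction: float = 0.20
    n_markers_per_stage: int = 30
    stage_content_multiplier: tuple[float, ...] = DEFAULT_CONTENT_MULTIPLIER
    maternal_decay: tuple[float, ...] = DEFAULT_MATERNAL_DECAY
    unannotated_tss_fraction: float = 0.25
    overdispersion: float = 0.3
    # mean molecules per gene per sample: lognormal(log(mean_expression), sigma)
    mean_expression: float = 100.0
    expression_sigma: float = 1.0
    marker_expression_range: tuple[float, float] = (150.0, 400.0)
    zygotic_basal: float = 0.02
    zygotic_onset_index: int = -2  # 16c in the default stage list
    umi_length: int = 10
    spikein_prefix: str = "spike_"
    min_gene_gap: int = 700  # > upstream classification window, avoids ambiguity

    def validate(self) -> None:
        if self.n_chromosomes <= 0 or self.chromosome_length <= 0:
            raise ValueError("need positive genome dimensions")
        if self.n_coding_genes < 0 or self.n_noncoding_genes < 0:
            raise ValueError("gene counts must be >= 0")
        if self.n_coding_genes + self.n_noncoding_genes <= 0:
            raise ValueError("need at least one gene")
        if self.n_spikeins <= 0 or self.spikein_molecules_per_sample <= 0:
            raise ValueError("need positive spike-in configuration")
        if not self.stages:
            raise ValueError("stage list is empty")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stage labels must be unique")
        if self.samples_per_stage <= 0:
            raise ValueError("samples_per_stage must be > 0")
        if not (0 < self.capture_efficiency <= 1):
            raise ValueError("capture_efficiency must be in (0, 1]")
        if self.pcr_duplicate_rate < 0 or self.tss_jitter_sd < 0:
            raise ValueError("rates must be >= 0")
        fracs = (
            self.maternal_fraction,
            self.zygotic_fraction,
            self.housekeeping_fraction,
            self.unannotated_tss_fraction,
        )
        if any(not (0 <= f <= 1) for f in fracs):
            raise ValueError("fractions must be in [0, 1]")
        if self.maternal_fraction + self.zygotic_fraction + self.housekeeping_fraction > 1:
            raise ValueError("class fractions must sum to <= 1")
        if len(self.stage_content_multiplier) != len(self.stages):
            raise ValueError("stage_content_multiplier length != number of stages")
        if any(m <= 0 for m in self.stage_content_multiplier):
            raise ValueError("stage_content_multiplier must be positive")
        if len(self.maternal_decay) != len(self.stages):
            raise ValueError("maternal_decay length != number of stages")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        if self.n_markers_per_stage < 0:
            raise ValueError("n_markers_per_stage must be >= 0")

    @property
    def n_genes(self) -> int:
        return self.n_coding_genes + self.n_noncoding_genes

    @property
    def sample_sheet(self) -> SampleSheet:
        samples = {
            f"{stage}_{i + 1}": stage
            for stage in self.stages
            for i in range(self.samples_per_stage)
        }
        return SampleSheet(samples=samples, stage_order=tuple(self.stages))


@dataclass
class Reference:
    """Synthetic genome + gene models + spike-in manifest."""

    sequences: dict[str, str]  # chromosomes and spike-in references
    genes: list[GeneModel]
    gene_table: pd.DataFrame  # index gene_id: chrom, strand, tss, biotype, annotated
    spikeins: pd.DataFrame  # index name: length, tss, molecules_per_sample

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def annotated_genes(self) -> list[GeneModel]:
        ann = set(self.gene_table.index[self.gene_table["annotated"]])
        return [g for g in self.genes if g.gene_id in ann]


@dataclass
class GroundTruth:
    """What the simulator actually planted, for recovery tests."""

    genes: pd.DataFrame  # index gene_id: chrom,strand,tss,biotype,annotated,gene_class,marker_stage,base_expression
    stage_means: pd.DataFrame  # gene x stage expected molecules
    content_ratio: pd.Series  # per-stage expected total molecules / reference stage
    spikeins: pd.DataFrame


class GenomeCapacityError(ValueError):
    """The configured genome cannot hold the requested gene models."""


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _make_gene(rng: np.random.Generator, gene_id: str, chrom: str, start: int,
               strand: str, coding: bool) -> GeneModel:
    n_exons = int(rng.integers(2, 5))
    exon_lens = [int(rng.integers(150, 401))]
    exon_lens += [int(rng.integers(120, 601)) for _ in range(n_exons - 1)]
    intron_lens = [int(rng.integers(80, 401)) for _ in range(n_exons - 1)]
    exons = []
    cursor = start
    for i, el in enumerate(exon_lens):
        exons.append((cursor, cursor + el))
        cursor += el
        if i < n_exons - 1:
            cursor += intron_lens[i]
    cds = None
    if coding:
        # margins eat into the genomically first/last exon; which one is the
        # 5'-UTR depends on strand
        utr5 = int(rng.integers(40, 121))
        utr3 = int(rng.integers(60, 201))
        left, right = (utr5, utr3) if strand == "+" else (utr3, utr5)
        left = min(left, exon_lens[0] - 10)
        right = min(right, exon_lens[-1] - 10)
        cds = (exons[0][0] + left, exons[-1][1] - right)
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        biotype="coding" if coding else "noncoding", exons=exons, cds=cds,
    )


def generate_reference(config: SimConfig) -> Reference:
    """Build the synthetic genome, gene models and spike-in manifest.

    Gene models are placed left-to-right with gaps of at least
    ``min_gene_gap`` bp, alternating chromosomes as they fill; a genome too
    small to hold them raises :class:`GenomeCapacityError`.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed) % (2**31), 11])

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    sequences = {c: _random_seq(rng, config.chromosome_length) for c in chroms}

    # interleave biotypes deterministically, then shuffle placement order
    biotypes = np.array(
        ["coding"] * config.n_coding_genes + ["noncoding"] * config.n_noncoding_genes
    )
    rng.shuffle(biotypes)

    genes: list[GeneModel] = []
    chrom_idx = 0
    cursor = config.min_gene_gap
    for i, bt in enumerate(biotypes):
        gid = f"g{i + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        placed = False
        while chrom_idx < len(chroms):
            gene = _make_gene(rng, gid, chroms[chrom_idx], cursor, strand, bt == "coding")
            if gene.end + config.min_gene_gap <= config.chromosome_length:
                genes.append(gene)
                cursor = gene.end + config.min_gene_gap + int(rng.integers(0, 300))
                placed = True
                break
            chrom_idx += 1
            cursor = config.min_gene_gap
        if not placed:
            raise GenomeCapacityError(
                f"genome too small: placed {len(genes)} of {len(biotypes)} genes; "
                "increase chromosome_length or n_chromosomes"
            )

    annotated = rng.random(len(genes)) >= config.unannotated_tss_fraction
    gene_table = pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
            "biotype": [g.biotype for g in genes],
            "annotated": annotated,
        },
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )

    # spike-ins: a dilution-series-like log-spaced molecule ladder summing
    # exactly to spikein_molecules_per_sample
    names = [f"{config.spikein_prefix}{i + 1:03d}" for i in range(config.n_spikeins)]
    lengths = rng.integers(400, 801, size=config.n_spikeins)
    for name, ln in zip(names, lengths):
        sequences[name] = _random_seq(rng, int(ln))
    if config.n_spikeins == 1:
        mols = np.array([config.spikein_molecules_per_sample])
    else:
        raw = 2.0 ** np.linspace(0, 6, config.n_spikeins)
        mols = np.maximum(
            1, np.round(raw / raw.sum() * config.spikein_molecules_per_sample)
        ).astype(np.int64)
        mols[-1] += config.spikein_molecules_per_sample - mols.sum()
    spikeins = pd.DataFrame(
        {"length": lengths.astype(np.int64), "tss": 50, "strand": "+",
         "molecules_per_sample": mols},
        index=pd.Index(names, name="name"),
    )
    return Reference(sequences=sequences, genes=genes, gene_table=gene_table,
                     spikeins=spikeins)


# ---------------------------------------------------------------------------
# expression programs and molecule counts
# ---------------------------------------------------------------------------

def _class_profiles(config: SimConfig) -> dict[str, np.ndarray]:
    n = len(config.stages)
    maternal = np.cumprod(np.asarray(config.maternal_decay, dtype=float))
    onset = config.zygotic_onset_index % n
    zygotic = np.full(n, config.zygotic_basal)
    zygotic[onset] = 1.0
    zygotic[onset + 1 :] = 1.2
    housekeeping = np.ones(n)
    return {"maternal": maternal, "zygotic": zygotic, "housekeeping": housekeeping}


def simulate_counts(
    reference: Reference, config: SimConfig, truth_seed: int = 1
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw per-gene, per-sample molecule counts and return ground truth.

    Stage means are built from class profiles (maternal decay, zygotic
    onset, flat housekeeping, stage-exclusive markers), then renormalized
    per stage so expected totals follow ``stage_content_multiplier``
    exactly relative to the first stage.  Counts are negative-binomial with
    biological CV^2 ``overdispersion`` around those means (Poisson when 0).
    """
    config.validate()
    rng = np.random.default_rng(
        [int(config.seed) % (2**31), 13, int(truth_seed) % (2**31)]
    )
    stages = list(config.stages)
    gene_ids = list(reference.gene_table.index)
    n_genes = len(gene_ids)

    n_marker_total = config.n_markers_per_stage * len(stages)
    if n_marker_total > n_genes:
        raise ValueError("more markers requested than genes available")

    # class assignment: markers first, remaining genes split by fractions
    perm = rng.permutation(n_genes)
    marker_idx = perm[:n_marker_total]
    rest = perm[n_marker_total:]
    weights = np.array(
        [config.maternal_fraction, config.zygotic_fraction, config.housekeeping_fraction]
    )
    if weights.sum() == 0:
        raise ValueError("at least one class fraction must be positive")
    probs = weights / weights.sum()
    n_mat = int(np.floor(probs[0] * len(rest)))
    n_zyg = int(np.floor(probs[1] * len(rest)))
    gene_class = np.empty(n_genes, dtype=object)
    marker_stage = np.full(n_genes, "", dtype=object)
    gene_class[marker_idx] = "marker"
    for k, gi in enumerate(marker_idx):
        marker_stage[gi] = stages[k % len(stages)]
    gene_class[rest[:n_mat]] = "maternal"
    gene_class[rest[n_mat : n_mat + n_zyg]] = "zygotic"
    gene_class[rest[n_mat + n_zyg :]] = "housekeeping"

    base = rng.lognormal(np.log(config.mean_expression), config.expression_sigma,
                         size=n_genes)
    lo, hi = config.marker_expression_range
    base[marker_idx] = rng.uniform(lo, hi, size=len(marker_idx))

    profiles = _class_profiles(config)
    n_stages = len(stages)
    raw = np.zeros((n_genes, n_stages))
    for cls, prof in profiles.items():
        mask = gene_class == cls
        raw[mask] = base[mask, None] * prof[None, :]
    for gi in marker_idx:
        raw[gi, stages.index(marker_stage[gi])] = base[gi]

    # renormalize stage totals to follow the content multipliers exactly
    mult = np.asarray(config.stage_content_multiplier, dtype=float)
    totals = raw.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("a stage has zero expected molecules; check fractions")
    scale = mult / mult[0] * totals[0] / totals
    means = raw * scale[None, :]

    sheet = config.sample_sheet
    counts = np.zeros((n_genes, len(sheet.sample_ids)), dtype=np.int64)
    b = config.overdispersion
    for j, sid in enumerate(sheet.sample_ids):
        stage = sheet.stage_of(sid)
        if stage not in stages:
            raise ValueError(f"unknown stage label {stage!r}")
        mu = means[:, stages.index(stage)]
        if b == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            lam = rng.gamma(shape=1.0 / b, scale=b * np.maximum(mu, 1e-12))
            lam[mu == 0] = 0.0
            counts[:, j] = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=sheet.sample_ids)
    genes_df = reference.gene_table.copy()
    genes_df["gene_class"] = gene_class
    genes_df["marker_stage"] = marker_stage
    genes_df["base_expression"] = base
    truth = GroundTruth(
        genes=genes_df,
        stage_means=pd.DataFrame(means, index=counts_df.index, columns=stages),
        content_ratio=pd.Series(mult / mult[0], index=stages, name="content_ratio"),
        spikeins=reference.spikeins.copy(),
    )
    return counts_df, truth


# ---------------------------------------------------------------------------
# alignment events
# ---------------------------------------------------------------------------

def _int_to_umi(values: np.ndarray, length: int) -> np.ndarray:
    digits = (values[:, None] // 4 ** np.arange(length)[None, :]) % 4
    chars = np.array(list("ACGT"))[digits]
    return chars.view(f"<U{length}").ravel()


def simulate_alignments(
    counts: pd.DataFrame,
    truth: GroundTruth,
    config: SimConfig,
    reference: Reference,
    keep_predup: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Turn molecule counts into a coordinate-sorted 5'-end event stream.

    Each molecule is captured with probability eta; a captured molecule
    emits one event at the gene's true TSS plus Normal(0, tss_jitter_sd)
    rounded and clipped to the chromosome, on the gene's strand, with a
    random UMI.  PCR then replicates each (position, UMI, sample) tuple
    ``1 + Poisson(pcr_duplicate_rate)`` times.  Spike-in molecules are
    treated identically on their own reference sequences.  With
    ``keep_predup`` the pre-duplication stream is returned as well.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed) % (2**31), 17])
    sizes = reference.chrom_sizes

    gene_chrom = truth.genes["chrom"].to_numpy()
    gene_strand = truth.genes["strand"].to_numpy()
    gene_tss = truth.genes["tss"].to_numpy()
    gene_len = np.array([sizes[c] for c in gene_chrom])

    sp = truth.spikeins
    sp_chrom = sp.index.to_numpy()
    sp_tss = sp["tss"].to_numpy()
    sp_mols = sp["molecules_per_sample"].to_numpy()
    sp_len = np.array([sizes[c] for c in sp_chrom])

    all_chrom = np.concatenate([gene_chrom, sp_chrom])
    all_strand = np.concatenate([gene_strand, np.full(len(sp), "+")])
    all_tss = np.concatenate([gene_tss, sp_tss])
    all_len = np.concatenate([gene_len, sp_len])
    all_spike = np.r_[np.zeros(len(gene_chrom), bool), np.ones(len(sp), bool)]

    eta = config.capture_efficiency
    frames = []
    for sid in counts.columns:
        mols = np.concatenate([counts[sid].to_numpy(), sp_mols])
        captured = rng.binomial(mols, eta)
        n = int(captured.sum())
        if n == 0:
            continue
        chrom = np.repeat(all_chrom, captured)
        strand = np.repeat(all_strand, captured)
        tss = np.repeat(all_tss, captured)
        clen = np.repeat(all_len, captured)
        spike = np.repeat(all_spike, captured)
        jitter = np.rint(rng.normal(0.0, config.tss_jitter_sd, size=n)).astype(np.int64)
        pos = np.clip(tss + jitter, 0, clen - 1)
        umi = _int_to_umi(rng.integers(0, 4**config.umi_length, size=n),
                          config.umi_length)
        dup = rng.poisson(config.pcr_duplicate_rate, size=n) if \
            config.pcr_duplicate_rate > 0 else np.zeros(n, dtype=np.int64)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "strand": strand, "umi": umi,
                 "sample": sid, "is_spikein": spike, "reps": 1 + dup}
            )
        )
    if not frames:
        raise ValueError("no events generated; check configuration")
    predup = pd.concat(frames, ignore_index=True)
    predup = predup.sort_values(
        ["chrom", "pos", "strand", "sample", "umi"], kind="mergesort"
    ).reset_index(drop=True)

    reps = predup.pop("reps").to_numpy()
    events = predup.loc[predup.index.repeat(reps)].reset_index(drop=True)
    events["read_id"] = [f"r{i:09d}" for i in range(len(events))]
    events = events[EVENT_COLUMNS]
    if keep_predup:
        predup = predup.copy()
        predup["read_id"] = [f"m{i:09d}" for i in range(len(predup))]
        return events, predup[EVENT_COLUMNS]
    return events


@dataclass
class SimBundle:
    """One fully simulated study."""

    config: SimConfig
    reference: Reference
    counts: pd.DataFrame
    truth: GroundTruth
    events: pd.DataFrame
    sheet: SampleSheet


def simulate_study(config: SimConfig, truth_seed: int = 1) -> SimBundle:
    """Convenience driver: reference -> counts -> events."""
    reference = generate_reference(config)
    counts, truth = simulate_counts(reference, config, truth_seed=truth_seed)
    events = simulate_alignments(counts, truth, config, reference)
    return SimBundle(config=config, reference=reference, counts=counts,
                     truth=truth, events=events, sheet=config.sample_sheet)
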