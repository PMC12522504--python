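"""End-to-end pipeline orchestration with a fixed output layout.

``run_pipeline`` drives simulate -> quantify -> annotate -> normalize ->
hvt -> de -> markers -> cluster -> promoters under a single run directory,
logs stage-tagged lines to stderr, and writes a manifest recording every
parameter that affects output plus per-output row counts.  A rerun with
the same config and seed reproduces byte-identical TSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotate as ann
from . import io as tio
from . import markers as mk
from . import normalize as norm
from . import promoters as prom
from . import quant
from . import stats as st
from .simulate import SimConfig, simulate_study

log = logging.getLogger("tfekit.pipeline")


@dataclass
class Thresholds:
    """All analysis constants in one record (defaults as used throughout)."""

    alpha: float = 0.05
    top_k: int = 20_000
    expr_threshold: float = -10.0
    lfc_threshold: float = 3.0
    up: int = 400
    down: int = 100
    k: int = 6
    restarts: int = 1000
    max_iter: int = 20
    min_count: int = 2
    max_gap: int = 60
    upstream_bp: int = 500
    pseudocount: float = 1.0
    spike_molecules: float = 9216.0
    reference_stage: str = "GV"


@dataclass
class RunConfig:
    outdir: str | Path = "tfekit_run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    marker_stages: tuple[str, ...] = mk.DEFAULT_MARKER_STAGES

    def __post_init__(self) -> None:
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    def to_dict(self) -> dict:
        """Every parameter that affects output; the output path is not one
        and is deliberately omitted so reruns hash identically."""
        d = dataclasses.asdict(self)
        d.pop("outdir", None)
        return d


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> int:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)
    return len(df)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage in dependency order; returns the manifest dict."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    th = cfg.thresholds
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
    }

    def record(stage: str, **outputs: int) -> None:
        manifest["stages"][stage] = {"outputs": outputs}
        log.info("[%s] done: %s", stage, outputs)

    # --- simulate ---------------------------------------------------------
    bundle = simulate_study(cfg.sim)
    tio.write_fasta(bundle.reference.sequences, out / "genome.fa")
    tio.write_gtf(bundle.reference.annotated_genes(), out / "models.gtf")
    tio.write_sample_sheet(bundle.sheet, out / "samples.tsv")
    tio.write_events(bundle.events, out / "events.tsv")
    bundle.reference.spikeins.to_csv(out / "spikeins.tsv", sep="\t")
    bundle.truth.genes.to_csv(out / "truth_genes.tsv", sep="\t")
    bundle.truth.stage_means.to_csv(out / "truth_stage_means.tsv", sep="\t",
                                    float_format="%.10g")
    bundle.truth.content_ratio.to_frame().to_csv(out / "truth_content.tsv", sep="\t")
    record("simulate", events=len(bundle.events), genes=len(bundle.truth.genes))

    # --- quantify ---------------------------------------------------------
    deduped = quant.dedup_events(bundle.events)
    regions = quant.call_tfes(deduped, min_count=th.min_count, max_gap=th.max_gap)
    matrix, unassigned = quant.build_count_matrix(regions, deduped, bundle.sheet)
    tio.write_count_matrix(matrix, out / "counts.tsv")
    tio.write_bed(regions, out / "tfes.bed", chrom_sizes=bundle.reference.chrom_sizes)
    record("quantify", tfes=len(regions), deduplicated=len(deduped),
           unassigned=unassigned)

    # --- annotate ---------------------------------------------------------
    models = tio.read_gene_models(out / "models.gtf")
    categories = ann.annotate_regions(matrix.regions, models,
                                      upstream_bp=th.upstream_bp)
    proportions = ann.annotation_proportions(matrix, categories, bundle.sheet)
    _write_tsv(categories.to_frame(), out / "annotations.tsv")
    _write_tsv(proportions, out / "proportions.tsv")
    record("annotate", classified=len(categories), stages=len(proportions))

    # --- normalize --------------------------------------------------------
    factors = norm.spikein_size_factors(matrix)
    values = norm.log2_normalize(matrix, factors, pseudocount=0.0)
    values_pc = norm.log2_normalize(matrix, factors, pseudocount=th.pseudocount)
    content = norm.relative_rna_content(matrix, bundle.sheet,
                                        reference_stage=th.reference_stage)
    _write_tsv(factors.to_frame(), out / "size_factors.tsv")
    _write_tsv(values, out / "values.tsv", index_label="tfe_id")
    _write_tsv(content.to_frame(), out / "content.tsv", index_label="stage")
    record("normalize", samples=len(factors), stages=len(content))

    # --- hvt --------------------------------------------------------------
    points = st.spikein_noise_points(matrix, factors)
    fit = st.fit_technical_noise(points["mu"], points["cv2"])
    var_table = st.variability_table(matrix, factors, fit)
    selected = st.select_top_variable(var_table, k=th.top_k, alpha=th.alpha)
    corr = st.pairwise_correlation(values_pc.loc[selected])
    _write_tsv(var_table, out / "variability.tsv", index_label="tfe_id")
    (out / "hvt.txt").write_text("\n".join(selected) + "\n")
    _write_tsv(corr, out / "correlation.tsv", index_label="sample")
    manifest["noise_fit"] = {"a0": fit.a0, "a1": fit.a1,
                             "fallback": fit.used_fallback}
    record("hvt", selected=len(selected), tested=len(var_table))

    # --- de ---------------------------------------------------------------
    de_dir = out / "de"
    de_dir.mkdir(exist_ok=True)
    de_tables = st.de_all_contrasts(matrix, factors, bundle.sheet, alpha=th.alpha)
    n_rows = 0
    for contrast, table in de_tables.items():
        n_rows += _write_tsv(table, de_dir / f"{contrast.label()}.tsv",
                             index_label="tfe_id")
    record("de", contrasts=len(de_tables), rows=n_rows)

    # --- markers ----------------------------------------------------------
    medians = mk.stage_medians(values, bundle.sheet)
    marker_set = mk.call_stage_markers(
        medians, de_tables,
        stage_order=tuple(bundle.sheet.stages_used()),
        stages=cfg.marker_stages,
        expr_threshold=th.expr_threshold,
        lfc_threshold=th.lfc_threshold,
        alpha=th.alpha,
    )
    _write_tsv(medians, out / "stage_medians.tsv", index_label="tfe_id")
    _write_tsv(marker_set.table, out / "markers.tsv")
    record("markers", markers=len(marker_set.table))

    # --- cluster ----------------------------------------------------------
    cluster_input = mk.scale_rows(values_pc.loc[selected])
    assignment = mk.kmeans_profiles(
        cluster_input, k=th.k, restarts=th.restarts, max_iter=th.max_iter,
        seed=cfg.seed,
    )
    _write_tsv(assignment.labels.to_frame(), out / "clusters.tsv",
               index_label="tfe_id")
    manifest["kmeans_wcss"] = assignment.wcss
    record("cluster", clustered=len(assignment.labels))

    # --- promoters --------------------------------------------------------
    ega_stage = cfg.marker_stages[-2] if len(cfg.marker_stages) >= 2 else \
        cfg.marker_stages[-1]
    target = marker_set.for_stage(ega_stage)
    windows = prom.promoter_windows(
        matrix.regions.loc[target], up=th.up, down=th.down,
        chrom_sizes=bundle.reference.chrom_sizes,
    )
    seqs = prom.extract_promoter_sequences(windows, bundle.reference.sequences)
    tio.write_bed(windows.assign(score=0), out / "promoters.bed",
                  chrom_sizes=bundle.reference.chrom_sizes)
    tio.write_fasta(seqs, out / "promoters.fa")
    record("promoters", windows=len(windows), stage_used=ega_stage)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
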