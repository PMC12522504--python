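"""Stage medians, stage-exclusive marker calling, row scaling, and k-means
temporal clustering.

A TFE is a marker of stage S when its stage-median log2 normalized value is
strictly above the expression threshold (default -10, roughly nine
molecule copies at the default spike-in calibration) in S and strictly
below it in every other stage, and the TFE is significantly upregulated
(BH-adjusted p < alpha, LFC > threshold) in the contrast of S against its
preceding stage.  The first stage has no preceding stage, so it is tested
against the following one instead (upregulation there means a negative LFC
in the later-vs-earlier table).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import SampleSheet
from .stats import Contrast

DEFAULT_MARKER_STAGES = ("GV", "MII", "16c", "Blc")


def stage_medians(values: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Per-TFE, per-stage median of log2 normalized values.

    Sentinel values (-inf) participate as ordinary lower-extreme numbers:
    the median of a stage whose lower middle value is a sentinel is itself
    the sentinel.
    """
    stage_of = pd.Series({s: sheet.stage_of(s) for s in values.columns})
    out = {}
    for stage in sheet.stages_used():
        cols = [s for s in values.columns if stage_of[s] == stage]
        if not cols:
            raise ValueError(f"stage {stage} has no samples")
        out[stage] = np.median(values[cols].to_numpy(), axis=1)
    med = pd.DataFrame(out, index=values.index)
    return med[list(sheet.stages_used())]


@dataclass
class MarkerSet:
    """Stage-exclusive marker TFEs with their supporting DE contrast."""

    table: pd.DataFrame  # index tfe_id: stage, contrast, lfc, padj

    def for_stage(self, stage: str) -> list[str]:
        return list(self.table.index[self.table["stage"] == stage])

    @property
    def stages(self) -> list[str]:
        return list(dict.fromkeys(self.table["stage"]))


def call_stage_markers(
    medians: pd.DataFrame,
    de_tables: dict[Contrast, pd.DataFrame],
    stage_order: tuple[str, ...],
    stages: tuple[str, ...] = DEFAULT_MARKER_STAGES,
    expr_threshold: float = -10.0,
    lfc_threshold: float = 3.0,
    alpha: float = 0.05,
) -> MarkerSet:
    """Call stage-exclusive markers for the requested stage subset.

    Exclusivity (above-threshold median in exactly the target stage) makes
    marker sets pairwise disjoint by construction.
    """
    by_label = {c: t for c, t in de_tables.items()}
    rows = []
    for stage in stages:
        if stage not in medians.columns:
            raise ValueError(f"stage {stage} missing from median matrix")
        i = stage_order.index(stage)
        if i == 0:
            if len(stage_order) < 2:
                raise ValueError("cannot test the only stage against a neighbor")
            contrast = Contrast(later=stage_order[1], earlier=stage)
            sign = -1.0  # upregulation in `stage` = negative later-vs-earlier LFC
        else:
            contrast = Contrast(later=stage, earlier=stage_order[i - 1])
            sign = 1.0
        if contrast not in by_label:
            raise ValueError(f"missing DE table for contrast {contrast.label()}")
        de = by_label[contrast]

        others = [c for c in medians.columns if c != stage]
        exclusive = (medians[stage] > expr_threshold) & (
            medians[others] < expr_threshold
        ).all(axis=1)
        candidates = medians.index[exclusive]
        de_hit = de.reindex(candidates)
        keep = (de_hit["padj"] < alpha) & (sign * de_hit["lfc"] > lfc_threshold)
        keep = keep.fillna(False)
        for tfe in candidates[keep.to_numpy()]:
            rows.append(
                (tfe, stage, contrast.label(), float(de.loc[tfe, "lfc"]),
                 float(de.loc[tfe, "padj"]))
            )
    table = pd.DataFrame(
        rows, columns=["tfe_id", "stage", "contrast", "lfc", "padj"]
    ).set_index("tfe_id")
    if table.index.has_duplicates:  # cannot happen via exclusivity; guard anyway
        raise AssertionError("marker assigned to more than one stage")
    return MarkerSet(table=table)


def scale_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row z-scores: per TFE subtract the mean and divide by the sample
    standard deviation.  Constant rows become all-zero with a warning."""
    vals = matrix.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("scale_rows requires finite values")
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s) scaled to zeros", stacklevel=2
        )
    sd[sd == 0] = 1.0
    return pd.DataFrame((vals - mean) / sd, index=matrix.index, columns=matrix.columns)


@dataclass
class ClusterAssignment:
    """k-means result: labels in 1..k, centers, WCSS, restart count."""

    labels: pd.Series
    centers: np.ndarray
    wcss: float
    restarts: int

    def recompute_wcss(self, data: pd.DataFrame) -> float:
        x = data.to_numpy(dtype=float)
        lab = self.labels.to_numpy() - 1
        return float(((x - self.centers[lab]) ** 2).sum())


def kmeans_profiles(
    scaled: pd.DataFrame,
    k: int = 6,
    restarts: int = 1000,
    max_iter: int = 20,
    seed: int = 0,
) -> ClusterAssignment:
    """Lloyd k-means with random row-sampled initial centers, best of
    ``restarts`` runs by WCSS; deterministic for a fixed seed."""
    if k > len(scaled):
        raise ValueError(f"k={k} exceeds number of rows {len(scaled)}")
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=restarts,
        max_iter=max_iter,
        algorithm="lloyd",
        random_state=int(seed) % (2**32),
    )
    labels = km.fit_predict(scaled.to_numpy(dtype=float))
    return ClusterAssignment(
        labels=pd.Series(labels + 1, index=scaled.index, name="cluster"),
        centers=km.cluster_centers_,
        wcss=float(km.inertia_),
        restarts=restarts,
    )
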