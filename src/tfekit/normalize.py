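"""Spike-in-anchored normalization and absolute-content calibration.

Size factors come from the median-of-ratios method restricted to spike-in
rows (the spike-in input per sample is constant, so systematic per-sample
depth differences are purely technical).  Log2 normalized values use the
convention

    value = log2( count / (size_factor * S_ref) )

with S_ref the mean total spike-in UMI count across samples, so a value of
0 corresponds to the per-sample spike-in yield and values are comparable
to molecule fractions of the spike-in input M.  A zero count with
pseudocount 0 maps to the sentinel ``-inf`` ("not expressed" at any finite
threshold).  With M molecules of spike-in input per sample, a value v
converts to an absolute estimate of ``2**v * M`` molecule copies; at the
default M = 9216 a value of -10 corresponds to exactly 9 copies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SENTINEL, CountMatrix, SampleSheet


def spikein_size_factors(matrix: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors computed on spike-in rows only.

    Per sample: median over usable spike-ins of count / geometric mean of
    that spike-in's counts across samples; then rescaled to geometric mean
    1 across samples.  Spike-ins with a zero count in any sample are
    excluded (their log geometric mean is undefined); at least two must
    remain.
    """
    sp = matrix.spikeins()
    if sp.empty:
        raise ValueError("no spike-in rows in matrix")
    all_zero = sp.sum(axis=0) == 0
    if all_zero.any():
        raise ValueError(
            f"sample with all-zero spike-in counts: {sp.columns[all_zero][0]}"
        )
    usable = sp.loc[(sp > 0).all(axis=1)]
    if len(usable) < 2:
        raise ValueError(
            f"need >= 2 spike-ins with nonzero counts in every sample, "
            f"got {len(usable)}"
        )
    log_counts = np.log(usable.to_numpy(dtype=float))
    log_geomean = log_counts.mean(axis=1, keepdims=True)
    ratios = np.exp(log_counts - log_geomean)
    factors = pd.Series(np.median(ratios, axis=0), index=sp.columns, name="size_factor")
    factors /= np.exp(np.log(factors).mean())  # geometric mean 1
    if not np.isfinite(factors).all() or (factors <= 0).any():
        raise ValueError("non-finite or non-positive size factor")
    return factors


def spikein_reference_total(matrix: CountMatrix) -> float:
    """S_ref: mean total spike-in UMI count across samples."""
    return float(matrix.spikeins().sum(axis=0).mean())


def log2_normalize(
    matrix: CountMatrix,
    factors: pd.Series,
    pseudocount: float = 0.0,
    s_ref: float | None = None,
) -> pd.DataFrame:
    """Log2 spike-in-normalized values; see module docstring for the
    convention.  Strictly increasing in counts for a fixed sample."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if s_ref is None:
        s_ref = spikein_reference_total(matrix)
    if s_ref <= 0:
        raise ValueError("spike-in reference total must be > 0")
    f = factors.reindex(matrix.sample_ids)
    if f.isna().any():
        raise ValueError("size factors missing for some samples")
    denom = f.to_numpy() * s_ref
    with np.errstate(divide="ignore"):
        vals = np.log2((matrix.counts.to_numpy(dtype=float) + pseudocount) / denom)
    return pd.DataFrame(vals, index=matrix.counts.index, columns=matrix.sample_ids)


def relative_rna_content(
    matrix: CountMatrix,
    sheet: SampleSheet,
    reference_stage: str = "GV",
) -> pd.Series:
    """Per-stage poly(A)-tailed RNA content relative to a reference stage.

    Per sample: endogenous (non-spike-in) total / spike-in total; the
    ratios are averaged by stage and divided by the reference stage's
    average (reference = 1 by construction).
    """
    spike_tot = matrix.spikeins().sum(axis=0)
    if (spike_tot == 0).any():
        raise ValueError(
            f"sample with zero spike-in total: {spike_tot.index[spike_tot == 0][0]}"
        )
    ratio = matrix.endogenous().sum(axis=0) / spike_tot
    stage_of = pd.Series({s: sheet.stage_of(s) for s in ratio.index})
    by_stage = ratio.groupby(stage_of).mean().reindex(sheet.stages_used())
    if reference_stage not in by_stage.index:
        raise ValueError(f"reference stage {reference_stage!r} has no samples")
    out = by_stage / by_stage[reference_stage]
    out.name = "relative_content"
    return out


@dataclass
class SpikeCalibration:
    """Links normalized values to absolute molecule copies.

    M is the spike-in molecule input per sample; eta is the per-sample
    capture efficiency estimate (spike-in UMI count / M).
    """

    M: float
    eta: pd.Series

    def __post_init__(self) -> None:
        if self.M <= 0:
            raise ValueError("M must be > 0")


def calibrate(matrix: CountMatrix, molecules_per_sample: float) -> SpikeCalibration:
    eta = matrix.spikeins().sum(axis=0) / molecules_per_sample
    return SpikeCalibration(M=float(molecules_per_sample), eta=eta)


def value_to_copies(value, calibration: SpikeCalibration):
    """Estimated molecule copies for a finite log2 normalized value."""
    arr = np.asarray(value, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("cannot estimate copies for sentinel / non-finite values")
    out = 2.0**arr * calibration.M
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


def copies_to_value(copies, calibration: SpikeCalibration):
    """Inverse of :func:`value_to_copies` (exact round-trip)."""
    arr = np.asarray(copies, dtype=float)
    if (arr <= 0).any():
        raise ValueError("copies must be > 0")
    out = np.log2(arr / calibration.M)
    return float(out) if np.isscalar(copies) or arr.ndim == 0 else out


def is_expressed(values: pd.DataFrame, threshold: float = -10.0) -> pd.DataFrame:
    """Strictly-above-threshold expression mask (sentinel is never expressed)."""
    return values > threshold


SENTINEL_VALUE = SENTINEL
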