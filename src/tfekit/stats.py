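"""Technical-noise modelling, variable-TFE selection, correlations, and
negative-binomial Wald differential expression between consecutive stages.

The technical-noise model is the spike-in CV^2-vs-mean relation

    CV2_tech(mu) = a1 / mu + a0

fitted by a gamma GLM with identity link (ordinary least squares fallback
when IRLS fails).  A TFE's observed CV^2 is then compared against the
technical expectation with the statistic T = (n-1) CV2 / CV2_tech(mu),
referred to a chi-square distribution with n-1 degrees of freedom; small
upper-tail p-values indicate excess (biological) variability.

The DE core is a deliberately transparent negative-binomial Wald test:
per-TFE method-of-moments dispersion on normalized counts pooled within
groups, delta-method standard error of the log2 fold change, and a
t reference with n1+n2-2 degrees of freedom (a small-sample adjustment;
the dispersion estimate has few degrees of freedom at this design).  No
dispersion shrinkage, LFC shrinkage, independent filtering or outlier
handling is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import CountMatrix, SampleSheet
from .normalize import log2_normalize

log = logging.getLogger(__name__)

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# technical noise
# ---------------------------------------------------------------------------

@dataclass
class NoiseFit:
    """CV2_tech(mu) = a1/mu + a0 fitted on spike-ins."""

    a0: float
    a1: float
    n_points: int
    used_fallback: bool = False

    def technical_cv2(self, mu):
        return self.a1 / np.asarray(mu, dtype=float) + self.a0


def spikein_noise_points(matrix: CountMatrix, factors: pd.Series) -> pd.DataFrame:
    """Mean and CV^2 of size-factor-normalized counts per spike-in."""
    q = matrix.spikeins().to_numpy(dtype=float) / factors.reindex(
        matrix.sample_ids
    ).to_numpy()
    mu = q.mean(axis=1)
    var = q.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(mu > 0, var / mu**2, np.nan)
    return pd.DataFrame({"mu": mu, "cv2": cv2}, index=matrix.spikeins().index)


def fit_technical_noise(mu, cv2) -> NoiseFit:
    """Fit CV2 ~ a1/mu + a0 (gamma GLM, identity link; Brennecke-style).

    Requires >= 10 usable spike-in points (mu > 0, finite positive CV^2).
    Falls back to ordinary least squares when the IRLS fit fails, with the
    fallback logged and flagged on the result.
    """
    mu = np.asarray(mu, dtype=float)
    cv2 = np.asarray(cv2, dtype=float)
    ok = (mu > 0) & np.isfinite(cv2) & (cv2 > 0)
    mu, cv2 = mu[ok], cv2[ok]
    if len(mu) < 10:
        raise ValueError(f"need >= 10 usable spike-ins, got {len(mu)}")
    X = sm.add_constant(1.0 / mu)  # columns: intercept (a0), 1/mu (a1)
    fallback = False
    try:
        import warnings

        with warnings.catch_warnings():
            # identity link on the gamma family is intentional (Brennecke-style)
            warnings.simplefilter("ignore")
            model = sm.GLM(
                cv2, X, family=sm.families.Gamma(link=sm.families.links.Identity())
            )
            res = model.fit(start_params=np.linalg.lstsq(X, cv2, rcond=None)[0])
        if not np.all(np.isfinite(res.params)):
            raise ValueError("non-finite GLM parameters")
        a0, a1 = res.params
    except Exception as exc:  # IRLS failure -> OLS fallback
        log.warning("gamma GLM failed (%s); falling back to OLS", exc)
        fallback = True
        a0, a1 = np.linalg.lstsq(X, cv2, rcond=None)[0]
    return NoiseFit(a0=float(a0), a1=float(a1), n_points=len(mu),
                    used_fallback=fallback)


def variability_test(mu, cv2, fit: NoiseFit, n_samples: int):
    """Upper-tail chi-square p-value for excess variability.

    T = (n-1) CV2 / CV2_tech(mu) ~ chi2(n-1) under purely technical noise.
    """
    if n_samples < 3:
        raise ValueError("need n >= 3 samples")
    mu = np.asarray(mu, dtype=float)
    cv2 = np.asarray(cv2, dtype=float)
    tech = fit.technical_cv2(mu)
    if np.any(tech <= 0):
        raise ValueError("technical CV2 <= 0 at some mean; fit unusable there")
    T = (n_samples - 1) * cv2 / tech
    p = sps.chi2.sf(T, df=n_samples - 1)
    return float(p) if np.isscalar(mu) or p.ndim == 0 else p


def variability_table(
    matrix: CountMatrix, factors: pd.Series, fit: NoiseFit
) -> pd.DataFrame:
    """Per-TFE mean, CV^2, p and BH-adjusted p for all non-spike-in TFEs
    with nonzero total count."""
    endo = matrix.endogenous()
    endo = endo.loc[endo.sum(axis=1) > 0]
    q = endo.to_numpy(dtype=float) / factors.reindex(matrix.sample_ids).to_numpy()
    mu = q.mean(axis=1)
    var = q.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(mu > 0, var / mu**2, 0.0)
    p = variability_test(mu, cv2, fit, n_samples=q.shape[1])
    out = pd.DataFrame({"mu": mu, "cv2": cv2, "pvalue": p}, index=endo.index)
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def select_top_variable(
    table: pd.DataFrame, k: int = 20_000, alpha: float = 0.05
) -> list[str]:
    """Top-K TFE ids by CV^2 among those with adjusted p < alpha.

    Ties in CV^2 break by TFE id, so selection is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sig = table.loc[table["padj"] < alpha]
    sig = sig.iloc[np.lexsort((sig.index, -sig["cv2"].to_numpy()))]
    return list(sig.index[:k])


def pairwise_correlation(values: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Pearson correlation of (finite) normalized values.

    Zero-variance samples yield NaN entries rather than a silent 0.
    """
    if values.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    if not np.isfinite(values.to_numpy()).all():
        raise ValueError(
            "values contain sentinels; use the pseudocount normalization variant"
        )
    return values.corr(method="pearson")


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contrast:
    """later-vs-earlier comparison of two consecutive developmental stages."""

    later: str
    earlier: str

    def label(self) -> str:
        return f"{self.later}_vs_{self.earlier}"


def consecutive_contrasts(stage_order: tuple[str, ...]) -> list[Contrast]:
    """The fixed later-vs-earlier ladder, e.g. MII|GV, 2c|MII, ..., Blc|16c."""
    return [Contrast(later=b, earlier=a) for a, b in zip(stage_order, stage_order[1:])]


def nb_wald_contrast(
    matrix: CountMatrix,
    factors: pd.Series,
    contrast: Contrast,
    sheet: SampleSheet,
    alpha: float = 0.05,
    dispersion_floor: float = 1e-8,
) -> pd.DataFrame:
    """Negative-binomial Wald test for one consecutive-stage contrast.

    Returns a per-TFE table (non-spike-in rows with nonzero counts in the
    contrast) with log2 fold change (later vs earlier), standard error,
    Wald statistic, two-sided p, BH-adjusted p, and a direction column
    (up/down/ns at the given alpha).
    """
    a_samples = sheet.samples_for(contrast.earlier)
    b_samples = sheet.samples_for(contrast.later)
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError(
            f"contrast {contrast.label()} needs >= 2 samples per stage, got "
            f"{len(a_samples)} vs {len(b_samples)}"
        )
    idx = ~matrix.spike_mask
    counts = matrix.counts.loc[idx, a_samples + b_samples]
    counts = counts.loc[counts.sum(axis=1) > 0]
    f = factors.reindex(a_samples + b_samples).to_numpy()
    q = counts.to_numpy(dtype=float) / f
    nA, nB = len(a_samples), len(b_samples)
    qA, qB = q[:, :nA], q[:, nA:]

    mA, mB = qA.mean(axis=1), qB.mean(axis=1)
    sA = qA.var(axis=1, ddof=1)
    sB = qB.var(axis=1, ddof=1)

    positive = q[q > 0]
    if positive.size == 0:
        raise ValueError("no positive counts in contrast")
    offset = 0.5 * positive.min()
    mA_off, mB_off = mA + offset, mB + offset

    # method-of-moments dispersion: E[s2_pooled] = avg_g(m_g + alpha m_g^2)
    pooled_var = ((nA - 1) * sA + (nB - 1) * sB) / (nA + nB - 2)
    mean_m = (nA * mA + nB * mB) / (nA + nB)
    mean_m2 = (nA * mA**2 + nB * mB**2) / (nA + nB)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean_m2 > 0, (pooled_var - mean_m) / mean_m2, 0.0)
    disp = np.clip(disp, dispersion_floor, None)

    lfc = np.log2(mB_off / mA_off)
    varA = (mA_off + disp * mA_off**2) / nA
    varB = (mB_off + disp * mB_off**2) / nB
    se = np.sqrt(varA / mA_off**2 + varB / mB_off**2) / LN2
    stat = lfc / se
    p = 2.0 * sps.t.sf(np.abs(stat), df=nA + nB - 2)
    p = np.minimum(p, 1.0)

    out = pd.DataFrame(
        {
            "baseMean": (mA * nA + mB * nB) / (nA + nB),
            "lfc": lfc,
            "se": se,
            "stat": stat,
            "pvalue": p,
        },
        index=counts.index,
    )
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    out["direction"] = "ns"
    out.loc[(out["padj"] < alpha) & (out["lfc"] > 0), "direction"] = "up"
    out.loc[(out["padj"] < alpha) & (out["lfc"] < 0), "direction"] = "down"
    return out


def de_all_contrasts(
    matrix: CountMatrix,
    factors: pd.Series,
    sheet: SampleSheet,
    alpha: float = 0.05,
) -> dict[Contrast, pd.DataFrame]:
    """Run the full consecutive-stage ladder in fixed developmental order."""
    return {
        c: nb_wald_contrast(matrix, factors, c, sheet, alpha=alpha)
        for c in consecutive_contrasts(tuple(sheet.stages_used()))
    }


def hvt_correlation(
    matrix: CountMatrix,
    factors: pd.Series,
    fit: NoiseFit,
    k: int = 20_000,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> tuple[list[str], pd.DataFrame]:
    """Select top variable TFEs and compute the sample correlation matrix
    on their pseudocount log2 normalized values."""
    table = variability_table(matrix, factors, fit)
    selected = select_top_variable(table, k=k, alpha=alpha)
    values = log2_normalize(matrix, factors, pseudocount=pseudocount)
    return selected, pairwise_correlation(values.loc[selected])
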