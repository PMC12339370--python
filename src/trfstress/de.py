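"""Prefiltering, median-of-ratios normalization and a simplified NB Wald test.

The differential-expression stage estimates, per feature, a stress-vs-control
log2 fold change with a Wald test under a negative-binomial model with
sample-specific size-factor offsets.  Dispersion is estimated per feature by
method-of-moments and shrunk toward a fitted mean-dispersion trend — a
deliberately simplified take on the DESeq2 approach.  The downstream family
trend analysis needs only signs and significance, and the pipeline accepts an
externally produced DE table in the same schema for real-data runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DE_COLUMNS = ["id", "baseMean", "log2FC", "stat", "pvalue", "padj"]


def prefilter(
    counts: pd.DataFrame, smallest_group_size: int, min_count: int = 10
) -> pd.DataFrame:
    """Keep features with ``count >= min_count`` in at least
    ``smallest_group_size`` samples (the rowSums(counts >= 10) >= n rule)."""
    if smallest_group_size > counts.shape[1]:
        raise ValueError(
            f"smallest_group_size={smallest_group_size} exceeds "
            f"{counts.shape[1]} samples"
        )
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    keep = (counts >= min_count).sum(axis=1) >= smallest_group_size
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample, the median over all-positive features of
    count / geometric-row-mean.  Errors if no feature is positive in every
    sample (a pseudo-reference fallback would then be needed).
    """
    x = counts.to_numpy(dtype=float)
    allpos = (x > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no feature with nonzero counts in every sample; "
            "median-of-ratios undefined (consider a pseudo-reference)"
        )
    logx = np.log(x[allpos])
    log_gm = logx.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logx - log_gm, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs pass through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------

def _moment_dispersions(
    x: np.ndarray, sf: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments per-feature dispersion from normalized counts.

    Uses the within-group pooled variance of normalized counts; the Poisson
    (shot-noise) part mu * mean(1/s) is subtracted before dividing by mu^2.
    Returns (dispersion, base mean).
    """
    norm = x / sf[None, :]
    mu_all = norm.mean(axis=1)
    num = np.zeros(x.shape[0])
    den = 0
    for g in np.unique(groups):
        cols = groups == g
        n_g = cols.sum()
        if n_g < 2:
            continue
        v = norm[:, cols].var(axis=1, ddof=1)
        num += (n_g - 1) * v
        den += n_g - 1
    pooled_var = num / max(den, 1)
    shot = mu_all * np.mean(1.0 / sf)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (pooled_var - shot) / mu_all**2
    return np.clip(np.nan_to_num(phi, nan=1e-8), 1e-8, 10.0), mu_all


def _trend_fit(phi: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Fit the parametric trend phi(mu) = a0 + a1/mu on informative features."""
    ok = (phi > 1e-6) & (mu > 0)
    if ok.sum() < 10:
        return np.full_like(phi, max(np.median(phi), 1e-4))
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    # One reweighted pass downweights outlying raw dispersions.
    coef, *_ = np.linalg.lstsq(X, phi[ok], rcond=None)
    fitted = X @ coef
    resid = np.abs(phi[ok] - fitted)
    w = 1.0 / (1.0 + (resid / np.maximum(np.median(resid), 1e-12)) ** 2)
    coef, *_ = np.linalg.lstsq(X * w[:, None], phi[ok] * w, rcond=None)
    a0, a1 = max(coef[0], 1e-6), max(coef[1], 0.0)
    return a0 + a1 / np.maximum(mu, 1e-8)


def shrink_dispersions(
    phi_mom: np.ndarray, mu: np.ndarray, weight: float = 0.5
) -> np.ndarray:
    """Shrink log method-of-moments dispersions toward the fitted trend."""
    trend = _trend_fit(phi_mom, mu)
    log_phi = (1 - weight) * np.log(np.maximum(phi_mom, 1e-8)) + weight * np.log(trend)
    return np.exp(log_phi)


# ---------------------------------------------------------------------------
# NB GLM with a two-level group factor (vectorized across features)
# ---------------------------------------------------------------------------

def _fit_group_logmean(
    y: np.ndarray, s: np.ndarray, phi: np.ndarray, n_iter: int = 50
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature NB MLE of the group log-mean with offsets log(s).

    Model: y_ij ~ NB(mean = exp(b_i) * s_j, dispersion phi_i).  Fisher
    scoring on the score sum_j (y - mu) / (1 + phi mu).  Returns
    (b, fisher_information, moderated_flag); all-zero features fall back to
    a moderated estimate with a 0.5 pseudo-total.
    """
    tot = y.sum(axis=1)
    moderated = tot == 0
    start = np.where(moderated, 0.5, tot) / s.sum()
    b = np.log(start)
    for _ in range(n_iter):
        mu = np.exp(b)[:, None] * s[None, :]
        w = 1.0 + phi[:, None] * mu
        score = ((y - mu) / w).sum(axis=1)
        info = (mu / w).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        b = b + step
        if np.max(np.abs(step)) < 1e-12:
            break
    mu = np.exp(b)[:, None] * s[None, :]
    info = (mu / (1.0 + phi[:, None] * mu)).sum(axis=1)
    return b, info, moderated


def nb_wald_de(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    group_col: str = "group",
    levels: tuple[str, str] = ("stress", "control"),
    subset: tuple[str, str] | None = None,
    alpha: float = 0.05,
    dispersion_weight: float = 0.5,
) -> pd.DataFrame:
    """Per-feature NB Wald differential expression for one contrast.

    ``levels`` is (numerator, denominator): positive log2FC means higher in
    the first level.  ``subset`` optionally restricts samples first, e.g.
    ``("sex", "F")`` for the female-only contrast.  Returns a DataFrame with
    columns ``id, baseMean, log2FC, stat, pvalue, padj, significant``;
    features whose fit was moderated (a group with all-zero counts) keep
    their moderated log2FC but get ``pvalue = NaN`` and are excluded from
    the FDR.
    """
    meta = metadata.set_index("sample_id").loc[counts.columns]
    if subset is not None:
        col, val = subset
        keep = meta[col] == val
        meta = meta[keep]
        counts = counts.loc[:, keep.to_numpy()]
    groups = meta[group_col].to_numpy()
    for lev in levels:
        if (groups == lev).sum() < 2:
            raise ValueError(
                f"contrast level {lev!r} has fewer than 2 samples after filtering"
            )

    x = counts.to_numpy(dtype=float)
    sf = size_factors(counts).to_numpy()
    phi_mom, mu_all = _moment_dispersions(x, sf, groups)
    phi = shrink_dispersions(phi_mom, mu_all, weight=dispersion_weight)

    a_cols, b_cols = groups == levels[0], groups == levels[1]
    b_a, info_a, mod_a = _fit_group_logmean(x[:, a_cols], sf[a_cols], phi)
    b_b, info_b, mod_b = _fit_group_logmean(x[:, b_cols], sf[b_cols], phi)
    moderated = mod_a | mod_b

    delta = b_a - b_b
    se = np.sqrt(1.0 / np.maximum(info_a, 1e-12) + 1.0 / np.maximum(info_b, 1e-12))
    stat = delta / se
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))
    pvalue = np.where(moderated, np.nan, pvalue)
    out = pd.DataFrame(
        {
            "id": counts.index,
            "baseMean": mu_all,
            "log2FC": delta / np.log(2.0),
            "stat": np.where(moderated, np.nan, stat),
            "pvalue": pvalue,
        }
    )
    out["padj"] = bh_fdr(out["pvalue"].to_numpy())
    out["significant"] = out["padj"] <= alpha
    out["moderated"] = moderated
    return out


def read_de_table(path) -> pd.DataFrame:
    """Read an externally produced DE table (e.g. a DESeq2 export)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if "significant" not in df.columns:
        df["significant"] = df["padj"] <= 0.05
    return df


def write_de_table(de: pd.DataFrame, path) -> None:
    de.loc[:, DE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")
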