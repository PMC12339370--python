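"""Directional family-trend statistics and family length-distribution analysis.

A tRF family's members are produced together by the same nucleases and often
shift together under stress.  Per-feature differential expression treats each
fragment independently and can miss a coherent family-wide drift; the exact
binomial sign test below asks instead whether the fraction of members with a
negative fold change departs from the 1/2 expected under no directional
preference.  Family-level length structure is summarized by expression-
weighted mean fragment lengths compared across the four stress-by-sex groups
with a Kruskal-Wallis test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import FamilyIndex, TRFAnnotation
from .de import bh_fdr

logger = logging.getLogger(__name__)


def exact_binomial_test(n: int, k: int, sided: str = "two") -> float:
    """Exact binomial test of k successes in n trials against p = 1/2.

    Two-sided p is the central method, ``min(1, 2 * min(P(X<=k), P(X>=k)))``;
    with a symmetric null this coincides with the minimum-likelihood method.
    ``sided='greater'`` gives P(X >= k) — the one-sided test for a downward
    trend when k counts members with negative fold change — and
    ``sided='less'`` the opposite tail.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    if sided == "two":
        return float(min(1.0, 2.0 * min(lower, upper)))
    if sided == "greater":
        return float(upper)
    if sided == "less":
        return float(lower)
    raise ValueError(f"unknown sidedness {sided!r}")


def family_direction_counts(
    de: pd.DataFrame, index: FamilyIndex
) -> pd.DataFrame:
    """Count, per family, members with a defined nonzero log2FC and how many
    are negative.

    Features with zero or missing log2FC carry no direction for a sign test;
    they are excluded from ``n`` and logged.  Every DE feature must belong to
    the index.
    """
    fam_of = index.family_of()
    missing = [i for i in de["id"] if i not in fam_of]
    if missing:
        raise ValueError(f"features absent from family index: {missing[:10]}")
    lfc = de.set_index("id")["log2FC"]
    dropped = lfc.index[~np.isfinite(lfc) | (lfc == 0)]
    if len(dropped):
        logger.info("excluding %d features with zero/undefined log2FC", len(dropped))
    rows = []
    for key in index.families:
        members = [m for m in index.members[key] if m in lfc.index]
        vals = lfc.loc[members]
        defined = vals[np.isfinite(vals) & (vals != 0)]
        rows.append(
            {
                "family": str(key),
                "origin": key.genome_origin,
                "amino_acid": key.amino_acid,
                "cleavage_type": key.cleavage_type,
                "n": int(defined.shape[0]),
                "k_down": int((defined < 0).sum()),
                "testable": index.testable(key),
            }
        )
    return pd.DataFrame(rows)


def family_trend_table(
    de: pd.DataFrame,
    index: FamilyIndex,
    alpha: float = 0.05,
    sided: str = "two",
) -> pd.DataFrame:
    """Exact binomial trend test per family with BH FDR across testable
    families.

    ``direction`` is 'down' when FDR <= alpha and more than half the members
    fell, 'up' when FDR <= alpha and fewer than half fell, else 'none'.  The
    signed size column (``n`` with the direction's sign) is bar-plot ready.
    """
    table = family_direction_counts(de, index)
    testable = table["testable"] & (table["n"] >= 1)
    pvals = np.full(len(table), np.nan)
    for i, row in table.iterrows():
        if testable[i]:
            pvals[i] = exact_binomial_test(row["n"], row["k_down"], sided=sided)
    table["prop_down"] = np.where(table["n"] > 0, table["k_down"] / table["n"], np.nan)
    table["pvalue"] = pvals
    table["padj"] = bh_fdr(pvals)
    sig = table["padj"] <= alpha
    table["direction"] = np.select(
        [sig & (table["prop_down"] > 0.5), sig & (table["prop_down"] < 0.5)],
        ["down", "up"],
        default="none",
    )
    table["signed_size"] = np.where(
        table["prop_down"] > 0.5, -table["n"], table["n"]
    )
    return table


# ---------------------------------------------------------------------------
# Length-distribution analysis
# ---------------------------------------------------------------------------

MIR_LENGTH_WINDOW = (16, 28)  # miRbase-typical miR lengths


def mean_length_profile(
    counts_normalized: pd.DataFrame,
    annotations: list[TRFAnnotation],
    groups: pd.Series,
) -> tuple[pd.DataFrame, pd.Series]:
    """Mean normalized expression summed per fragment length (16-50 nt).

    For each group: per sample, total normalized counts at each length, then
    the mean across the group's samples.  Also returns, per group, the
    fraction of total signal within the 16-28 nt miR-length window.
    """
    lengths = pd.Series({a.id: a.length for a in annotations})
    if not lengths.between(16, 50).all():
        raise ValueError("fragment lengths outside 16-50 nt")
    grid = np.arange(16, 51)
    per_len = counts_normalized.groupby(lengths.reindex(counts_normalized.index)).sum()
    per_len = per_len.reindex(grid, fill_value=0.0)
    profile = per_len.T.groupby(groups.reindex(per_len.columns)).mean().T
    profile.index.name = "length"
    lo, hi = MIR_LENGTH_WINDOW
    total = profile.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mir_frac = profile.loc[lo:hi].sum(axis=0) / total.where(total > 0)
    return profile, mir_frac.rename("mir_window_fraction")


def weighted_mean_lengths(
    counts_normalized: pd.DataFrame,
    annotations: list[TRFAnnotation],
    index: FamilyIndex,
) -> pd.DataFrame:
    """Per family x sample expression-weighted mean member length.

    Weights are size-factor-normalized counts; samples with zero family
    signal get NaN.
    """
    lengths = pd.Series({a.id: a.length for a in annotations})
    rows = {}
    for key in index.families:
        members = [m for m in index.members[key] if m in counts_normalized.index]
        if not members:
            continue
        w = counts_normalized.loc[members]
        tot = w.sum(axis=0)
        wl = (w.mul(lengths.loc[members], axis=0)).sum(axis=0) / tot.where(tot > 0)
        rows[str(key)] = wl
    out = pd.DataFrame(rows).T
    out.index.name = "family"
    return out


def kw_family_length(
    counts_normalized: pd.DataFrame,
    annotations: list[TRFAnnotation],
    index: FamilyIndex,
    groups: pd.Series,
) -> pd.DataFrame:
    """Kruskal-Wallis test of family weighted mean lengths across groups.

    ``groups`` maps sample -> one of the four stress-by-sex groups.  All-tied
    values yield H = 0, p = 1 (not an error).  BH FDR across families.
    """
    if groups.nunique() < 2:
        raise ValueError("need at least 2 non-empty groups")
    wml = weighted_mean_lengths(counts_normalized, annotations, index)
    rows = []
    for fam, vals in wml.iterrows():
        key_members = index.members[[k for k in index.families if str(k) == fam][0]]
        if len(key_members) < 2:
            continue
        by_group = [
            vals[groups[groups == g].index].dropna().to_numpy()
            for g in sorted(groups.unique())
        ]
        by_group = [v for v in by_group if len(v) > 0]
        flat = np.concatenate(by_group)
        if len(by_group) < 2 or np.all(flat == flat[0]):
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*by_group)
        rows.append({"family": fam, "H": float(h), "pvalue": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = bh_fdr(out["pvalue"].to_numpy())
    return out
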