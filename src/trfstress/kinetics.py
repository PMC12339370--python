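"""Ellman-assay cholinesterase kinetics and the associated group statistics.

Serum samples (diluted 1:20) hydrolyze the Ellman substrate; absorbance at
436 nm is read over 21 one-minute kinetic cycles under three conditions:
no inhibitor (total cholinesterase), iso-OMPA (BChE inhibited, isolating
AChE) and BW284c51 (AChE inhibited, isolating BChE).  The catalytic rate is
the OLS slope of the trace, in mOD/min scaled by the dilution factor.
Negative blank-corrected slopes can occur with noise and are reported but
flagged rather than clipped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_fdr

logger = logging.getLogger(__name__)

CONDITIONS = ("uninhibited", "iso-OMPA", "BW284c51")
N_CYCLES = 21


@dataclass
class KineticTrace:
    """One sample x condition absorbance trace (21 one-minute cycles)."""

    sample_id: str
    role: str                       # 'mother' or 'newborn'
    condition: str                  # one of CONDITIONS
    readings: np.ndarray            # 21 absorbance values (OD)
    dilution: float = 20.0

    def __post_init__(self) -> None:
        self.readings = np.asarray(self.readings, dtype=float)
        if self.readings.shape != (N_CYCLES,):
            raise ValueError(
                f"{self.sample_id}/{self.condition}: expected {N_CYCLES} readings, "
                f"got {self.readings.shape}"
            )
        if not np.isfinite(self.readings).all():
            raise ValueError(f"{self.sample_id}/{self.condition}: non-finite readings")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.dilution <= 0:
            raise ValueError("dilution must be positive")


@dataclass
class ActivityResult:
    """Per-sample catalytic rates (mOD/min x dilution) and diagnostics."""

    sample_id: str
    role: str
    ache: float | None = None
    bche: float | None = None
    total: float | None = None
    r2: dict = field(default_factory=dict)
    additivity_gap: float | None = None
    flags: list[str] = field(default_factory=list)


def fit_slope(
    trace: KineticTrace, window: tuple[int, int] | None = None
) -> tuple[float, float]:
    """OLS slope of the trace in mOD/min scaled by dilution, plus fit R².

    ``window`` is an inclusive (start, end) cycle range, 1-based; default all
    21 cycles.  A perfectly constant trace has rate 0 with R² = 1 by the
    zero-residual convention.
    """
    y = trace.readings
    t = np.arange(N_CYCLES, dtype=float)  # minutes
    if window is not None:
        lo, hi = window
        if not (1 <= lo <= hi <= N_CYCLES):
            raise ValueError(f"window {window} outside [1, {N_CYCLES}]")
        sel = slice(lo - 1, hi)
        y, t = y[sel], t[sel]
    if len(y) < 3:
        raise ValueError("need at least 3 points to fit a slope")
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float((resid**2).sum())
    r2 = 1.0 if ss_tot == 0 or math.isclose(ss_res, 0.0, abs_tol=1e-30) else 1 - ss_res / ss_tot
    rate = slope * 1000.0 * trace.dilution  # OD/min -> mOD/min, dilution-corrected
    return float(rate), float(r2)


def compute_activities(
    traces: list[KineticTrace], window: tuple[int, int] | None = None
) -> ActivityResult:
    """AChE/BChE/total rates for one sample from its three condition traces.

    AChE is the iso-OMPA slope, BChE the BW284c51 slope, total the
    uninhibited slope.  Missing conditions give a partial result with the
    absent fields None and a flag.  The additivity diagnostic
    |total - (AChE + BChE)| / total is reported when all three are present.
    """
    by_cond = {t.condition: t for t in traces}
    sample_ids = {t.sample_id for t in traces}
    roles = {t.role for t in traces}
    if len(sample_ids) != 1 or len(roles) != 1:
        raise ValueError("traces must belong to a single sample")
    dilutions = {t.dilution for t in traces}
    if len(dilutions) > 1:
        logger.warning("%s: mixed dilution factors %s", sample_ids, dilutions)
    res = ActivityResult(sample_id=sample_ids.pop(), role=roles.pop())
    mapping = {"iso-OMPA": "ache", "BW284c51": "bche", "uninhibited": "total"}
    for cond, attr in mapping.items():
        if cond in by_cond:
            rate, r2 = fit_slope(by_cond[cond], window)
            setattr(res, attr, rate)
            res.r2[cond] = r2
            if rate < 0:
                res.flags.append(f"negative rate under {cond}")
        else:
            res.flags.append(f"missing condition {cond}")
    if res.ache is not None and res.bche is not None and res.total:
        res.additivity_gap = abs(res.total - (res.ache + res.bche)) / abs(res.total)
    return res


def traces_from_long(df: pd.DataFrame) -> dict[str, list[KineticTrace]]:
    """Group a long kinetics table into per-sample trace lists.

    Expected columns: ``sample_id, role, condition, cycle, absorbance`` and
    optionally ``dilution``.
    """
    out: dict[str, list[KineticTrace]] = {}
    for (sid, role, cond), sub in df.groupby(["sample_id", "role", "condition"]):
        sub = sub.sort_values("cycle")
        dil = float(sub["dilution"].iloc[0]) if "dilution" in sub.columns else 20.0
        out.setdefault(sid, []).append(
            KineticTrace(sid, role, cond, sub["absorbance"].to_numpy(), dilution=dil)
        )
    return out


def iqr_filter(values: np.ndarray) -> np.ndarray:
    """Drop values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation between order statistics.  With fewer
    than 4 values no filtering is applied (warned).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        logger.warning("iqr_filter: n=%d < 4, returning input unfiltered", len(x))
        return x
    q1, q3 = np.percentile(x, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return x[(x >= lo) & (x <= hi)]


def group_compare(
    a: np.ndarray, b: np.ndarray, paired: bool = False
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (unpaired) or Wilcoxon signed-rank (paired).

    Exact null distributions for small samples without ties, otherwise the
    normal approximation with tie/continuity corrections (scipy's 'auto').
    Identical paired vectors (no informative pairs) give p = 1.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison needs equal lengths")
        d = a - b
        if np.all(d == 0):
            return 0.0, 1.0
        res = stats.wilcoxon(a, b, alternative="two-sided", zero_method="wilcox")
        return float(res.statistic), float(res.pvalue)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both groups need at least one value")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def dyad_ratio(
    newborn: ActivityResult, mother: ActivityResult, enzyme: str
) -> float | None:
    """Newborn / mother activity ratio for one enzyme ('ache' or 'bche').

    Non-positive rates cannot form a meaningful ratio and are excluded
    (returns None with a log line).  A ratio of 1 means equal activities.
    """
    nb, mo = getattr(newborn, enzyme), getattr(mother, enzyme)
    if nb is None or mo is None or nb <= 0 or mo <= 0:
        logger.info(
            "dyad %s/%s excluded for %s: non-positive or missing rate",
            newborn.sample_id, mother.sample_id, enzyme,
        )
        return None
    return float(nb / mo)


def ratio_vs_one_test(ratios: np.ndarray) -> tuple[float, float]:
    """Wilcoxon signed-rank of log-ratios against 0 (ratio against 1)."""
    logr = np.log(np.asarray(ratios, dtype=float))
    if np.all(logr == 0):
        return 0.0, 1.0
    res = stats.wilcoxon(logr, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def activity_trf_correlation(
    activities: pd.Series, trf_levels: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Spearman correlation between an activity and selected tRF levels.

    ``pairs`` lists (activity label, trf id); samples are matched on index.
    Constant vectors leave rho undefined (flagged NaN).  BH FDR across the
    tested pairs.
    """
    rows = []
    for label, trf in pairs:
        x = activities.dropna()
        y = trf_levels.loc[trf].reindex(x.index).dropna()
        x = x.reindex(y.index)
        if len(x) < 4:
            raise ValueError(f"pair ({label}, {trf}): need >= 4 matched samples")
        if x.nunique() <= 1 or y.nunique() <= 1:
            rows.append({"activity": label, "trf": trf, "rho": np.nan, "pvalue": np.nan,
                         "flag": "constant vector"})
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append({"activity": label, "trf": trf, "rho": float(rho),
                     "pvalue": float(p), "flag": ""})
    out = pd.DataFrame(rows)
    out["padj"] = bh_fdr(out["pvalue"].to_numpy())
    return out
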