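"""Weighted cholinergic target scoring and enrichment statistics.

Small RNAs (miRs and tRFs, 17-28 nt) whose predicted targets include genes
of the cholinergic system are scored by summing gene weights: core genes
(e.g. CHAT, ACHE) weigh 5, peripheral genes (e.g. IL6, CHKB) weigh 1.  An
RNA is designated a CholinotRF/CholinomiR when it targets at least one core
gene or at least five peripheral genes.  Only predictions with score >= 80
qualify; duplicate predictions for the same RNA-gene pair collapse to the
maximum score before filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CORE_WEIGHT = 5
PERIPHERAL_WEIGHT = 1


@dataclass
class WeightedGeneList:
    """Weighted cholinergic gene universe: gene -> (tier, weight, class)."""

    table: pd.DataFrame  # columns: gene, tier, functional_class

    def __post_init__(self) -> None:
        t = self.table.copy()
        t["gene"] = t["gene"].str.upper()
        if t["gene"].duplicated().any():
            raise ValueError("duplicate gene symbols in weighted list")
        bad = ~t["tier"].isin(["core", "peripheral"])
        if bad.any():
            raise ValueError(f"unknown tiers: {t.loc[bad, 'tier'].unique()}")
        t["weight"] = np.where(t["tier"] == "core", CORE_WEIGHT, PERIPHERAL_WEIGHT)
        self.table = t

    @classmethod
    def from_csv(cls, path) -> "WeightedGeneList":
        return cls(pd.read_csv(path, comment="#"))

    @property
    def core(self) -> set[str]:
        return set(self.table.loc[self.table["tier"] == "core", "gene"])

    @property
    def peripheral(self) -> set[str]:
        return set(self.table.loc[self.table["tier"] == "peripheral", "gene"])

    def __len__(self) -> int:
        return len(self.table)


def filter_candidates(
    lengths: pd.Series,
    predictions: pd.DataFrame,
    min_len: int = 17,
    max_len: int = 28,
    min_score: int = 80,
) -> pd.DataFrame:
    """Qualifying (rna, gene) prediction pairs.

    ``lengths`` maps rna id -> nt length.  Keeps RNAs with length in
    [min_len, max_len] and predictions with score >= min_score, after
    collapsing duplicate rna-gene pairs to their maximum score.  Unknown RNA
    ids are logged and skipped.
    """
    pred = predictions.copy()
    unknown = ~pred["rna_id"].isin(lengths.index)
    if unknown.any():
        logger.warning(
            "skipping %d predictions for unknown RNAs", int(unknown.sum())
        )
        pred = pred[~unknown]
    pred = (
        pred.groupby(["rna_id", "gene"], as_index=False)["score"].max()
    )
    ok_len = pred["rna_id"].map(lengths).between(min_len, max_len)
    return pred[ok_len & (pred["score"] >= min_score)].reset_index(drop=True)


def score_rna(
    targets: pd.DataFrame, gene_list: WeightedGeneList
) -> dict:
    """Cholinergic score for one RNA's qualifying targets.

    ``targets`` has columns gene, score.  Genes absent from the weighted list
    contribute nothing.  Designation: >= 1 core or >= 5 peripheral targets.
    """
    genes = {str(g).upper() for g in targets["gene"]}
    n_core = len(genes & gene_list.core)
    n_peripheral = len(genes & gene_list.peripheral)
    score = CORE_WEIGHT * n_core + PERIPHERAL_WEIGHT * n_peripheral
    return {
        "n_core": n_core,
        "n_peripheral": n_peripheral,
        "score": score,
        "is_cholino": n_core >= 1 or n_peripheral >= 5,
    }


def score_table(
    lengths: pd.Series,
    predictions: pd.DataFrame,
    gene_list: WeightedGeneList,
    rna_class: pd.Series | None = None,
    min_len: int = 17,
    max_len: int = 28,
    min_score: int = 80,
) -> pd.DataFrame:
    """Score every length-eligible RNA; one row per RNA.

    RNAs within the length window but with no qualifying target get score 0.
    Output columns: ``rna_id, class, n_core, n_peripheral, score,
    is_cholino``.
    """
    qual = filter_candidates(lengths, predictions, min_len, max_len, min_score)
    eligible = lengths[lengths.between(min_len, max_len)].index
    rows = []
    grouped = dict(list(qual.groupby("rna_id")))
    for rna in eligible:
        targets = grouped.get(
            rna, pd.DataFrame({"gene": pd.Series(dtype=str), "score": []})
        )
        rec = score_rna(targets, gene_list)
        rec["rna_id"] = rna
        rec["class"] = rna_class.get(rna, "tRF") if rna_class is not None else "tRF"
        rows.append(rec)
    cols = ["rna_id", "class", "n_core", "n_peripheral", "score", "is_cholino"]
    return pd.DataFrame(rows, columns=cols)


def fisher_origin_enrichment(
    is_cholino: pd.Series, origins: pd.Series
) -> tuple[float, float, pd.DataFrame]:
    """Two-sided Fisher exact test of designation against genome origin.

    Builds the 2x2 table [cholino x {MT, Nuc}]; returns (odds ratio, p,
    table).  The odds ratio is the sample OR with a Haldane 0.5 correction
    when any cell is zero; a zero margin gives p = 1 and OR = NaN.
    """
    tab = np.array(
        [
            [(is_cholino & (origins == "MT")).sum(), (is_cholino & (origins == "Nuc")).sum()],
            [(~is_cholino & (origins == "MT")).sum(), (~is_cholino & (origins == "Nuc")).sum()],
        ],
        dtype=int,
    )
    table_df = pd.DataFrame(tab, index=["cholino", "other"], columns=["MT", "Nuc"])
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        return float("nan"), 1.0, table_df
    _, p = stats.fisher_exact(tab, alternative="two-sided")
    a, b, c, d = tab.ravel().astype(float)
    if 0 in tab:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(a * d / (b * c)), float(p), table_df


def hypergeom_target_enrichment(
    universe_size: int,
    n_cholinergic: int,
    n_predicted_targets: int,
    n_overlap: int,
) -> float:
    """Upper-tail hypergeometric enrichment P(X >= n_overlap).

    Drawing ``n_predicted_targets`` genes from a universe containing
    ``n_cholinergic`` cholinergic genes, the p-value is the probability of
    at least the observed cholinergic overlap.
    """
    if not (
        0 <= n_overlap <= min(n_cholinergic, n_predicted_targets) <= universe_size
    ):
        raise ValueError("inconsistent hypergeometric counts")
    return float(
        stats.hypergeom.sf(n_overlap - 1, universe_size, n_cholinergic, n_predicted_targets)
    )
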