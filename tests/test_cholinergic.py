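"""Weighted cholinergic scoring rule and enrichment statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import fisher_two_sided_enum, hypergeom_tail_sum
from trfstress.cholinergic import (
    WeightedGeneList,
    filter_candidates,
    fisher_origin_enrichment,
    hypergeom_target_enrichment,
    score_rna,
    score_table,
)
from trfstress.simulate import simulate_catalog, simulate_prediction_table


def _gene_list():
    return WeightedGeneList(
        pd.DataFrame(
            {
                "gene": ["CHAT", "ACHE", "IL6", "CHKB", "SLC5A7", "PRKCA", "BCHE",
                         "CHRNA7", "TNF"],
                "tier": ["core", "core", "peripheral", "peripheral", "core",
                         "peripheral", "core", "peripheral", "peripheral"],
                "functional_class": ["synthesis", "degradation", "cytokine",
                                     "metabolism", "transport", "signaling",
                                     "degradation", "receptor", "cytokine"],
            }
        )
    )


@pytest.fixture
def gene_list():
    return _gene_list()


class TestFilterCandidates:
    def test_length_and_score_windows(self):
        lengths = pd.Series({"a": 21, "b": 36, "c": 17, "d": 28, "e": 16, "f": 29})
        pred = pd.DataFrame(
            {
                "rna_id": ["a", "b", "c", "d", "e", "f", "a"],
                "gene": ["G1"] * 7,
                "score": [85, 99, 80, 80, 99, 99, 79],
            }
        )
        out = filter_candidates(lengths, pred)
        # a(21nt,85), c(17nt,80 boundary), d(28nt,80 boundary) qualify;
        # b too long, e too short, f too long, and the duplicate a-G1 pair
        # collapses to its max score first
        assert sorted(out["rna_id"]) == ["a", "c", "d"]

    def test_duplicates_collapse_to_max_before_filtering(self):
        lengths = pd.Series({"a": 20})
        pred = pd.DataFrame(
            {"rna_id": ["a", "a"], "gene": ["G1", "G1"], "score": [60, 90]}
        )
        out = filter_candidates(lengths, pred)
        assert len(out) == 1 and out["score"].iloc[0] == 90

    def test_unknown_rna_skipped(self):
        lengths = pd.Series({"a": 20})
        pred = pd.DataFrame(
            {"rna_id": ["a", "ghost"], "gene": ["G1", "G2"], "score": [90, 90]}
        )
        out = filter_candidates(lengths, pred)
        assert list(out["rna_id"]) == ["a"]

    def test_hand_counted_pairs(self):
        lengths = pd.Series({"r1": 20, "r2": 25, "r3": 40})
        pred = pd.DataFrame(
            {
                "rna_id": ["r1", "r1", "r2", "r2", "r3"],
                "gene": ["G1", "G2", "G1", "G3", "G1"],
                "score": [90, 70, 80, 85, 95],
            }
        )
        assert len(filter_candidates(lengths, pred)) == 3


class TestScoreRNA:
    def test_core_plus_peripherals(self, gene_list):
        targets = pd.DataFrame({"gene": ["ACHE", "IL6", "CHKB"], "score": [90] * 3})
        out = score_rna(targets, gene_list)
        assert out == {"n_core": 1, "n_peripheral": 2, "score": 7, "is_cholino": True}

    @pytest.mark.parametrize(
        "n_periph,expected",
        [(4, False), (5, True)],
    )
    def test_peripheral_rule_boundary(self, gene_list, n_periph, expected):
        periphs = ["IL6", "CHKB", "PRKCA", "CHRNA7", "TNF"][:n_periph]
        out = score_rna(pd.DataFrame({"gene": periphs, "score": [90] * n_periph}),
                        gene_list)
        assert out["score"] == n_periph
        assert out["is_cholino"] is expected

    def test_unlisted_genes_contribute_nothing(self, gene_list):
        out = score_rna(pd.DataFrame({"gene": ["NOTAGENE"], "score": [99]}), gene_list)
        assert out == {"n_core": 0, "n_peripheral": 0, "score": 0, "is_cholino": False}

    @given(n_core=st.integers(0, 3), n_periph=st.integers(0, 5))
    @settings(max_examples=30, deadline=None)
    def test_monotone_and_additive(self, n_core, n_periph):
        """Adding a qualifying target never revokes the designation; the
        score is the weighted count."""
        gene_list = _gene_list()
        cores = ["CHAT", "ACHE", "SLC5A7", "BCHE"][:n_core]
        periphs = ["IL6", "CHKB", "PRKCA", "CHRNA7", "TNF"][:n_periph]
        base = score_rna(
            pd.DataFrame({"gene": cores + periphs, "score": [90] * (n_core + n_periph)}),
            gene_list,
        )
        assert base["score"] == 5 * n_core + n_periph
        more = score_rna(
            pd.DataFrame({"gene": cores + periphs + ["BCHE"],
                          "score": [90] * (n_core + n_periph + 1)}),
            gene_list,
        )
        assert more["is_cholino"] >= base["is_cholino"]
        assert more["score"] >= base["score"]


class TestScoreTable:
    def test_planted_recovery_exact(self):
        """The designation rule is deterministic: planted cholinergic RNAs
        are recovered exactly on the synthetic prediction table."""
        cat = simulate_catalog(10, 120, seed=81)
        pred, genes, truth = simulate_prediction_table(
            cat, planted_cholino_fraction=0.15, seed=82
        )
        table = score_table(
            pd.Series({a.id: a.length for a in cat}), pred, WeightedGeneList(genes)
        ).set_index("rna_id")
        planted = truth.set_index("rna_id")["planted_cholino"]
        eligible = planted.index.intersection(table.index)
        assert (table.loc[eligible, "is_cholino"] == planted[eligible]).all()

    def test_length_ineligible_excluded(self):
        cat = simulate_catalog(4, 40, seed=83)
        pred, genes, _ = simulate_prediction_table(cat, seed=84)
        table = score_table(
            pd.Series({a.id: a.length for a in cat}), pred, WeightedGeneList(genes)
        )
        lengths = {a.id: a.length for a in cat}
        assert all(17 <= lengths[r] <= 28 for r in table["rna_id"])


class TestFisher:
    def test_small_table_enumeration(self):
        _, p, _ = _fisher_from_cells(3, 1, 1, 3)
        assert p == pytest.approx(34 / 70, rel=1e-12)

    def test_diagonal_table_enumeration(self):
        _, p, _ = _fisher_from_cells(5, 0, 0, 5)
        assert p == pytest.approx(2 / 252, rel=1e-12)

    def test_matches_enumeration_all_margins(self):
        """Exact agreement with rational enumeration for margins <= 8."""
        for a in range(0, 6):
            for b in range(0, 6):
                for c in range(0, 6):
                    for d in range(0, 6):
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        _, p, _ = _fisher_from_cells(a, b, c, d)
                        assert p == pytest.approx(
                            fisher_two_sided_enum([[a, b], [c, d]]), abs=1e-12
                        ), (a, b, c, d)

    def test_zero_margin(self):
        or_, p, _ = _fisher_from_cells(0, 0, 3, 4)
        assert p == 1.0 and np.isnan(or_)

    def test_haldane_or_with_zero_cell(self):
        or_, _, _ = _fisher_from_cells(5, 0, 0, 5)
        assert or_ == pytest.approx(5.5 * 5.5 / (0.5 * 0.5))


def _fisher_from_cells(a, b, c, d):
    flags = pd.Series([True] * (a + b) + [False] * (c + d))
    origins = pd.Series(["MT"] * a + ["Nuc"] * b + ["MT"] * c + ["Nuc"] * d)
    return fisher_origin_enrichment(flags, origins)


class TestHypergeom:
    def test_direct_summation(self):
        assert hypergeom_target_enrichment(100, 10, 10, 5) == pytest.approx(
            hypergeom_tail_sum(100, 10, 10, 5), rel=1e-12
        )

    def test_zero_overlap_is_certain(self):
        assert hypergeom_target_enrichment(100, 10, 10, 0) == pytest.approx(1.0)

    def test_degenerate_full_overlap(self):
        assert hypergeom_target_enrichment(10, 10, 10, 10) == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_target_enrichment(10, 5, 5, 6)

    @given(
        universe=st.integers(5, 40),
        marked=st.integers(1, 20),
        drawn=st.integers(1, 20),
        k=st.integers(0, 20),
    )
    @settings(max_examples=80, deadline=None)
    def test_tail_matches_summation(self, universe, marked, drawn, k):
        marked, drawn = min(marked, universe), min(drawn, universe)
        k = min(k, marked, drawn)
        assert hypergeom_target_enrichment(universe, marked, drawn, k) == pytest.approx(
            hypergeom_tail_sum(universe, marked, drawn, k), rel=1e-9
        )
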