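"""Exact binomial family-trend test and length-distribution analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import binom_two_sided_enum, kruskal_h
from trfstress.catalog import TRFAnnotation, build_family_index
from trfstress.de import nb_wald_de, prefilter, size_factors
from trfstress.families import (
    exact_binomial_test,
    family_direction_counts,
    family_trend_table,
    kw_family_length,
    mean_length_profile,
    weighted_mean_lengths,
)
from trfstress.simulate import (
    EffectSpec,
    FamilyEffect,
    simulate_catalog,
    simulate_counts,
)


def _de_frame(ids, lfcs, pvals=None):
    return pd.DataFrame(
        {
            "id": ids,
            "log2FC": lfcs,
            "pvalue": pvals if pvals is not None else [0.5] * len(ids),
        }
    )


class TestExactBinomial:
    @pytest.mark.parametrize(
        "n,k,expected",
        [
            (4, 4, 0.125),            # 2 * 0.5^4
            (10, 8, 0.109375),        # frozen from the 2^10 enumeration oracle
            (29, 29, 2 * 0.5**29),
        ],
    )
    def test_worked_examples(self, n, k, expected):
        assert exact_binomial_test(n, k) == pytest.approx(expected, rel=1e-12)

    def test_matches_enumeration_oracle(self):
        """Full 2^n enumeration agreement for all n <= 12, every k."""
        for n in range(1, 13):
            for k in range(n + 1):
                assert exact_binomial_test(n, k) == pytest.approx(
                    binom_two_sided_enum(n, k), abs=1e-12
                )

    @given(n=st.integers(1, 200), k=st.integers(0, 200))
    @settings(max_examples=200, deadline=None)
    def test_symmetry(self, n, k):
        """p(n, k) == p(n, n-k): the null is symmetric."""
        k = min(k, n)
        assert exact_binomial_test(n, k) == pytest.approx(
            exact_binomial_test(n, n - k), rel=1e-12
        )

    def test_closed_form_extremes(self):
        for n in (1, 5, 50, 200):
            assert exact_binomial_test(n, 0) == pytest.approx(min(1, 2 * 0.5**n))
            assert exact_binomial_test(n, n) == pytest.approx(min(1, 2 * 0.5**n))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            exact_binomial_test(0, 0)
        with pytest.raises(ValueError):
            exact_binomial_test(5, 6)


class TestDirectionCounts:
    def test_mixed_signs(self, toy_annotations):
        extra = TRFAnnotation("mtDR-2:24-Gly-TCC-3", 23, "MT", "Gly", "TCC", "i-tRF")
        extra2 = TRFAnnotation("mtDR-3:25-Gly-TCC-4", 23, "MT", "Gly", "TCC", "i-tRF")
        index = build_family_index(toy_annotations + [extra, extra2])
        de = _de_frame(
            [a.id for a in toy_annotations] + [extra.id, extra2.id],
            [-1.0, -2.0, -0.1, -0.5, 0.3],
        )
        tab = family_direction_counts(de, index).set_index("family")
        assert tab.loc["MT-Gly-i-tRF", "n"] == 4
        assert tab.loc["MT-Gly-i-tRF", "k_down"] == 3

    def test_zero_and_nan_excluded(self, toy_annotations):
        index = build_family_index(toy_annotations)
        de = _de_frame([a.id for a in toy_annotations], [0.0, np.nan, -1.0])
        tab = family_direction_counts(de, index).set_index("family")
        assert tab.loc["MT-Gly-i-tRF", "n"] == 0
        assert tab.loc["Nuc-Asp-i-tRF", "n"] == 1
        assert tab.loc["Nuc-Asp-i-tRF", "k_down"] == 1

    def test_unknown_feature_rejected(self, toy_annotations):
        index = build_family_index(toy_annotations)
        de = _de_frame(["nonexistent-id"], [-1.0])
        with pytest.raises(ValueError, match="absent from family index"):
            family_direction_counts(de, index)

    def test_planted_fraction_recovered(self):
        """fraction_down=0.989 over ~90 members lands within sampling error."""
        cat = simulate_catalog(2, 180, family_sizes=[90, 90], seed=51)
        fam = sorted({a.family_key for a in cat}, key=lambda k: k.sort_key)[0]
        effects = EffectSpec({fam: FamilyEffect(fraction_down=0.989, log2fc=1.5)})
        counts, meta, _ = simulate_counts(cat, None, effects, seed=52)
        de = nb_wald_de(prefilter(counts, 6), meta)
        index = build_family_index([a for a in cat if a.id in set(de["id"])])
        tab = family_direction_counts(de, index).set_index("family")
        prop = tab.loc[str(fam), "k_down"] / tab.loc[str(fam), "n"]
        # 3 binomial sds at p=0.989, n~90
        assert prop == pytest.approx(0.989, abs=3 * np.sqrt(0.989 * 0.011 / 90) + 0.02)


class TestTrendTable:
    def test_single_family_bh_identity(self, toy_annotations):
        index = build_family_index(toy_annotations[:2])
        de = _de_frame([a.id for a in toy_annotations[:2]], [-1.0, -2.0])
        tab = family_trend_table(de, index)
        assert tab["padj"].iloc[0] == pytest.approx(tab["pvalue"].iloc[0])

    def test_bh_stepup_arithmetic(self):
        """Three families at p=(0.01, 0.02, 0.04) adjust to (0.03, 0.03, 0.04)."""
        from trfstress.de import bh_fdr

        np.testing.assert_allclose(
            bh_fdr(np.array([0.01, 0.02, 0.04])), [0.03, 0.03, 0.04]
        )

    def test_planted_down_family_flagged(self, small_cohort):
        counts, meta = small_cohort["counts"], small_cohort["metadata"]
        kept = prefilter(counts, 6)
        de = nb_wald_de(kept, meta)
        cat_ids = set(kept.index)
        index = build_family_index(
            [a for a in small_cohort["catalog"] if a.id in cat_ids]
        )
        tab = family_trend_table(de, index).set_index("family")
        assert tab.loc[str(small_cohort["planted"]), "direction"] == "down"


class TestLengthProfiles:
    def _norm(self, counts):
        return counts.div(size_factors(counts), axis=1)

    def test_single_length_single_group(self):
        anns = [
            TRFAnnotation(f"tDR-1:20-Ala-AGC-{i}", 20, "Nuc", "Ala", "AGC", "i-tRF")
            for i in range(3)
        ]
        counts = pd.DataFrame(
            np.full((3, 4), 10.0), index=[a.id for a in anns],
            columns=list("abcd"),
        )
        groups = pd.Series(["g1"] * 4, index=list("abcd"))
        profile, mir_frac = mean_length_profile(counts, anns, groups)
        assert profile.loc[20, "g1"] > 0
        assert profile.drop(index=20).sum().sum() == 0
        assert mir_frac["g1"] == pytest.approx(1.0)  # 20 nt is in the 16-28 window

    def test_identical_groups_identical_profiles(self, small_catalog):
        counts, meta, _ = simulate_counts(small_catalog, seed=61)
        norm = self._norm(counts)
        half = norm.shape[1] // 2
        dup = pd.concat([norm.iloc[:, :half]] * 2, axis=1)
        dup.columns = [f"s{i}" for i in range(2 * half)]
        groups = pd.Series(["g1"] * half + ["g2"] * half, index=dup.columns)
        profile, _ = mean_length_profile(dup, small_catalog, groups)
        np.testing.assert_allclose(profile["g1"], profile["g2"])

    def test_planted_36nt_peak_is_argmax(self):
        """A dominant 36-nt half family produces the profile's highest peak."""
        cat = simulate_catalog(
            6, 120, seed=62,
            length_peaks={"5p-tRF": 18.5, "i-tRF": 23.5, "3p-tRF": 26.0,
                          "5p-half": 36.0, "3p-half": 36.0},
            length_sd=0.5,
        )
        halves = [a for a in cat if a.cleavage_type.endswith("half")]
        if not halves:  # ensure the draw contains halves for this seed
            pytest.skip("seed draws no half families")
        counts, meta, _ = simulate_counts(cat, seed=63)
        # boost the halves' signal so the peak dominates
        counts.loc[[a.id for a in halves]] *= 30
        norm = self._norm(counts)
        groups = pd.Series(["all"] * norm.shape[1], index=norm.columns)
        profile, _ = mean_length_profile(norm, cat, groups)
        assert abs(int(profile["all"].idxmax()) - 36) <= 1


class TestKruskalWallis:
    def test_identical_groups_null(self, small_catalog):
        counts, meta, _ = simulate_counts(small_catalog, seed=71)
        norm = counts.div(size_factors(counts), axis=1)
        block = norm.iloc[:, :8]
        rep = pd.concat([block] * 4, axis=1)
        rep.columns = [f"s{i}" for i in range(32)]
        groups = pd.Series(
            np.repeat(["g1", "g2", "g3", "g4"], 8), index=rep.columns
        )
        index = build_family_index(small_catalog)
        out = kw_family_length(rep, small_catalog, index, groups)
        assert (out["H"] == 0).all()
        assert (out["pvalue"] == 1).all()

    def test_h_matches_rank_oracle(self):
        """H equals the rank-sum formula on a hand-made 3-group table."""
        from scipy.stats import kruskal

        groups = [
            np.array([1.2, 3.4, 5.1, 2.2]),
            np.array([4.4, 6.1, 5.9, 8.0]),
            np.array([0.5, 1.1, 2.0, 0.9]),
        ]
        h_lib, _ = kruskal(*groups)
        assert h_lib == pytest.approx(kruskal_h(groups), rel=1e-12)

    def test_shifted_group_detected(self):
        """A +6 nt shift in one group's weighted lengths at n=10/group."""
        cat = simulate_catalog(3, 60, seed=72, length_sd=1.0)
        index = build_family_index(cat)
        rng = np.random.default_rng(73)
        counts = pd.DataFrame(
            rng.negative_binomial(10, 0.1, size=(60, 40)).astype(float),
            index=[a.id for a in cat],
            columns=[f"s{i}" for i in range(40)],
        )
        groups = pd.Series(np.repeat(["g1", "g2", "g3", "g4"], 10),
                           index=counts.columns)
        # shift group g1's expression toward each family's longest members
        lengths = pd.Series({a.id: a.length for a in cat})
        for key in index.families:
            ids = index.members[key]
            longest = lengths.loc[ids].nlargest(max(2, len(ids) // 4)).index
            counts.loc[longest, groups[groups == "g1"].index] *= 50
        out = kw_family_length(counts, cat, index, groups)
        assert (out["pvalue"] < 0.01).all()
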