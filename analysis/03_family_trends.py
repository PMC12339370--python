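"""Directional family-trend analysis: the cohort's core statistic.

For each contrast, counts how many members of every tRF family fell in the
stress group, tests the proportion against 1/2 with the exact binomial test
(BH FDR across families), and checks recovery of the planted MT decline.
Also runs the coarser super-family groupings (genome origin, cleavage type)
and draws the signed family bar plot.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from trfstress.catalog import build_family_index, read_annotation_table
from trfstress.families import family_trend_table

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"


def main() -> None:
    annotations = read_annotation_table(DATA / "annotations.tsv")
    truth = pd.read_csv(DATA / "truth.tsv", sep="\t")
    planted = set(truth.loc[truth["log2fc_all"] != 0, "family"])

    for contrast in ("all", "female", "male"):
        de = pd.read_csv(ROOT / f"de_{contrast}.tsv", sep="\t")
        ids = set(de["id"])
        kept_ann = [a for a in annotations if a.id in ids]
        index = build_family_index(kept_ann, min_size=2)
        trend = family_trend_table(de, index)
        trend.to_csv(ROOT / f"family_trend_{contrast}.tsv", sep="\t",
                     index=False, float_format="%.10g")

        sig = trend[trend["direction"] != "none"]
        hits = set(sig["family"]) & planted
        print(f"contrast {contrast:7s}: {len(trend)} families, "
              f"{len(sig)} significant trends "
              f"({len(hits)}/{len(planted & set(trend['family']))} planted "
              f"families recovered)")

        for by, label in (("origin", "genome origin"), ("cleavage", "cleavage type")):
            coarse = family_trend_table(de, index.coarsen(by))
            for _, row in coarse.iterrows():
                if row["direction"] != "none":
                    print(f"    {label:13s} {row['family']:18s}: "
                          f"{row['prop_down']:.1%} down "
                          f"(n={row['n']}, FDR={row['padj']:.2e})")

    trend_all = pd.read_csv(ROOT / "family_trend_all.tsv", sep="\t")
    trend_all = trend_all.sort_values("signed_size")
    colors = trend_all["direction"].map(
        {"down": "#b2182b", "up": "#2166ac", "none": "#cccccc"}
    )
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.bar(range(len(trend_all)), trend_all["signed_size"], color=colors)
    ax.set_xticks(range(len(trend_all)))
    ax.set_xticklabels(trend_all["family"], rotation=90, fontsize=5)
    ax.set_ylabel("family size (signed by trend direction)")
    ax.axhline(0, color="black", lw=0.5)
    fig.tight_layout()
    fig.savefig(ROOT / "family_trend_bars.png", dpi=150)
    print(f"bar plot -> {ROOT / 'family_trend_bars.png'}")


if __name__ == "__main__":
    main()
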