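"""Prefilter the cohort and run stress-vs-control differential expression.

Runs the simplified NB Wald test for the combined contrast and within each
sex, mirroring the study's three comparisons, and reports how many
individual tRFs reach FDR <= 0.05 in each.
"""

from pathlib import Path

import pandas as pd

from trfstress.de import nb_wald_de, prefilter, write_de_table

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"

CONTRASTS = {"all": None, "female": ("sex", "F"), "male": ("sex", "M")}


def main() -> None:
    counts = pd.read_csv(DATA / "counts.tsv", sep="\t", index_col=0)
    metadata = pd.read_csv(DATA / "metadata.csv")
    kept = prefilter(counts, smallest_group_size=6, min_count=10)
    print(f"prefilter: {len(kept)} of {len(counts)} tRFs retained "
          f"(count >= 10 in >= 6 samples)")

    for name, subset in CONTRASTS.items():
        de = nb_wald_de(kept, metadata, subset=subset)
        out = ROOT / f"de_{name}.tsv"
        write_de_table(de, out)
        n_sig = int(de["significant"].sum())
        n_down = int((de["log2FC"] < 0).sum())
        print(f"contrast {name:7s}: {len(de)} tested, {n_sig} significant at "
              f"FDR<=0.05, {n_down} ({n_down / len(de):.1%}) with negative "
              f"fold change -> {out.name}")


if __name__ == "__main__":
    main()
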