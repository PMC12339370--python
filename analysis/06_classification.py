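"""Stress/control classification from marker-set expression.

Evaluates LOOCV SVM classifiers for the study's marker groups — all DE
tRFs, female DE tRFs and CholinotRFs — in the female-only and combined
cohorts, with permutation significance and BH FDR across marker sets.
"""

import sys
from pathlib import Path

import pandas as pd

from trfstress.classify import SVMConfig, evaluate_marker_sets
from trfstress.de import size_factors

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"

B = int(sys.argv[1]) if len(sys.argv) > 1 else 999
SEED = 20240917


def _marker_ids(path, counts, top=10):
    de = pd.read_csv(path, sep="\t")
    sig = de.loc[de["padj"] <= 0.05, "id"]
    ids = sig if len(sig) else de.nsmallest(top, "pvalue")["id"]
    return [i for i in ids if i in counts.index]


def main() -> None:
    counts = pd.read_csv(DATA / "counts.tsv", sep="\t", index_col=0)
    metadata = pd.read_csv(DATA / "metadata.csv").set_index("sample_id")
    scores = pd.read_csv(ROOT / "cholinergic_scores.tsv", sep="\t")

    marker_sets = {
        "all-DE-tRFs": _marker_ids(ROOT / "de_all.tsv", counts),
        "female-DE-tRFs": _marker_ids(ROOT / "de_female.tsv", counts),
        "CholinotRFs": [
            i for i in scores.loc[scores["is_cholino"], "rna_id"]
            if i in counts.index
        ],
    }
    marker_sets = {k: v for k, v in marker_sets.items() if v}

    for cohort, subset in (("females", metadata["sex"] == "F"),
                           ("all", pd.Series(True, index=metadata.index))):
        cols = metadata.index[subset].intersection(counts.columns)
        sub = counts[cols]
        sf = size_factors(sub)
        labels = metadata.loc[cols, "group"]
        res = evaluate_marker_sets(sub, sf, labels, marker_sets, B=B,
                                   config=SVMConfig(seed=SEED))
        res.insert(0, "cohort", cohort)
        out = ROOT / f"classification_{cohort}.tsv"
        res.to_csv(out, sep="\t", index=False, float_format="%.6g")
        print(f"cohort {cohort} (n={len(cols)}; B={B} permutations):")
        for _, row in res.iterrows():
            print(f"  {row['marker_set']:15s} AUC={row['AUC']:.2f} "
                  f"acc={row['accuracy']:.2f} p={row['p_perm']:.4g} "
                  f"FDR={row['fdr']:.4g}")


if __name__ == "__main__":
    main()
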