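"""End-to-end orchestration: load -> prefilter -> DE -> family trends ->
length analysis -> cholinergic scoring -> classification -> kinetics.

A :class:`RunConfig` (YAML) drives the run; every threshold is echoed into
the output manifest and reruns with the same config and seed produce
byte-identical result files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import build_family_index, read_annotation_table
from .cholinergic import (
    WeightedGeneList,
    fisher_origin_enrichment,
    score_table,
)
from .classify import SVMConfig, evaluate_marker_sets
from .de import nb_wald_de, prefilter, read_de_table, size_factors
from .families import family_trend_table, kw_family_length, mean_length_profile
from .kinetics import compute_activities, group_compare, iqr_filter, traces_from_long

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    input_dir: str = "."
    output_dir: str = "results/run"
    de_table: str | None = None          # import an external DE table instead
    contrasts: list = field(
        default_factory=lambda: ["all", "female", "male"]
    )
    smallest_group_size: int = 6
    min_count: int = 10
    family_min_size: int = 2
    binomial_sided: str = "two"
    alpha: float = 0.05
    scoring_min_len: int = 17
    scoring_max_len: int = 28
    scoring_min_score: int = 80
    classifier_kernel: str = "rbf"
    classifier_C: float = 1.0
    permutations: int = 10_000
    pss_control_max: int = 10
    pss_stress_min: int = 19
    seed: int = 0
    run_kinetics: bool = True
    run_classifier: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


_CONTRAST_SUBSET = {"all": None, "female": ("sex", "F"), "male": ("sex", "M")}


def validate_inputs(input_dir) -> list[str]:
    """Schema and referential-integrity check of a data bundle.

    Errors are collected and reported together rather than failing on the
    first problem.
    """
    input_dir = Path(input_dir)
    errors: list[str] = []
    ann_path = input_dir / "annotations.tsv"
    counts_path = input_dir / "counts.tsv"
    meta_path = input_dir / "metadata.csv"
    for p in (ann_path, counts_path, meta_path):
        if not p.exists():
            errors.append(f"missing required input {p.name}")
    if errors:
        return errors
    try:
        annotations = read_annotation_table(ann_path)
    except (ValueError, KeyError) as e:
        errors.append(f"annotations.tsv: {e}")
        annotations = []
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path)
    need = {"sample_id", "cohort", "group", "sex", "birth_type", "pss"}
    missing_cols = need - set(meta.columns)
    if missing_cols:
        errors.append(f"metadata.csv missing columns: {sorted(missing_cols)}")
    else:
        meta_samples = set(meta["sample_id"])
        count_samples = set(counts.columns)
        for s in sorted(count_samples - meta_samples):
            errors.append(f"sample {s} in counts but not metadata")
        for s in sorted(meta_samples - count_samples):
            errors.append(f"sample {s} in metadata but not counts")
    ann_ids = {a.id for a in annotations}
    orphan = set(counts.index) - ann_ids
    if annotations and orphan:
        errors.append(
            f"{len(orphan)} count features missing annotation "
            f"(e.g. {sorted(orphan)[:3]})"
        )
    return errors


def _write(df: pd.DataFrame, path: Path, **kw) -> int:
    df.to_csv(path, sep="\t", index=kw.pop("index", False),
              float_format=_FLOAT_FMT, **kw)
    return len(df)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages on a data bundle; returns the run manifest."""
    indir, outdir = Path(config.input_dir), Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": {},
        "warnings": [],
    }

    # -- load ---------------------------------------------------------------
    errors = validate_inputs(indir)
    if errors:
        raise ValueError("input validation failed:\n" + "\n".join(errors))
    annotations = read_annotation_table(indir / "annotations.tsv")
    counts = pd.read_csv(indir / "counts.tsv", sep="\t", index_col=0)
    metadata = pd.read_csv(indir / "metadata.csv")
    manifest["stages"]["load"] = {
        "features": len(counts), "samples": counts.shape[1],
        "annotations": len(annotations),
    }

    # -- prefilter ----------------------------------------------------------
    kept = prefilter(counts, config.smallest_group_size, config.min_count)
    manifest["stages"]["prefilter"] = {"in": len(counts), "out": len(kept)}
    ann_kept = [a for a in annotations if a.id in set(kept.index)]
    index = build_family_index(ann_kept, min_size=config.family_min_size)
    sf = size_factors(kept)
    norm = kept.div(sf, axis=1)

    # -- DE (or imported table) --------------------------------------------
    de_tables: dict[str, pd.DataFrame] = {}
    for contrast in config.contrasts:
        if config.de_table is not None:
            de = read_de_table(config.de_table)
        else:
            de = nb_wald_de(
                kept, metadata, subset=_CONTRAST_SUBSET[contrast],
                alpha=config.alpha,
            )
        de_tables[contrast] = de
        _write(de, outdir / f"de_{contrast}.tsv")
    manifest["stages"]["de"] = {
        c: {"features": len(t), "significant": int(t["significant"].sum())}
        for c, t in de_tables.items()
    }

    # -- family trends ------------------------------------------------------
    trend_tables = {}
    for contrast, de in de_tables.items():
        trend = family_trend_table(
            de, index, alpha=config.alpha, sided=config.binomial_sided
        )
        trend_tables[contrast] = trend
        _write(trend, outdir / f"family_trend_{contrast}.tsv")
    manifest["stages"]["family_trend"] = {
        c: {"families": len(t),
            "significant": int((t["direction"] != "none").sum())}
        for c, t in trend_tables.items()
    }

    # -- length analysis ----------------------------------------------------
    meta_idx = metadata.set_index("sample_id")
    groups4 = (meta_idx["sex"] + "-" + meta_idx["group"]).reindex(norm.columns)
    profile, mir_frac = mean_length_profile(norm, ann_kept, groups4)
    _write(profile, outdir / "length_profile.tsv", index=True)
    _write(mir_frac.to_frame().T, outdir / "mir_window_fraction.tsv")
    kw = kw_family_length(norm, ann_kept, index, groups4)
    _write(kw, outdir / "family_length_kw.tsv")
    manifest["stages"]["lengths"] = {
        "families_tested": len(kw),
        "significant": int((kw.get("padj", pd.Series(dtype=float)) <= config.alpha).sum()),
    }

    # -- cholinergic scoring ------------------------------------------------
    pred_path = indir / "predictions.tsv"
    genes_path = indir / "cholinergic_genes.csv"
    scores = None
    if pred_path.exists() and genes_path.exists():
        predictions = pd.read_csv(pred_path, sep="\t")
        gene_list = WeightedGeneList.from_csv(genes_path)
        lengths = pd.Series({a.id: a.length for a in annotations})
        scores = score_table(
            lengths, predictions, gene_list,
            min_len=config.scoring_min_len, max_len=config.scoring_max_len,
            min_score=config.scoring_min_score,
        )
        origin = pd.Series({a.id: a.genome_origin for a in annotations})
        odds, p, tab = fisher_origin_enrichment(
            scores.set_index("rna_id")["is_cholino"],
            origin.reindex(scores["rna_id"]).set_axis(scores["rna_id"]),
        )
        _write(scores, outdir / "cholinergic_scores.tsv")
        manifest["stages"]["cholinergic"] = {
            "scored": len(scores),
            "cholino": int(scores["is_cholino"].sum()),
            "fisher_or": None if np.isnan(odds) else float(odds),
            "fisher_p": float(p),
        }
    else:
        manifest["stages"]["cholinergic"] = {"skipped": "no prediction inputs"}
        manifest["warnings"].append("cholinergic stage skipped: inputs absent")

    # -- classification -----------------------------------------------------
    if config.run_classifier:
        marker_sets = _default_marker_sets(de_tables, scores)
        # markers must survive the prefilter to be usable as features
        marker_sets = {
            name: [i for i in ids if i in kept.index]
            for name, ids in marker_sets.items()
        }
        marker_sets = {k: v for k, v in marker_sets.items() if v}
        labels = meta_idx["group"].reindex(kept.columns)
        svm = SVMConfig(kernel=config.classifier_kernel, C=config.classifier_C,
                        seed=config.seed)
        cls = evaluate_marker_sets(
            kept, sf, labels, marker_sets, B=config.permutations, config=svm
        )
        _write(cls, outdir / "classification.tsv")
        (outdir / "classification.json").write_text(
            json.dumps(cls.to_dict(orient="records"), indent=2, sort_keys=True)
        )
        manifest["stages"]["classify"] = {
            "marker_sets": list(marker_sets),
            "B": config.permutations,
        }
    else:
        manifest["stages"]["classify"] = {"skipped": "disabled"}

    # -- kinetics -----------------------------------------------------------
    kin_path = indir / "kinetics.csv"
    if config.run_kinetics and kin_path.exists():
        kin = pd.read_csv(kin_path)
        traces = traces_from_long(kin)
        acts = [compute_activities(tr) for tr in traces.values()]
        act_df = pd.DataFrame(
            {
                "sample_id": [a.sample_id for a in acts],
                "role": [a.role for a in acts],
                "AChE": [a.ache for a in acts],
                "BChE": [a.bche for a in acts],
                "total": [a.total for a in acts],
                "flags": [";".join(a.flags) for a in acts],
            }
        ).sort_values("sample_id")
        _write(act_df, outdir / "activities.tsv")
        stats_json = {}
        meta_all = metadata.set_index("sample_id")
        for enzyme in ("AChE", "BChE"):
            vals = act_df.set_index("sample_id")[enzyme].dropna()
            grp = meta_all["group"].reindex(vals.index)
            a = iqr_filter(vals[grp == "stress"].to_numpy())
            b = iqr_filter(vals[grp == "control"].to_numpy())
            if len(a) and len(b):
                u, p = group_compare(a, b)
                stats_json[enzyme] = {"U": u, "p": p,
                                      "n_stress": len(a), "n_control": len(b)}
        (outdir / "kinetics_stats.json").write_text(
            json.dumps(stats_json, indent=2, sort_keys=True)
        )
        manifest["stages"]["kinetics"] = {"samples": len(act_df)}
    else:
        manifest["stages"]["kinetics"] = {"skipped": "no kinetics input or disabled"}

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest


def _default_marker_sets(
    de_tables: dict[str, pd.DataFrame], scores: pd.DataFrame | None
) -> dict[str, list[str]]:
    """Marker sets mirroring the study's groups: all DE tRFs, female DE
    tRFs, and CholinotRFs when scoring ran.  Falls back to the top-10
    smallest-p features when a contrast has no significant hits."""
    sets: dict[str, list[str]] = {}

    def _de_ids(de: pd.DataFrame) -> list[str]:
        sig = de.loc[de["significant"].fillna(False), "id"].tolist()
        if sig:
            return sorted(sig)
        return de.nsmallest(10, "pvalue")["id"].tolist()

    sets["all-DE-tRFs"] = _de_ids(de_tables["all"])
    if "female" in de_tables:
        sets["female-DE-tRFs"] = _de_ids(de_tables["female"])
    if scores is not None and scores["is_cholino"].any():
        sets["CholinotRFs"] = sorted(
            scores.loc[scores["is_cholino"], "rna_id"].tolist()
        )
    return sets
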