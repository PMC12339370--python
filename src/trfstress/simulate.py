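"""Seeded synthetic cohorts with the statistical structure of the real study.

Every generator is a pure function of (parameters, seed) and writes/returns
the same tabular shapes the real-data mode consumes, plus a ground-truth
table so downstream recovery tests only ever consume generator *outputs*.

The default condition mirrors the study design: four stress-by-sex newborn
groups of sizes 6 (female stress), 8 (male stress), 11 (female control) and
10 (male control); 45 tRF families totalling 565 surviving fragments;
perceived-stress scores of controls at most 10 and of the stress group at
least 19; a 102-gene weighted cholinergic list; and 21-cycle, one-minute
Ellman kinetic traces under no inhibitor, iso-OMPA (isolates AChE) and
BW284c51 (isolates BChE).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import (
    CLEAVAGE_TYPES,
    MAX_TRF_LEN,
    MIN_TRF_LEN,
    FamilyKey,
    TRFAnnotation,
    format_tdr_name,
)

# Amino acids used when drawing family keys.
_AMINO_ACIDS = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp "
    "Tyr Val"
).split()

_ANTICODON = {
    "Ala": "AGC", "Arg": "ACG", "Asn": "GTT", "Asp": "GTC", "Cys": "GCA",
    "Gln": "TTG", "Glu": "TTC", "Gly": "TCC", "His": "GTG", "Ile": "AAT",
    "Leu": "AAG", "Lys": "CTT", "Met": "CAT", "Phe": "GAA", "Pro": "AGG",
    "Ser": "AGA", "Thr": "AGT", "Trp": "CCA", "Tyr": "GTA", "Val": "AAC",
}

#: Typical fragment-length peaks (nt) per cleavage type.  Short 5'-tRFs sit
#: around 18-19 nt, i-tRFs around 23-24 nt, 3'-tRFs around 31-32 nt and
#: halves near 36 nt, reproducing the multi-peak serum length profile.
DEFAULT_LENGTH_PEAKS: dict[str, float] = {
    "5p-tRF": 18.5,
    "i-tRF": 23.5,
    "3p-tRF": 31.5,
    "5p-half": 34.0,
    "3p-half": 36.0,
}


@dataclass
class CohortDesign:
    """Group sizes and the perceived-stress (PSS-10) assignment rule."""

    group_sizes: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("F", "stress"): 6,
            ("M", "stress"): 8,
            ("F", "control"): 11,
            ("M", "control"): 10,
        }
    )
    cohort: str = "newborn"
    pss_control_max: int = 10
    pss_stress_min: int = 19

    def __post_init__(self) -> None:
        for key, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {key} must have at least 2 samples, got {n}")

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())


@dataclass
class FamilyEffect:
    """Planted directional effect for one family.

    ``fraction_down`` is the probability that a member's true stress-vs-
    control log2 fold change is negative; ``log2fc`` its magnitude;
    ``subgroup`` restricts the effect to 'all', 'females' or 'males'.
    """

    fraction_down: float = 1.0
    log2fc: float = 1.0
    subgroup: str = "all"

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_down <= 1.0:
            raise ValueError("fraction_down must be in [0, 1]")
        if self.subgroup not in ("all", "females", "males"):
            raise ValueError(f"unknown subgroup {self.subgroup!r}")


@dataclass
class EffectSpec:
    """Per-family planted effects plus global length-distribution knobs."""

    family_effects: dict[FamilyKey, FamilyEffect] = field(default_factory=dict)
    length_peaks: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_PEAKS)
    )


@dataclass
class NBModel:
    """Negative-binomial count model: mean grid, dispersion, library sizes.

    Dispersion follows var = mu + phi(mu) * mu^2 with the decreasing trend
    phi(mu) = 0.1 + 1/mu typical of serum small-RNA data; library-size
    factors are log-normal around 1.
    """

    mean_low: float = 5.0
    mean_high: float = 500.0
    dispersion: Callable[[np.ndarray], np.ndarray] = field(
        default=lambda mu: 0.1 + 1.0 / np.maximum(mu, 1e-8)
    )
    libsize_sigma: float = 0.3


def simulate_catalog(
    n_families: int = 45,
    n_features: int = 565,
    mt_fraction: float = 0.4,
    length_sd: float = 2.0,
    length_peaks: Mapping[str, float] | None = None,
    family_sizes: Sequence[int] | None = None,
    seed: int = 0,
) -> list[TRFAnnotation]:
    """Draw a seeded tRF catalog with ``n_families`` families.

    Family keys are distinct (origin, amino acid, cleavage type) combinations;
    member counts are drawn from a Dirichlet-multinomial so that sizes sum to
    ``n_features`` exactly (or are given explicitly via ``family_sizes``).
    Fragment lengths are normal around the cleavage-type peak plus a small
    family-specific offset, clipped to the 16-50 nt tRF range.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    peaks = dict(length_peaks or DEFAULT_LENGTH_PEAKS)

    all_keys = [
        FamilyKey(origin, aa, ct)
        for origin in ("Nuc", "MT")
        for aa in _AMINO_ACIDS
        for ct in CLEAVAGE_TYPES
    ]
    if n_families > len(all_keys):
        raise ValueError(f"at most {len(all_keys)} distinct family keys available")
    # Weight MT keys so the catalog has roughly the requested MT share.
    w = np.array([mt_fraction if k.genome_origin == "MT" else 1 - mt_fraction
                  for k in all_keys])
    idx = rng.choice(len(all_keys), size=n_families, replace=False, p=w / w.sum())
    keys = sorted((all_keys[i] for i in idx), key=lambda k: k.sort_key)

    if family_sizes is None:
        if n_features < n_families:
            raise ValueError("n_features must be >= n_families")
        props = rng.dirichlet(np.full(n_families, 2.0))
        sizes = np.maximum(1, np.round(props * n_features).astype(int))
        # Adjust largest/smallest families so sizes sum exactly.
        while sizes.sum() > n_features:
            sizes[np.argmax(sizes)] -= 1
        while sizes.sum() < n_features:
            sizes[np.argmin(sizes)] += 1
    else:
        sizes = np.asarray(family_sizes, dtype=int)
        if len(sizes) != n_families:
            raise ValueError("family_sizes length must equal n_families")

    annotations: list[TRFAnnotation] = []
    # the name suffix is a global disambiguator: families sharing origin and
    # amino acid would otherwise collide (names do not encode cleavage type)
    serial = 0
    for key, size in zip(keys, sizes):
        family_shift = rng.normal(0.0, 1.0)
        mean_len = peaks[key.cleavage_type] + family_shift
        for j in range(size):
            serial += 1
            length = int(np.clip(round(rng.normal(mean_len, length_sd)),
                                 MIN_TRF_LEN, MAX_TRF_LEN))
            start = int(rng.integers(1, 40))
            name = format_tdr_name(
                key.genome_origin,
                (start, start + length - 1),
                key.amino_acid,
                _ANTICODON[key.amino_acid],
                suffix=str(serial),
            )
            seq = "".join(rng.choice(list("ACGT"), size=length))
            annotations.append(
                TRFAnnotation(
                    id=name,
                    sequence=seq,
                    length=length,
                    genome_origin=key.genome_origin,
                    amino_acid=key.amino_acid,
                    anticodon=_ANTICODON[key.amino_acid],
                    cleavage_type=key.cleavage_type,
                    parent_trnas=[f"tRNA-{key.amino_acid}-{_ANTICODON[key.amino_acid]}-1"],
                )
            )
    return annotations


def simulate_mother_catalog(
    newborn_catalog: Sequence[TRFAnnotation],
    n_families: int = 30,
    n_shared: int = 19,
    n_features: int = 174,
    length_sd: float = 2.0,
    length_peaks: Mapping[str, float] | None = None,
    seed: int = 0,
) -> list[TRFAnnotation]:
    """Maternal-serum catalog partially overlapping the newborn one.

    Serum tRF repertoires of mothers and newborns overlap only partly; by
    default 19 of the mother's 30 families share a key with the newborn's
    families and the rest are fresh keys, at the maternal scale of 174
    surviving fragments.  Member ids carry an ``m<serial>`` suffix so they
    never collide with newborn ids.
    """
    if n_shared > n_families:
        raise ValueError("n_shared cannot exceed n_families")
    rng = np.random.default_rng(seed)
    peaks = dict(length_peaks or DEFAULT_LENGTH_PEAKS)
    newborn_keys = sorted({a.family_key for a in newborn_catalog},
                          key=lambda k: k.sort_key)
    if n_shared > len(newborn_keys):
        raise ValueError("newborn catalog has too few families to share")
    shared = [newborn_keys[i]
              for i in rng.choice(len(newborn_keys), size=n_shared, replace=False)]
    pool = [
        FamilyKey(origin, aa, ct)
        for origin in ("Nuc", "MT")
        for aa in _AMINO_ACIDS
        for ct in CLEAVAGE_TYPES
        if FamilyKey(origin, aa, ct) not in set(newborn_keys)
    ]
    fresh_idx = rng.choice(len(pool), size=n_families - n_shared, replace=False)
    keys = sorted(shared + [pool[i] for i in fresh_idx], key=lambda k: k.sort_key)

    props = rng.dirichlet(np.full(n_families, 2.0))
    sizes = np.maximum(1, np.round(props * n_features).astype(int))
    while sizes.sum() > n_features:
        sizes[np.argmax(sizes)] -= 1
    while sizes.sum() < n_features:
        sizes[np.argmin(sizes)] += 1

    annotations: list[TRFAnnotation] = []
    serial = 0
    for key, size in zip(keys, sizes):
        mean_len = peaks[key.cleavage_type] + rng.normal(0.0, 1.0)
        for _ in range(size):
            serial += 1
            length = int(np.clip(round(rng.normal(mean_len, length_sd)),
                                 MIN_TRF_LEN, MAX_TRF_LEN))
            start = int(rng.integers(1, 40))
            name = format_tdr_name(
                key.genome_origin, (start, start + length - 1), key.amino_acid,
                _ANTICODON[key.amino_acid], suffix=f"m{serial}",
            )
            annotations.append(
                TRFAnnotation(
                    id=name,
                    sequence="".join(rng.choice(list("ACGT"), size=length)),
                    length=length,
                    genome_origin=key.genome_origin,
                    amino_acid=key.amino_acid,
                    anticodon=_ANTICODON[key.amino_acid],
                    cleavage_type=key.cleavage_type,
                    parent_trnas=[
                        f"tRNA-{key.amino_acid}-{_ANTICODON[key.amino_acid]}-1"
                    ],
                )
            )
    return annotations


def _sample_table(design: CohortDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    i = 0
    prefix = "NB" if design.cohort == "newborn" else "MO"
    for (sex, group), n in sorted(design.group_sizes.items()):
        for _ in range(n):
            i += 1
            if group == "control":
                pss = int(rng.integers(0, design.pss_control_max + 1))
            else:
                pss = int(rng.integers(design.pss_stress_min, 41))
            rows.append(
                {
                    "sample_id": f"{prefix}{i:03d}",
                    "cohort": design.cohort,
                    "group": group,
                    "sex": sex,
                    "birth_type": "vaginal",
                    "pss": pss,
                }
            )
    return pd.DataFrame(rows)


def simulate_counts(
    catalog: Sequence[TRFAnnotation],
    design: CohortDesign | None = None,
    effects: EffectSpec | None = None,
    nb: NBModel | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate an NB count matrix (features x samples) with planted effects.

    Returns ``(counts, metadata, truth)``.  ``truth`` lists every feature's
    true log2 fold change in each of the three contrasts (all / females /
    males); features of families without a planted effect carry zeros.
    """
    design = design or CohortDesign()
    effects = effects or EffectSpec()
    nb = nb or NBModel()
    rng = np.random.default_rng(seed)

    known = {a.family_key for a in catalog}
    for key in effects.family_effects:
        if key not in known:
            raise ValueError(f"effect references absent family {key}")

    metadata = _sample_table(design, rng)
    n_feat, n_samp = len(catalog), len(metadata)
    ids = [a.id for a in catalog]

    base_mean = np.exp(
        rng.uniform(np.log(nb.mean_low), np.log(nb.mean_high), size=n_feat)
    )
    size_factors = np.exp(rng.normal(0.0, nb.libsize_sigma, size=n_samp))

    # Planted member-level signs and per-contrast truth.
    truth = pd.DataFrame(
        {
            "id": ids,
            "family": [str(a.family_key) for a in catalog],
            "base_mean": base_mean,
            "log2fc_all": 0.0,
            "log2fc_female": 0.0,
            "log2fc_male": 0.0,
        }
    )
    metadata["true_size_factor"] = size_factors
    lfc_sex = np.zeros((n_feat, 2))  # columns: applies-to-F, applies-to-M
    for i, ann in enumerate(catalog):
        eff = effects.family_effects.get(ann.family_key)
        if eff is None or eff.log2fc == 0.0:
            continue
        sign = -1.0 if rng.random() < eff.fraction_down else 1.0
        lfc = sign * abs(eff.log2fc)
        if eff.subgroup in ("all", "females"):
            lfc_sex[i, 0] = lfc
            truth.iloc[i, truth.columns.get_loc("log2fc_female")] = lfc
        if eff.subgroup in ("all", "males"):
            lfc_sex[i, 1] = lfc
            truth.iloc[i, truth.columns.get_loc("log2fc_male")] = lfc
        if eff.subgroup == "all":
            truth.iloc[i, truth.columns.get_loc("log2fc_all")] = lfc

    stress = (metadata["group"] == "stress").to_numpy()
    is_f = (metadata["sex"] == "F").to_numpy()
    # log2FC applies only in stress samples of the affected subgroup.
    lfc_matrix = np.where(
        stress[None, :],
        np.where(is_f[None, :], lfc_sex[:, [0]], lfc_sex[:, [1]]),
        0.0,
    )
    mu = base_mean[:, None] * size_factors[None, :] * np.exp2(lfc_matrix)
    phi = nb.dispersion(mu)
    n_param = 1.0 / phi
    counts = rng.negative_binomial(n_param, n_param / (n_param + mu))

    counts_df = pd.DataFrame(counts, index=ids, columns=metadata["sample_id"])
    counts_df.index.name = "id"
    return counts_df, metadata, truth


def simulate_prediction_table(
    catalog: Sequence[TRFAnnotation],
    gene_universe: int = 2000,
    n_core: int = 15,
    n_peripheral: int = 87,
    planted_cholino_fraction: float = 0.1,
    mt_enrichment: float = 4.0,
    targets_per_rna: tuple[int, int] = (3, 15),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a target-prediction table and weighted cholinergic gene list.

    Returns ``(predictions, gene_list, truth)``.  Genes are ``GENE0001..``;
    the cholinergic list has ``n_core`` core (weight 5) and ``n_peripheral``
    peripheral (weight 1) genes (defaults total the study's 102).  A seeded
    subset of length-eligible (17-28 nt) fragments is planted as cholinergic:
    each receives at least one core-gene target with prediction score >= 80.
    ``mt_enrichment`` is the relative odds that a planted fragment is of
    mitochondrial origin, emulating the strong MT bias of cholinergic-
    targeting fragments in serum.  Non-planted fragments draw targets
    outside the cholinergic list so the designation rule's recovery is
    exact by construction.
    """
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:04d}" for i in range(gene_universe)]
    chol = rng.choice(gene_universe, size=n_core + n_peripheral, replace=False)
    core = sorted(genes[i] for i in chol[:n_core])
    peripheral = sorted(genes[i] for i in chol[n_core:])
    gene_list = pd.DataFrame(
        {
            "gene": core + peripheral,
            "tier": ["core"] * n_core + ["peripheral"] * n_peripheral,
            "functional_class": ["synthesis"] * n_core + ["signaling"] * n_peripheral,
        }
    )
    non_chol = sorted(set(genes) - set(core) - set(peripheral))

    eligible = [a for a in catalog if 17 <= a.length <= 28]
    n_plant = int(round(planted_cholino_fraction * len(eligible)))
    if n_plant:
        w = np.array(
            [mt_enrichment if a.genome_origin == "MT" else 1.0 for a in eligible]
        )
        planted = set(
            rng.choice([a.id for a in eligible], size=n_plant, replace=False,
                       p=w / w.sum())
        )
    else:
        planted = set()

    rows = []
    for ann in catalog:
        k = int(rng.integers(targets_per_rna[0], targets_per_rna[1] + 1))
        if ann.id in planted:
            n_core_hits = int(rng.integers(1, 3))
            for g in rng.choice(core, size=n_core_hits, replace=False):
                rows.append((ann.id, g, int(rng.integers(80, 101))))
            k = max(0, k - n_core_hits)
        for g in rng.choice(non_chol, size=min(k, len(non_chol)), replace=False):
            rows.append((ann.id, g, int(rng.integers(50, 101))))
    predictions = pd.DataFrame(rows, columns=["rna_id", "gene", "score"])
    truth = pd.DataFrame(
        {
            "rna_id": [a.id for a in catalog],
            "planted_cholino": [a.id in planted for a in catalog],
        }
    )
    return predictions, gene_list, truth


def simulate_ellman_traces(
    true_rates: Mapping[str, Mapping[str, float]],
    noise_sd: float = 0.0,
    n_cycles: int = 21,
    baseline: float = 0.1,
    dilution: float = 1.0,
    role: str = "newborn",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate Ellman-assay kinetic traces for each sample.

    ``true_rates`` maps sample id -> ``{"AChE": rate, "BChE": rate}`` in
    mOD/min of the measured (diluted) reaction.  Each sample yields three
    ``n_cycles``-point linear traces: uninhibited (slope AChE+BChE),
    iso-OMPA (BChE inhibited; slope AChE) and BW284c51 (AChE inhibited;
    slope BChE), with additive Gaussian noise and non-negative absorbance.

    Returns a long-format frame: ``sample_id, role, condition, cycle,
    absorbance, dilution``.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_cycles, dtype=float)
    rows = []
    for sample_id, rates in true_rates.items():
        ache, bche = float(rates["AChE"]), float(rates["BChE"])
        if ache < 0 or bche < 0:
            raise ValueError(f"{sample_id}: rates must be non-negative")
        for condition, slope in (
            ("uninhibited", ache + bche),
            ("iso-OMPA", ache),
            ("BW284c51", bche),
        ):
            # slope is in mOD/min after dilution scaling; the raw trace (OD)
            # therefore rises at slope/dilution mOD per cycle.
            trace = baseline + (slope / dilution) * t / 1000.0
            if noise_sd > 0:
                trace = trace + rng.normal(0.0, noise_sd, size=n_cycles)
            trace = np.maximum(trace, 0.0)
            for cyc, ab in zip(range(1, n_cycles + 1), trace):
                rows.append((sample_id, role, condition, cyc, float(ab), dilution))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "role", "condition", "cycle", "absorbance", "dilution"],
    )


def write_bundle(
    outdir,
    catalog: Sequence[TRFAnnotation],
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    truth: pd.DataFrame,
    predictions: pd.DataFrame | None = None,
    gene_list: pd.DataFrame | None = None,
    traces: pd.DataFrame | None = None,
) -> None:
    """Write a synthetic bundle in the formats the real-data mode reads."""
    from pathlib import Path

    from .catalog import write_annotation_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_annotation_table(catalog, outdir / "annotations.tsv")
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    metadata.to_csv(outdir / "metadata.csv", index=False)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    if predictions is not None:
        predictions.to_csv(outdir / "predictions.tsv", sep="\t", index=False)
    if gene_list is not None:
        gene_list.to_csv(outdir / "cholinergic_genes.csv", index=False)
    if traces is not None:
        traces.to_csv(outdir / "kinetics.csv", index=False)
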