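"""Shared fixtures: small seeded synthetic objects used across test modules."""

import numpy as np
import pandas as pd
import pytest

from trfstress.catalog import TRFAnnotation, build_family_index
from trfstress.simulate import (
    CohortDesign,
    EffectSpec,
    FamilyEffect,
    simulate_catalog,
    simulate_counts,
)


@pytest.fixture(scope="session")
def small_catalog():
    return simulate_catalog(n_families=8, n_features=80, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_catalog):
    """Counts/metadata/truth with one planted all-down family."""
    keys = sorted({a.family_key for a in small_catalog}, key=lambda k: k.sort_key)
    sizes = {k: sum(a.family_key == k for a in small_catalog) for k in keys}
    planted = max(sizes, key=sizes.get)
    effects = EffectSpec({planted: FamilyEffect(fraction_down=1.0, log2fc=1.5)})
    counts, meta, truth = simulate_counts(
        small_catalog, CohortDesign(), effects, seed=43
    )
    return {
        "counts": counts,
        "metadata": meta,
        "truth": truth,
        "planted": planted,
        "catalog": small_catalog,
        "index": build_family_index(small_catalog),
    }


@pytest.fixture
def toy_annotations():
    """Hand-built annotations: two families (MT/Gly/i-tRF x2, Nuc/Asp/i-tRF)."""
    return [
        TRFAnnotation("mtDR-1:20-Gly-TCC-1", 20, "MT", "Gly", "TCC", "i-tRF"),
        TRFAnnotation("mtDR-5:26-Gly-TCC-2", 22, "MT", "Gly", "TCC", "i-tRF"),
        TRFAnnotation("tDR-1:18-Asp-GTC-1", 18, "Nuc", "Asp", "GTC", "i-tRF"),
    ]
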