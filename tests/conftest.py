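"""Shared fixtures: small planted atlases and simulated cohorts.

Everything is generated programmatically at test time; fixtures that are
expensive to simulate are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import bloodlens as bl


@pytest.fixture(scope="session")
def small_atlas():
    """4 cell types x 200 genes, 5 planted 10-fold markers per type."""
    atlas, markers = bl.make_reference(
        n_cell_types=4, n_genes=200, markers_per_type=5,
        marker_enrichment=10.0, seed=11,
    )
    return atlas, markers


@pytest.fixture(scope="session")
def blood_atlas():
    """Default study-scale atlas: 19 immune types, 2000 genes, 20
    effectively exclusive markers per type."""
    return bl.make_reference(seed=101)


def target_base_proportions(atlas: bl.ReferenceAtlas, target: str, frac: float = 0.10):
    """Mixing vector with the target type pinned at ``frac``."""
    base = bl.default_proportions(atlas)
    types = atlas.specific_types
    ti = types.index(target)
    base = base * ((1.0 - frac) / (base.sum() - base[ti]))
    base[ti] = frac
    return base


def analyze_cohort(counts, meta, atlas, config=None):
    """Run the full in-memory pipeline and return the results dict."""
    return bl.run_pipeline(config or bl.PipelineConfig(), counts, meta, atlas)


@pytest.fixture(scope="session")
def expression_shift_cohort(blood_atlas):
    atlas, _ = blood_atlas
    base = target_base_proportions(atlas, "mait_t", 0.10)
    spec = bl.ScenarioSpec(
        kind="expression_shift", target_cell_type="mait_t", per_cell_fold=2.0,
        perturbed_gene_count=10, n_per_group=20, dispersion=0.1, seed=42,
    )
    counts, meta, truth = bl.simulate_cohort(atlas, spec, base_proportions=base)
    return atlas, counts, meta, truth, spec, base


@pytest.fixture(scope="session")
def null_cohort(blood_atlas):
    atlas, _ = blood_atlas
    spec = bl.ScenarioSpec(kind="null", n_per_group=20, dispersion=0.1, seed=7)
    counts, meta, truth = bl.simulate_cohort(atlas, spec)
    return atlas, counts, meta, truth


@pytest.fixture()
def tiny_counts():
    """3 genes x 4 samples with hand-checkable values."""
    return bl.CountMatrix(
        ["g1", "g2", "g3"],
        ["s1", "s2", "s3", "s4"],
        np.array([[10, 20, 10, 20], [5, 10, 5, 10], [100, 200, 100, 200]]),
    )


@pytest.fixture()
def nrc_frame(null_cohort):
    atlas, counts, meta, _ = null_cohort
    sf = bl.estimate_size_factors(counts)
    return pd.DataFrame(
        bl.normalize_counts(counts, sf), index=counts.gene_ids, columns=counts.sample_ids
    ), meta
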