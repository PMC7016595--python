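import numpy as np
import pandas as pd
import pytest

import prostasig as ps
from prostasig.io import annotation_series


@pytest.fixture
def tiny_expr():
    """4-gene x 4-sample toy matrix."""
    data = pd.DataFrame(
        [[4.0, 1.0, 2.0, 8.0],
         [3.0, 2.0, 4.0, 6.0],
         [2.0, 3.0, 6.0, 4.0],
         [1.0, 4.0, 8.0, 2.0]],
        index=list("abcd"),
        columns=["s1", "s2", "s3", "s4"],
    )
    return ps.ExpressionMatrix(data, scale="linear")


@pytest.fixture(scope="session")
def sorted_experiment():
    """Default 4x5 sorted-cell design with 20 planted markers per type."""
    cfg = ps.SimulationConfig(markers_per_type=20, n_background_genes=120, seed=0)
    expr, ann, truth = ps.simulate_sorted_experiment(cfg)
    return cfg, expr, annotation_series(ann, "cell_type"), truth


@pytest.fixture(scope="session")
def bulk_cohort():
    """Default 300-sample bulk mixture cohort with planted low-luminal subset."""
    cfg = ps.SimulationConfig(seed=0)
    expr, truth = ps.simulate_bulk_cohort(cfg)
    return cfg, expr, truth


@pytest.fixture(scope="session")
def bulk_scores(bulk_cohort):
    _, expr, truth = bulk_cohort
    return ps.score_pipeline(expr, truth.marker_sets)


@pytest.fixture(scope="session")
def classifier_setting():
    """Panel + multi-platform cohorts for the mini-classifier pipeline.

    The panel keeps only the top 20 of 40 planted markers per type, so
    cell-type-informative genes remain outside the signature — the candidate
    pool the classifier is allowed to draw from.
    """
    cfg = ps.SimulationConfig(
        markers_per_type=40, n_background_genes=400, n_bulk_samples=300, seed=0
    )
    sexpr, ann, _ = ps.simulate_sorted_experiment(cfg)
    design = annotation_series(ann, "cell_type")
    panel = ps.extract_metagenes(sexpr, design, n_genes=20, n_perm=1000, seed=0)
    family = ps.simulate_platform_family(cfg, n_datasets=4, overlap_fraction=0.8)
    return cfg, panel, family
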