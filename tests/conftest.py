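"""Shared fixtures: the two trial arms' designs and small synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from trialsig import (
    DesignHypotheses,
    GeneSet,
    PlantedSet,
    SyntheticCohortConfig,
    TwoStageDesign,
    simulate_expression_cohort,
)


@pytest.fixture(scope="session")
def arm1_design() -> TwoStageDesign:
    """Triplet-arm design: p0=0.20 vs p1=0.40, alpha=beta=0.10 -> (3/17, 10/37)."""
    return TwoStageDesign(DesignHypotheses(0.20, 0.40, 0.10, 0.10), r1=3, n1=17, r=10, n=37)


@pytest.fixture(scope="session")
def arm2_design() -> TwoStageDesign:
    """Doublet-arm design: p0=0.10 vs p1=0.30, alpha=beta=0.10 -> (1/12, 5/35)."""
    return TwoStageDesign(DesignHypotheses(0.10, 0.30, 0.10, 0.10), r1=1, n1=12, r=5, n=35)


@pytest.fixture(scope="session")
def planted_cohort():
    """One synthetic cohort with a 20-gene resistance program up in NCB."""
    planted = PlantedSet("planted_ncb_program", tuple(range(20)), lfc=1.0, up_in="NCB")
    cfg = SyntheticCohortConfig(
        planted_sets=(planted,), survival_set="planted_ncb_program", seed=42, n_genes=600
    )
    counts, clinical, truth = simulate_expression_cohort(cfg)
    return counts, clinical, truth


@pytest.fixture()
def toy_ranking() -> pd.DataFrame:
    """10-gene ranking with statistics 10..1 used by the hand-worked ES example."""
    return pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(10)],
            "statistic": np.arange(10, 0, -1, dtype=float),
            "p_raw": 0.5,
            "p_adj": 0.5,
        }
    )


@pytest.fixture()
def five_gene_single_sample() -> pd.DataFrame:
    """One sample whose five genes hold expression ranks 1..5."""
    return pd.DataFrame(
        {"s1": [1.0, 2.0, 3.0, 4.0, 5.0]}, index=list("abcde")
    )
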