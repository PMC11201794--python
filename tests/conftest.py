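"""Shared fixtures: small synthetic studies and a toy pathway catalog."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from plasmameta import SyntheticConfig, generate_multicohort
from plasmameta.preprocess import CohortDataset, ExpressionMatrix, collapse_probes


def gene_level(sim):
    """Gene-level cohorts from a simulation (collapse probes, or rename when
    the platform has one probe per gene)."""
    out = []
    for cohort in sim.cohorts:
        if sim.config.probes_per_gene == 1:
            matrix = ExpressionMatrix(
                cohort.matrix.data.rename(index=sim.probe_map), scale="log2"
            )
        else:
            matrix = collapse_probes(cohort.matrix, sim.probe_map)
        out.append(CohortDataset(matrix, cohort.groups, cohort.cohort_id))
    return out


@pytest.fixture(scope="session")
def default_sim():
    """The default planted study: 5 cohorts of 4+4, 1000 genes, 50 plants."""
    return generate_multicohort(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def null_sim():
    """Global-null study: no planted genes, single probe per gene."""
    return generate_multicohort(
        SyntheticConfig(n_genes=2000, n_signature=0, probes_per_gene=1, seed=5)
    )


@pytest.fixture
def tiny_cohort():
    """A 6-gene, 3+3 cohort with hand-controllable values."""
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.normal(7, 1, size=(6, 6)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(6)],
    )
    groups = {f"s{i}": ("control" if i < 3 else "treated") for i in range(6)}
    return CohortDataset(ExpressionMatrix(data), groups, "tiny")
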