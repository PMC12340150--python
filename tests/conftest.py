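"""Shared fixtures: small simulated datasets and matrix builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pepmarker.io import QuantMatrix
from pepmarker.sim import (
    EffectSpec,
    SimConfig,
    generate_peptidome,
    generate_proteome,
    simulate_cohort,
)


def build_log2_matrix(
    n_peptides: int,
    n_a: int,
    n_b: int,
    cv: float = 0.2,
    seed: int = 0,
    effects: dict[int, float] | None = None,
    group_a: str = "ALS",
    group_b: str = "Con",
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Complete log2 matrix with lognormal noise and optional planted log2 shifts.

    `effects` maps peptide row index -> log2 difference added to group A.
    """
    rng = np.random.default_rng(seed)
    sigma_log2 = np.sqrt(np.log1p(cv**2)) / np.log(2)
    base = rng.uniform(10, 30, size=n_peptides)
    cols = [f"{group_a}_{i}" for i in range(n_a)] + [
        f"{group_b}_{i}" for i in range(n_b)
    ]
    X = base[:, None] + rng.normal(0, sigma_log2, size=(n_peptides, n_a + n_b))
    if effects:
        for row, shift in effects.items():
            X[row, :n_a] += shift
    labels = {c: (group_a if c.startswith(group_a) else group_b) for c in cols}
    ids = [f"P{i:04d}" for i in range(n_peptides)]
    return pd.DataFrame(X, index=ids, columns=cols), labels


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete simulated cohort shared across tests."""
    cfg = SimConfig(
        n_proteins=40,
        n_peptides=600,
        n_per_group={"Con": 12, "ALS": 12},
        effect_table=(EffectSpec("PEP001", "ALS", 2.0, "up"),),
        tryptic_like_fraction={"Con": 0.20, "ALS": 0.25},
    )
    proteins = generate_proteome(cfg.n_proteins, 11)
    catalog, state = generate_peptidome(proteins, cfg, 11)
    matrix, annotations, state = simulate_cohort(catalog, state, cfg, 11)
    return dict(
        config=cfg, proteins=proteins, catalog=catalog, matrix=matrix,
        annotations=annotations, state=state,
    )
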