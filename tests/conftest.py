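"""Shared fixtures: small hand-built census tables and session-scoped
simulation studies reused by several test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from shellrank.glmm import fit_glmm
from shellrank.recovery import glmm_recovery, mnlogit_recovery
from shellrank.simulate import OCCUPANCY_SPEC, generate_table


@pytest.fixture()
def tiny_shells() -> pd.DataFrame:
    """Well-formed five-shell census across two groups."""
    return pd.DataFrame(
        {
            "group_id": ["A", "A", "A", "B", "B"],
            "shell_id": ["s1", "s2", "s3", "s1", "s2"],
            "location": ["surface", "basement", "surface", "surface", "basement"],
            "intactness_pct": [80, 30, 100, 60, 90],
            "entrance_cm": [2.0, 1.5, 2.4, 1.8, 2.1],
            "smooth": [0, 1, 0, 0, 0],
            "sponge": [0, 0, 1, 0, 0],
            "shrimp": [0, 0, 0, 1, 0],
            "crab": [0, 0, 0, 0, 1],
            "excluded_reason": ["none"] * 5,
        }
    )


def synthetic_census_with_printed_margins() -> pd.DataFrame:
    """Synthetic stand-in for the field census, built so its *marginal*
    counts equal the field-census margins the generator is calibrated to:
    1256 shells collected over 41 groups,
    exclusions 57 (live snail) + 138 (sediment/blocked) + 4 (heterospecific
    fish), and among the 1057 usable shells 76 smooth, 49 sponge-covered,
    43 with shrimp, 35 with crabs, and 282 basement vs 775 surface."""
    n_usable, n_groups = 1057, 41
    rows = {
        "group_id": [f"G{(i % n_groups) + 1:02d}" for i in range(n_usable)],
        "shell_id": [f"S{i:04d}" for i in range(n_usable)],
        "location": ["basement"] * 282 + ["surface"] * 775,
        "intactness_pct": [30 + 10 * (i % 8) for i in range(n_usable)],
        "entrance_cm": [round(1.5 + 0.1 * (i % 10), 1) for i in range(n_usable)],
        "smooth": [1] * 76 + [0] * (n_usable - 76),
        "sponge": [1] * 49 + [0] * (n_usable - 49),
        "shrimp": [0] * 76 + [1] * 43 + [0] * (n_usable - 119),
        "crab": [0] * 119 + [1] * 35 + [0] * (n_usable - 154),
        "excluded_reason": ["none"] * n_usable,
    }
    usable = pd.DataFrame(rows)
    excl = []
    for reason, count in (
        ("live_snail", 57),
        ("sediment_blocked", 138),
        ("heterospecific_fish", 4),
    ):
        for i in range(count):
            excl.append(
                {
                    "group_id": f"G{(i % n_groups) + 1:02d}",
                    "shell_id": f"X{reason[:4]}{i:04d}",
                    "location": "surface",
                    "intactness_pct": 50,
                    "entrance_cm": 2.0,
                    "smooth": 0,
                    "sponge": 0,
                    "shrimp": 0,
                    "crab": 0,
                    "excluded_reason": reason,
                }
            )
    return pd.concat([usable, pd.DataFrame(excl)], ignore_index=True)


@pytest.fixture(scope="session")
def margin_census() -> pd.DataFrame:
    return synthetic_census_with_printed_margins()


@pytest.fixture(scope="session")
def default_table():
    """One generator-default census (41 groups) plus its truth."""
    return generate_table(seed=42)


@pytest.fixture(scope="session")
def occupancy_fit(default_table):
    shells, _ = default_table
    return fit_glmm(OCCUPANCY_SPEC, shells)


@pytest.fixture(scope="session")
def glmm_recovery_study():
    """200-replicate occupancy-GLMM recovery at the default conditions."""
    return glmm_recovery(n_reps=200, master_seed=1)


@pytest.fixture(scope="session")
def mnlogit_recovery_study():
    """100-replicate occupant-class multinomial recovery (group dummies)."""
    return mnlogit_recovery(n_reps=100, master_seed=1)


def toy_glmm_data(seed: int = 7, n_groups: int = 3, per_group: int = 6):
    """Tiny grouped binary dataset with one continuous and one binary
    covariate, for loglik-oracle comparisons."""
    rng = np.random.default_rng(seed)
    n = n_groups * per_group
    df = pd.DataFrame(
        {
            "x": rng.normal(size=n),
            "b": rng.integers(0, 2, size=n).astype(float),
            "group_id": np.repeat([f"g{i}" for i in range(n_groups)], per_group),
        }
    )
    beta = np.array([-0.5, 0.8, 0.4])
    sigma = 0.7
    u = rng.normal(0, sigma, n_groups)
    eta = beta[0] + beta[1] * df["x"].to_numpy() + beta[2] * df["b"].to_numpy()
    eta = eta + u[np.repeat(np.arange(n_groups), per_group)]
    df["y"] = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return df
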