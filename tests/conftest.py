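import numpy as np
import pytest

from fcselect import (
    CohortSpec,
    RegionMap,
    SsvsConfig,
    VariableSpec,
    standardize,
)


@pytest.fixture
def tiny_map() -> RegionMap:
    """Three regions over six atlas labels."""
    return RegionMap(
        regions=(("A", (1, 2)), ("B", (3,)), ("C", (4, 5, 6))),
        atlas_name="toy",
    )


@pytest.fixture
def two_region_map() -> RegionMap:
    """Two four-label regions (enough labels to limit aggregation noise)."""
    return RegionMap(
        regions=(("A", (1, 2, 3, 4)), ("B", (5, 6, 7, 8))),
        atlas_name="toy",
    )


@pytest.fixture
def small_spec(tiny_map) -> CohortSpec:
    """A fast, fully specified cohort recipe for end-to-end tests."""
    variables = [
        VariableSpec("age", "continuous", 45.0, 15.0, lower=18, upper=85),
        VariableSpec("gender", "binary", 0.6),
        VariableSpec("stress", "continuous", 5.0, 2.0),
        VariableSpec("sleep", "continuous", 4.0, 3.0, lower=0),
    ]
    corr = np.eye(4)
    corr[2, 3] = corr[3, 2] = 0.4
    return CohortSpec(
        n_subjects=40,
        n_timepoints=60,
        region_map=tiny_map,
        self_report=variables,
        self_report_corr=corr,
        true_beta={"sleep": 0.6},
        noise_sd=1.0,
        mcar_rates={"stress": 0.1},
        by_design_rule=None,
        seed=123,
    )


def make_design(n: int, p: int, beta: np.ndarray, noise_sd: float, seed: int):
    """Standardized Gaussian design with a known sparse linear signal."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, p))
    y = x @ beta + rng.normal(0.0, noise_sd, n)
    return standardize(x, y)


@pytest.fixture
def fast_config() -> SsvsConfig:
    return SsvsConfig(n_iter=4000, burn_in=1000, seed=5)
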