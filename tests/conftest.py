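import pandas as pd
import pytest

import dualreporter as dr

# Conditions for large-n estimator-convergence checks: total sigma_G = 0.4
# placed at the cell level (the decomposition cannot distinguish levels and
# cell-level placement gives the smallest Monte-Carlo error per cell).
LARGE_N_COMMON = dict(
    sigma_G_animal=0.0, sigma_G_cell=0.4, sigma_P=0.1,
    sigma_gamma=0.05, sigma_meas=0.0,
    n_experiments=1, n_animals_per_experiment=12500, cells_per_animal=8,
)


@pytest.fixture(scope="session")
def large_type2_params() -> dr.GenerativeParams:
    return dr.GenerativeParams(experiment_type="typeII",
                               promoter_a="hsp-16.2", promoter_b="vit-2",
                               seed=11, **LARGE_N_COMMON)


@pytest.fixture(scope="session")
def large_type2_cells(large_type2_params) -> pd.DataFrame:
    return dr.simulate_cells(large_type2_params, include_latent=False)


@pytest.fixture(scope="session")
def large_type1_gamma(large_type2_params) -> dict:
    """Type I intrinsic-noise estimates for both promoters at n = 1e5."""
    lookup = {}
    for seed, prom in ((12, "hsp-16.2"), (13, "vit-2")):
        params = dr.type1_params(large_type2_params, prom, seed=seed)
        cells = dr.simulate_cells(params, include_latent=False)
        res = dr.decompose_type1(cells)
        lookup[prom] = res.aggregate["eta2_gamma"]
    return lookup


@pytest.fixture(scope="session")
def paper_scale_type2_cells() -> pd.DataFrame:
    """One paper_like Type II table at the study scale (3 x 10 x 8 cells)."""
    params = dr.default_params("paper_like", experiment_type="typeII",
                               seed=101)
    return dr.simulate_cells(params)


@pytest.fixture()
def four_point_two_ring_cells() -> pd.DataFrame:
    """Zero-noise two-ring table whose setpoint ratio differs 1 vs 3."""
    return pd.DataFrame({
        "experiment_id": ["e"] * 4,
        "animal_id": ["a1", "a2", "a1", "a2"],
        "ring": [1, 1, 2, 2],
        "cell_id": ["int1.1", "int1.2", "int2.1", "int2.2"],
        "nucleus_count": [2] * 4,
        "ch_green": [1.0, 1.0, 1.0, 1.0],
        "ch_red": [1.0, 1.0, 3.0, 3.0],
    })
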