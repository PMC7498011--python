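import numpy as np
import pytest

import switchla as sla


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def null_matrix_transformed():
    """50 genes x 120 samples of pure noise, NQT + standardized."""
    m = sla.generate_null_matrix(50, 120, seed=101)
    return sla.transform_matrix(m)


def planted_study_spec(seed: int, rho_high: float = 0.8, rho_low: float = -0.8) -> sla.StudySpec:
    """Three planted switch triplets among 50 genes, 120 samples."""
    triplets = tuple(
        sla.TripletSpec(
            x3_id=f"g{i * 3:04d}",
            pair_ids=(f"g{i * 3 + 1:04d}", f"g{i * 3 + 2:04d}"),
            rho_high=rho_high,
            rho_low=rho_low,
        )
        for i in range(3)
    )
    return sla.StudySpec(n_genes=50, n_samples=120, seed=seed, triplets=triplets)


PLANTED_TRIOS = {
    ("g0001", "g0002", "g0000"),
    ("g0004", "g0005", "g0003"),
    ("g0007", "g0008", "g0006"),
}
PLANTED_GENES = {g for trio in PLANTED_TRIOS for g in trio}


@pytest.fixture(scope="session")
def planted_screen():
    """One planted study and its screened triplet list."""
    mat, truth = sla.generate_study(planted_study_spec(seed=424242))
    triplets = sla.screen_triplets(sla.transform_matrix(mat))
    return mat, truth, triplets


@pytest.fixture(scope="session")
def toy_run(tmp_path_factory):
    """One full pipeline run on the packaged toy config."""
    out = tmp_path_factory.mktemp("toy_run")
    return sla.run_pipeline(sla.toy_config(out, seed=17)), out
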