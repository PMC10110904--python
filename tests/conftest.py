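import numpy as np
import pandas as pd
import pytest

from panchol import (
    PangenomeConfig,
    PresenceAbsenceMatrix,
    classify,
    generate_pangenome,
    infer_orthogroups,
    summarize,
)

FIXTURE_SEED = 11


@pytest.fixture()
def rng():
    # fresh, identically-seeded generator per test: results do not depend on
    # which other tests ran first
    return np.random.default_rng(FIXTURE_SEED)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale pangenome: same structure as the default, fewer families."""
    return PangenomeConfig(
        n_core_families=12,
        n_accessory_families=8,
        n_unique_per_strain=2,
        n_group_marker_families=4,
        substitution_rate=0.02,
        seed=FIXTURE_SEED,
    )


@pytest.fixture(scope="session")
def small_pangenome(small_config):
    return generate_pangenome(small_config)


@pytest.fixture(scope="session")
def small_inference(small_pangenome):
    proteomes, truth = small_pangenome
    ogs, matrix, hits = infer_orthogroups(proteomes)
    return proteomes, truth, ogs, matrix, hits


@pytest.fixture(scope="session")
def small_summary(small_inference):
    _, _, _, matrix, _ = small_inference
    labels = classify(matrix)
    return labels, summarize(matrix, labels)


def build_matrix(rows: dict[str, list[int]], strains: list[str]) -> PresenceAbsenceMatrix:
    """Helper: presence/copy-number matrix from literal row dicts."""
    return PresenceAbsenceMatrix(
        counts=pd.DataFrame.from_dict(rows, orient="index", columns=strains)
    )
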