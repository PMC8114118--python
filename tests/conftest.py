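"""Shared fixtures: small synthetic experiments with known ground truth."""

import numpy as np
import pandas as pd
import pytest

from protprep import (
    CVPolicy,
    SyntheticConfig,
    assemble_experiment,
    average_replicates,
    correct_local,
    filter_replicates,
    generate_experiment,
    read_layout,
    read_quantification_file,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    # compact geometry for speed; noise model at the package defaults
    return SyntheticConfig(n_slides=2, blocks_per_slide=4, n_features=20, seed=1)


@pytest.fixture(scope="session")
def small_experiment(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    return generate_experiment(small_config, out_dir=str(out))


@pytest.fixture(scope="session")
def assembled(small_experiment):
    layout = read_layout(*small_experiment.layout_paths)
    fragments = [read_quantification_file(p) for p in small_experiment.gpr_paths]
    return assemble_experiment(fragments, layout), layout


@pytest.fixture(scope="session")
def corrected(assembled):
    table, layout = assembled
    return correct_local(table), layout


@pytest.fixture(scope="session")
def antigen_matrix(corrected):
    """Replicate-averaged antigen matrix from the small experiment."""
    table, layout = corrected
    filtered, report = filter_replicates(table, CVPolicy(20.0, 100.0, 2))
    matrix = average_replicates(filtered, report)
    antigens = layout.features.loc[layout.features["feature_class"] == "antigen", "feature"]
    return matrix.loc[matrix.index.intersection(antigens)]


def spot_table_from_records(records) -> "pd.DataFrame":
    return pd.DataFrame.from_records(records)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
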