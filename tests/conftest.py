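"""Shared fixtures: small planted simulations and the packaged reference tables."""

import pandas as pd
import pytest

from coldomics import io, simulate
from coldomics.degsets import ExpressionMatrix


@pytest.fixture(scope="session")
def planted_config() -> simulate.ExpressionSimConfig:
    """Small zero-noise design with every planted category populated."""
    return simulate.ExpressionSimConfig(
        n_genes=400,
        tolerant_only_up=12,
        tolerant_only_down=8,
        sensitive_only_up=9,
        sensitive_only_down=6,
        common_up=15,
        common_down=10,
        enhanced_common_up=7,
        enhanced_common_down=4,
        noise_sd_log=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def planted_matrix(planted_config) -> tuple[ExpressionMatrix, simulate.SimTruth]:
    values, meta, truth = simulate.gen_expression(planted_config)
    return ExpressionMatrix(values, meta), truth


@pytest.fixture(scope="session")
def lipidome_noise_free():
    cfg = simulate.LipidomeSimConfig(noise_cv=0.0, replicates=3, seed=5)
    values, meta, truth = simulate.gen_lipidome(cfg)
    return values, meta, truth


@pytest.fixture(scope="session")
def reference_dbi() -> pd.DataFrame:
    return io.reference_dbi_table()


@pytest.fixture(scope="session")
def reference_ffa() -> pd.DataFrame:
    return io.reference_ffa_table()
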