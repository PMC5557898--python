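"""Shared fixtures: small synthetic studies generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from twinconcord.expression import PairedExpressionMatrix
from twinconcord.simulate import GeneratorConfig, SimulatedStudy, simulate_study


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Compact study: 8 MZ pairs, 20 DZ pairs, 300 genes."""
    return GeneratorConfig(
        seed=11,
        n_mz_pairs=8,
        n_dz_pairs=20,
        n_controls=4,
        n_genes=300,
        n_epi_program=25,
        n_tracing=30,
    )


@pytest.fixture(scope="session")
def study(small_config) -> SimulatedStudy:
    return simulate_study(small_config)


def make_matrix(
    values: np.ndarray | list,
    genes: list[str],
    samples: list[str],
    pairs: dict[str, str],
    group: dict[str, str] | None = None,
    scale: str = "linear",
) -> PairedExpressionMatrix:
    """Hand-build a small paired expression matrix."""
    df = pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=samples)
    return PairedExpressionMatrix(
        values=df,
        pair_map=pd.Series(pairs),
        group=pd.Series(group) if group else None,
        scale=scale,
    )
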