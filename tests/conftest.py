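from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ribopolya.expression import ExpressionMatrix
from ribopolya.io_formats import SampleMeta

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(values: np.ndarray, library_type: str = "polyA",
                condition: str = "0h", prefix: str | None = None,
                genes: list[str] | None = None) -> ExpressionMatrix:
    """Small ExpressionMatrix helper: values is genes x samples."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    prefix = prefix or ("P" if library_type == "polyA" else "R")
    samples = [
        SampleMeta(f"{prefix}{j}", library_type, condition, str(j + 1))
        for j in range(n_samples)
    ]
    df = pd.DataFrame(values, index=genes, columns=[s.sample_id for s in samples])
    return ExpressionMatrix(df, samples)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


@pytest.fixture
def paired_matrices(rng):
    """Random paired polyA/ribo matrices over a shared gene universe."""
    n_genes, n_reps = 200, 6
    base = rng.lognormal(2.0, 1.5, size=n_genes)
    polya = make_matrix(
        base[:, None] * rng.lognormal(0.0, 0.1, size=(n_genes, n_reps)),
        "polyA",
    )
    effect = rng.lognormal(0.0, 0.5, size=n_genes)
    ribo = make_matrix(
        (base * effect)[:, None] * rng.lognormal(0.0, 0.1, size=(n_genes, n_reps)),
        "ribominus",
    )
    return polya, ribo
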