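"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stromastage.io_formats import CountMatrix
from stromastage.sc_pipeline import ClusterLabeling, NormalizedMatrix, normalize


def make_count_matrix(counts: np.ndarray, stage: str = "IB",
                      genes=None, cells=None) -> CountMatrix:
    """Wrap a raw gene x cell array in a CountMatrix with stub metadata."""
    counts = np.asarray(counts)
    g = genes or [f"G{i}" for i in range(counts.shape[0])]
    c = cells or [f"C{i}" for i in range(counts.shape[1])]
    meta = pd.DataFrame(
        {"patient_id": "P01",
         "tissue": "normal" if stage == "Normal" else "tumor",
         "stage": stage},
        index=c,
    )
    return CountMatrix(genes=g, cells=c, counts=counts, cell_meta=meta)


def make_norm(counts: np.ndarray, **kw) -> NormalizedMatrix:
    return normalize(make_count_matrix(counts, **kw))


def nb_counts(rng: np.random.Generator, mu, theta: float,
              shape) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draw with mean mu, dispersion
    theta."""
    lam = rng.gamma(theta, np.broadcast_to(mu, shape) / theta)
    return rng.poisson(lam)


@pytest.fixture(scope="session")
def default_sim():
    """One full-size synthetic cohort plus its truth tables."""
    from stromastage import synthetic_data as sd

    spec = sd.default_spec(seed=11)
    cm, truth = sd.generate_scrnaseq(spec)
    return spec, cm, truth


def labeling_from(labels) -> ClusterLabeling:
    return ClusterLabeling(labels=np.asarray(labels), params={})
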