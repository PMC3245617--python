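"""Shared fixtures: one default-size synthetic study and its preprocessed
matrices, generated once per session."""

import numpy as np
import pandas as pd
import pytest

from mirlineage import (ExpressionMatrix, SimulationConfig, detection_filter,
                        preprocess_mirna, simulate_dataset)


@pytest.fixture(scope="session")
def default_dataset():
    """Study-scale dataset with every kind of planted effect (seed 1)."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def preprocessed(default_dataset):
    mirna, mrna, sheet, pmap, targets, truth = default_dataset
    normalized, zscores = preprocess_mirna(mirna, pmap)
    mrna_filtered = detection_filter(mrna)
    return normalized, zscores, mrna_filtered


def make_matrix(values, samples=None, probes=None, calls=None, scale="log2"):
    """Small hand-built ExpressionMatrix for unit tests."""
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    vdf = pd.DataFrame(values, index=pd.Index(probes, name="probe"),
                       columns=samples)
    cdf = None
    if calls is not None:
        cdf = pd.DataFrame(np.asarray(calls, dtype="<U1"),
                           index=vdf.index, columns=samples)
    return ExpressionMatrix(values=vdf, calls=cdf, scale=scale)


def make_probe_map(probes, features=None, strand=None, is_control=None,
                   species_ok=None, kind="miRNA"):
    n = len(probes)
    return pd.DataFrame({
        "probe": probes,
        "feature": features or [f"f{i}" for i in range(n)],
        "kind": kind,
        "strand": strand or ["+"] * n,
        "is_control": is_control or [0] * n,
        "species_ok": species_ok or [1] * n,
        "replicate": [1] * n,
    })
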