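"""Shared fixtures: small hand-built and random intensity tables."""

from __future__ import annotations

import numpy as np
import pytest

from lfqdiff import ALL_TISSUES, Tissue, make_intensity_table


@pytest.fixture
def rng():
    return np.random.default_rng(20140805)


def build_table(intensities, tissues=ALL_TISSUES, accessions=None, **kwargs):
    """Build an IntensityTable from a (protein, experiment, tissue) array."""
    arr = np.asarray(intensities, dtype=float)
    if accessions is None:
        accessions = [f"P{i:04d}" for i in range(arr.shape[0])]
    return make_intensity_table(accessions, arr, tissues=tissues, **kwargs)


def random_table(rng, n_proteins=30, n_experiments=3, dropout=0.15, scale=1000.0):
    """Random positive intensities with independent missingness, all 5 tissues."""
    arr = scale * rng.lognormal(mean=0.0, sigma=1.0,
                                size=(n_proteins, n_experiments, len(ALL_TISSUES)))
    mask = rng.random(arr.shape) < dropout
    arr[mask] = 0.0
    # keep every sample non-degenerate
    for e in range(n_experiments):
        for t in range(len(ALL_TISSUES)):
            if (arr[:, e, t] == 0).all():
                arr[0, e, t] = scale
    return build_table(arr)


@pytest.fixture
def table_factory(rng):
    def make(**kwargs):
        return random_table(rng, **kwargs)

    return make


CHOL, NECK, TYMP, EACS, MUC = Tissue
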