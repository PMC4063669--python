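"""Shared fixtures: synthetic embryos generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from atlasforge import EmbryoSpec, NucleusSet, generate_embryo


@pytest.fixture(scope="session")
def default_embryo():
    """The default synthetic blastoderm: channels plus ground truth."""
    spec = EmbryoSpec(seed=0)
    nuc, genes, truth = generate_embryo(spec)
    return spec, nuc, genes, truth


@pytest.fixture(scope="session")
def noiseless_embryo():
    """Noise-free embryo for exact detection checks."""
    spec = EmbryoSpec(seed=1, noise_sd=0.0)
    nuc, genes, truth = generate_embryo(spec)
    return spec, nuc, genes, truth


@pytest.fixture(scope="session")
def true_nuclei(default_embryo):
    _, _, _, truth = default_embryo
    return NucleusSet(truth.true_centers)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
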