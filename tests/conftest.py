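"""Shared fixtures: small synthetic worlds reused across test modules."""
from __future__ import annotations

import numpy as np
import pytest

from e2dyn.synthetic import (
    PerturbationSpec,
    SpectrumSpec,
    internal_mode_basis,
    make_ca_chain,
    make_toy_structure,
    make_variant_family,
)


@pytest.fixture(scope="session")
def chain40():
    return make_ca_chain(40, seed=0)


@pytest.fixture(scope="session")
def toy_structure():
    return make_toy_structure(10, seed=1)


@pytest.fixture(scope="session")
def separated_spectrum():
    """10 well-separated modes (ratio 0.6) on 40 atoms."""
    return SpectrumSpec(eigenvalues=0.004 * 0.6 ** np.arange(10), n_atoms=40)


@pytest.fixture(scope="session")
def swap_family(separated_spectrum):
    """Reference + a variant whose PC1 content sits at PC4 (swap fixture)."""
    return make_variant_family(
        separated_spectrum,
        [PerturbationSpec(swap_map=((1, 4),), label="swapped")],
        n_frames=500,
        n_replicates=1,
        seed=7,
    )


@pytest.fixture(scope="session")
def angle_family(separated_spectrum):
    """Reference + three variants of increasing subspace rotation."""
    perts = [
        PerturbationSpec(angle=0.25, label="mild"),
        PerturbationSpec(angle=0.60, label="moderate"),
        PerturbationSpec(angle=1.10, label="strong"),
    ]
    return make_variant_family(separated_spectrum, perts, n_frames=400,
                               n_replicates=2, seed=11)


@pytest.fixture(scope="session")
def mode20():
    """A single internal mode of a 20-atom chain."""
    chain = make_ca_chain(20, seed=0)
    return chain, internal_mode_basis(chain, 1, seed=2)[:, 0]
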