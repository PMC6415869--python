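"""Shared fixtures: small toy networks and synthetic sequencing samples."""

import pytest

from auxodesign import Medium, apply_medium
from auxodesign.synthdata import (
    SyntheticSeqSpec,
    ToyNetworkSpec,
    make_synthetic_coverage,
    make_toy_network,
)


@pytest.fixture(scope="session")
def toy():
    """3-precursor network: p1 has isozymes, p0 has an alternative substrate."""
    net, truth = make_toy_network(
        ToyNetworkSpec(
            seed=1,
            n_precursors=3,
            biomass_stoich=(1.78, 2.876, 0.86),
            isozymes=(1, 2, 1),
            alt_substrate_for=0,
        )
    )
    return net, truth


@pytest.fixture(scope="session")
def toy_on_medium(toy):
    net, truth = toy
    return apply_medium(net, truth.medium), truth


@pytest.fixture(scope="session")
def symmetric_pair():
    """2-precursor network with unit biomass coefficients, no decoys.

    Used for community tests: knocking SYN_p0 in one strain and SYN_p1 in the
    other gives a perfectly symmetric cross-feeding pair.
    """
    net, truth = make_toy_network(
        ToyNetworkSpec(
            seed=7,
            n_precursors=2,
            biomass_stoich=(1.0, 1.0),
            include_decoys=False,
        )
    )
    return net, truth, Medium({"EX_glc_e": 5.0})


@pytest.fixture(scope="session")
def seq_sample():
    """Synthetic 70/30 co-culture sample with one planted 2x duplication."""
    spec = SyntheticSeqSpec(
        seed=11,
        strain_fractions=(0.7, 0.3),
        planted_duplications=((40, 42, 2.0),),
    )
    track, genes, truth = make_synthetic_coverage(spec)
    return spec, track, genes, truth
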