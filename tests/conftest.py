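import pytest

from methanocom.synthetic import ToySpec, make_toy_community, make_toy_methanotroph


@pytest.fixture
def chain_spec():
    """Linear-chain toy: yield 0.5, 2 O2 per CH4, no secretion/maintenance."""
    return ToySpec(biomass_yield_per_ch4=0.5, o2_per_ch4=2.0)


@pytest.fixture
def chain_model(chain_spec):
    return make_toy_methanotroph(chain_spec)


@pytest.fixture
def defect_model():
    """Toy with every plantable defect present."""
    return make_toy_methanotroph(
        ToySpec(
            planted_defects=frozenset(
                {
                    "futile-loop",
                    "duplicate-reaction",
                    "proton-imbalance",
                    "orphan-metabolite",
                }
            )
        )
    )


@pytest.fixture
def asymmetric_pair():
    """Two-member toy community, member A yield 0.6 > member B yield 0.4."""
    return make_toy_community(
        ToySpec(biomass_yield_per_ch4=0.6), ToySpec(biomass_yield_per_ch4=0.4)
    )
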