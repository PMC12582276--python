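import numpy as np
import pytest

from chromatac.simulate import FragmentSimParams, StateSimSpec


@pytest.fixture(scope="session")
def type_c_lengths():
    """200k fragment lengths from a strong-ladder (Type C-like) stratum."""
    from chromatac.simulate import simulate_fragment_lengths
    return simulate_fragment_lengths(FragmentSimParams(
        period_bp=190.0, periodic_fraction=0.6, n_fragments=200_000, seed=1))


@pytest.fixture(scope="session")
def abc_specs():
    """Three states planted as Type A / B / C responses."""
    return [
        StateSimSpec("stateA",
                     FragmentSimParams(periodic_fraction=0.0),
                     FragmentSimParams(periodic_fraction=0.0),
                     gc_fraction=0.55, genome_share=0.3),
        StateSimSpec("stateB",
                     FragmentSimParams(period_bp=186.0, periodic_fraction=0.3),
                     FragmentSimParams(period_bp=190.0, periodic_fraction=0.3),
                     gc_fraction=0.45, genome_share=0.3),
        StateSimSpec("stateC",
                     FragmentSimParams(periodic_fraction=0.0),
                     FragmentSimParams(period_bp=190.0, periodic_fraction=0.7),
                     gc_fraction=0.35, genome_share=0.4),
    ]
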