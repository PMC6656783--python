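import numpy as np
import pytest

from alexburst import SimConfig, SimSpecies

STATE_MEANS = {"open": 0.30, "intermediate": 0.60, "closed": 0.90}
STATE_WEIGHTS = {"open": 0.50, "intermediate": 0.30, "closed": 0.20}
STATE_BOUND_FRACTION = {"open": 0.80, "intermediate": 0.50, "closed": 0.20}
D_BOUND = 0.60   # ribosome-bound, 1/ms
D_FREE = 1.10    # free, 1/ms
STATE_WINDOWS = {"open": (0.0, 0.45), "intermediate": (0.45, 0.75),
                 "closed": (0.75, 1.0)}


def three_state_species():
    """Six species: three conformational states, each split into a slow
    ribosome-bound and a fast free diffusing population."""
    species = []
    for st, w in STATE_WEIGHTS.items():
        a = STATE_BOUND_FRACTION[st]
        for tag, d, frac in (("bound", D_BOUND, a), ("free", D_FREE, 1 - a)):
            species.append(SimSpecies(
                name=f"{st}-{tag}", fret_e=STATE_MEANS[st],
                diffusion_rate_D=d, fraction=w * frac))
    return species


@pytest.fixture(scope="session")
def single_species_config():
    return SimConfig(
        species=[SimSpecies("da", fret_e=0.6)],
        duration_s=20.0, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
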