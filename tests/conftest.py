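import warnings

import numpy as np
import pytest

from rivertide import abundance as ab
from rivertide import synthetic_data as sd
from rivertide.core_io import Compartment

# short-sequence d2* warnings and zero-variance exclusions are expected noise
# in small-fixture tests
warnings.filterwarnings("ignore", message="sequence shorter than the recommended")
warnings.filterwarnings("ignore", message="excluded zero-variance genomes")


@pytest.fixture(scope="session")
def default_community():
    """The default synthetic dataset: 500 genomes, 32 samples, planted truth."""
    return sd.simulate_community(n_viral=350, n_microbial=150, seed=1)


@pytest.fixture(scope="session")
def module_community():
    """Module-recovery design: 3 planted modules of 30 + 60 noise genomes,
    all persistent, one compartment."""
    design = [s for s in sd.default_design(1) if s.compartment == Compartment.SW]
    return sd.simulate_community(
        n_viral=75,
        n_microbial=75,
        design=design,
        class_fractions={"SW": (1.0, 0.0, 0.0), "PW": (1.0, 0.0, 0.0)},
        compartment_fractions=(1.0, 0.0, 0.0),
        n_modules=3,
        module_size=30,
        seed=1,
    )


@pytest.fixture(scope="session")
def planted_genomes():
    """10 hosts, 10 linked + 10 unlinked viruses with planted evidence."""
    return sd.simulate_genomes(n_hosts=10, n_linked_viruses=10, n_unlinked_viruses=10,
                               seed=1)


@pytest.fixture(scope="session")
def tmm_default(default_community):
    cov, design, truth = default_community
    return ab.tmm_normalize(cov)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
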