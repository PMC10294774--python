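import numpy as np
import pytest

import freqtag as ft


@pytest.fixture(scope="session")
def pool():
    """A 60-sentence pool, the default stimulus inventory size."""
    return ft.make_sentence_pool(60, seed=11)


@pytest.fixture(scope="session")
def small_pool():
    return ft.make_sentence_pool(12, seed=7)


@pytest.fixture(scope="session")
def default_design():
    return ft.CohortDesign(seed=0)


@pytest.fixture(scope="session")
def tiny_design():
    """Minimal runnable cohort: 2 subjects/group, 8 trials."""
    return ft.CohortDesign(n_per_group=2, n_trials=8, seed=5)


def uniform_phase_spectrum(rng, n_trials, n_channels, n_bins):
    """Unit-magnitude spectrum with fully random trial phases (null data)."""
    phases = rng.uniform(-np.pi, np.pi, size=(n_trials, n_channels, n_bins))
    return ft.ComplexSpectrum.from_phases(phases)
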