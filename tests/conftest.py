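"""Shared fixtures: packaged bin grid, profile library, and simulated
datasets at the study's design conditions (built once per session)."""

import numpy as np
import pytest

from oilauth import default_bin_config, make_profile_library, synth
from oilauth.featurize import expand_bins, featurize_dataset


@pytest.fixture(scope="session")
def bin_config():
    return default_bin_config()


@pytest.fixture(scope="session")
def grid(bin_config):
    return expand_bins(bin_config)


@pytest.fixture(scope="session")
def library(bin_config):
    return make_profile_library(42, bins=bin_config)


@pytest.fixture(scope="session")
def study_records(library, grid):
    """The full adulteration design (495 mixtures) plus 21 pure replicates
    per class = 600 samples, simulated at default noise with a fixed seed
    and featurized with the packaged grid."""
    designs = synth.enumerate_design()
    samples = synth.simulate_dataset(library, designs, synth.NoiseModel(),
                                     pure_replicates=21, seed=7)
    return featurize_dataset(samples, grid)


@pytest.fixture(scope="session")
def binary_records(library, grid):
    """Qualitative-task dataset: the 495 mixtures plus 60 pure replicates
    per class (795 samples), so the pure-CAO class is populated enough for
    threshold classification to be meaningful rather than a majority-class
    artifact."""
    designs = synth.enumerate_design()
    samples = synth.simulate_dataset(library, designs, synth.NoiseModel(),
                                     pure_replicates=60, seed=7)
    return featurize_dataset(samples, grid)


@pytest.fixture(scope="session")
def small_noisefree_records(library, grid):
    """A compact zero-noise dataset (binary system only + pure controls)
    for exact-linearity and recovery oracles."""
    designs = synth.enumerate_design(systems=(1, 2))
    samples = synth.simulate_dataset(library, designs, synth.ZERO_NOISE,
                                     pure_replicates=3, seed=11)
    return featurize_dataset(samples, grid)
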