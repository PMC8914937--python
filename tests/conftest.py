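"""Shared fixtures: small synthetic datasets and pattern sets."""

import dataclasses

import numpy as np
import pytest

from imucanvas.pipeline import calibrate_on, prepare_patterns
from imucanvas.streams import WindowSpec
from imucanvas.synthetic import default_benchmark, generate_streams


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_dataset_spec():
    """Default benchmark classes, shrunk to 1 subject x 15 windows each."""
    dspec = default_benchmark(seed=17)
    return dataclasses.replace(
        dspec,
        n_subjects=1,
        classes=tuple(dataclasses.replace(c, duration=15) for c in dspec.classes),
    )


@pytest.fixture(scope="session")
def small_pattern_set(small_dataset_spec):
    streams = generate_streams(small_dataset_spec)
    return prepare_patterns(streams, WindowSpec(small_dataset_spec.window_length))


@pytest.fixture(scope="session")
def small_stats(small_pattern_set):
    return calibrate_on(small_pattern_set, range(len(small_pattern_set)))
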