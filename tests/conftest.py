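"""Shared fixtures: tiny phantom datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from wmhseg.model import MemberSpec
from wmhseg.phantom import PhantomConfig, generate_dataset


def tiny_phantom_config(seed=1, n_cases=8, size=64, n_slices=6):
    """A small, fast phantom configuration for unit tests."""
    return PhantomConfig(
        seed=seed,
        n_cases=n_cases,
        slice_shape=(size, size),
        n_slices=n_slices,
        spacing_mm=(5.5, 3.4, 3.4),
    )


def tiny_members(input_size=64, base_channels=4):
    return [
        MemberSpec("resnext", base_channels=base_channels, depth=2, groups=2,
                   input_size=input_size, lr_scale=1.0),
        MemberSpec("efficientnet", base_channels=base_channels, depth=2, expansion=2,
                   input_size=input_size, lr_scale=2.5),
    ]


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """8 phantom cases (4 train / 2 test / 2 unlabeled) written to disk once."""
    out = tmp_path_factory.mktemp("tiny_phantoms")
    config = tiny_phantom_config()
    manifest = generate_dataset(config, out, split=(0.5, 0.25, 0.25))
    return config, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
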