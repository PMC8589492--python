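"""Shared fixtures: small synthetic datasets and precision control."""

from __future__ import annotations

import numpy as np
import pytest

from gdynet import SynthParams, render_sample
from gdynet.nn.autograd import default_dtype


@pytest.fixture
def float64():
    """Run the autodiff engine in double precision (for FD oracles)."""
    with default_dtype(np.float64):
        yield


@pytest.fixture(scope="session")
def synth_params() -> SynthParams:
    return SynthParams()


@pytest.fixture(scope="session")
def sample_pair(synth_params):
    """One normal and one glaucomatous sample, fixed seeds."""
    return (render_sample(synth_params, 0, 101),
            render_sample(synth_params, 1, 202))


def make_arrays(params: SynthParams, n_per_class: int, seed0: int):
    """(images NCHW, labels, masks) for a tiny balanced set."""
    imgs, labels, masks = [], [], []
    i = 0
    for label in (0, 1):
        for _ in range(n_per_class):
            s = render_sample(params, label, seed0 + i)
            i += 1
            imgs.append(s.image.transpose(2, 0, 1))
            labels.append(label)
            masks.append(s.disc_mask)
    return np.stack(imgs), np.array(labels), np.stack(masks)


@pytest.fixture(scope="session")
def tiny_arrays(synth_params):
    return make_arrays(synth_params, 4, 7000)
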