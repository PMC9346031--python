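"""Shared fixtures: phantoms and end-to-end pipeline runs are expensive,
so they are generated once per session and shared across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from pancreatoscopy import default_duct_spec, generate_phantom, run_pipeline


@pytest.fixture(scope="session")
def easy_truth():
    return generate_phantom(default_duct_spec("easy", seed=7))


@pytest.fixture(scope="session")
def easy_result(easy_truth):
    return run_pipeline(
        easy_truth.image,
        easy_truth.head_tail,
        truth_mask=easy_truth.duct_mask,
        truth_centerline=easy_truth.centerline,
    )


@pytest.fixture(scope="session")
def realistic_truth():
    return generate_phantom(default_duct_spec("realistic", seed=7))


@pytest.fixture(scope="session")
def realistic_result(realistic_truth):
    return run_pipeline(
        realistic_truth.image,
        realistic_truth.head_tail,
        truth_mask=realistic_truth.duct_mask,
        truth_centerline=realistic_truth.centerline,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
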