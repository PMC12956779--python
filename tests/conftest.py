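"""Shared fixtures.

Phantom rendering is the expensive step, so the commonly used volumes are
session-scoped and rendered once.  Tests must not mutate fixture volumes;
use ``.copy()`` first.
"""

import pytest

from cordmorph import build_default_config, render_phantom, subset_config


@pytest.fixture(scope="session")
def small_config():
    """Three mid-cervical segments at the default 0.1 mm spacing."""
    return subset_config(build_default_config(seed=1, spacing=0.1),
                         ["C5", "C6", "C7"])


@pytest.fixture(scope="session")
def small_phantom(small_config):
    """(volume, truth) for the three-segment config."""
    return render_phantom(small_config)


@pytest.fixture(scope="session")
def small_volume(small_phantom):
    return small_phantom[0]


@pytest.fixture(scope="session")
def small_truth(small_phantom):
    return small_phantom[1]
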