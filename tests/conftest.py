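import numpy as np
import pytest

from alskit.track_io import Branch, Spot


def make_branch(positions, dt=2.0, branch_id=0, track_id=0):
    """Branch from a list of positions sampled at a fixed interval."""
    spots = [
        Spot(spot_id=i, track_id=track_id, frame=i, t=i * dt, position=tuple(p))
        for i, p in enumerate(positions)
    ]
    return Branch(branch_id=branch_id, track_id=track_id, spots=spots)


@pytest.fixture
def branch_factory():
    return make_branch


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
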