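"""Shared fixtures: synthetic scenes and docking templates."""

import numpy as np
import pytest

from origamech import probe_template, scan_recognition_sites, synth


@pytest.fixture(scope="session")
def duplex_scene():
    return synth.make_duplex_scene("AAAGCGCAAA", jitter=0.02, n_frames=5, seed=1)


@pytest.fixture(scope="session")
def raft_alternating():
    return synth.make_raft_scene(gap_schedule=[0.5, 10.0] * 3, probe_extent=3.0, seed=0)


@pytest.fixture(scope="session")
def probe3():
    return probe_template(3.0, 4000, seed=0)


@pytest.fixture(scope="session")
def raft_site(raft_alternating):
    sites = scan_recognition_sites(
        raft_alternating.design, raft_alternating.topology, "GCGC"
    )
    assert len(sites) == 1
    return sites[0]


def random_rigid_motion(rng):
    """A haphazard proper rotation + translation for invariance checks."""
    from scipy.spatial.transform import Rotation

    r = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return r.as_matrix(), rng.uniform(-20, 20, 3)
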