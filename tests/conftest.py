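import numpy as np
import pytest

import forktrace as ft


@pytest.fixture(scope="session")
def sim_config():
    return ft.SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def matrices(sim_config):
    return ft.make_transition_matrices(sim_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_profile(values, spacing=10, read_id="p", chrom="chrT", start=0,
                 raw_sd=None):
    """A smoothed-content profile on an evenly spaced coordinate grid."""
    values = np.asarray(values, dtype=float)
    positions = start + spacing * np.arange(values.size)
    return ft.BrdUProfile(read_id, chrom, positions, content=values,
                          raw_sd=raw_sd)


def track_profile(peak=0.7, floor=0.1, rise_pts=6, decay_pts=60, pre_pts=30,
                  post_pts=30, spacing=10, mirror=False, **kw):
    """Noiseless single-track content shape: steep rise, shallow decay."""
    rise = np.linspace(0.0, peak, rise_pts, endpoint=False)
    decay = floor + (peak - floor) * np.exp(-3 * np.linspace(0, 1, decay_pts))
    values = np.concatenate([
        np.zeros(pre_pts), rise, decay, np.full(post_pts, floor)])
    if mirror:
        values = values[::-1]
    return make_profile(values, spacing=spacing, **kw)
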