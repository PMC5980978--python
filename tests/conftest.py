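"""Shared fixtures: tiny geometric masks and random small-stack scenes."""

import numpy as np
import pytest
from skimage import draw

from viastack import ChannelStack, RunConfig

#: analysis parameters used for all random oracle-equivalence cases
ORACLE_PARAMS = dict(tmin=100, tmax=200, min_area=6, dilation=2)


def disk_mask(shape, center_rc, radius):
    """Boolean mask with one filled disk."""
    m = np.zeros(shape, dtype=bool)
    rr, cc = draw.disk(center_rc, radius, shape=shape)
    m[rr, cc] = True
    return m


def random_small_stack(rng, shape=(64, 64), n_slices=5):
    """A random three-channel stack of disjoint convex blobs.

    Objects are disks of constant intensity drawn from below, inside, and
    above the binarization window, plus sub-area debris; nuclei may chain
    over up to 3 consecutive slices with 1 px jitter.  Same-channel
    objects never touch in-plane, so both the watershed pipeline and the
    split-free brute-force reference see identical components.
    """
    h, w = shape
    green = np.zeros((n_slices, h, w), dtype=np.uint8)
    blue = np.zeros_like(green)
    red = np.zeros_like(green)

    def draw_disk(vol, z, center, radius, value):
        rr, cc = draw.disk(center, radius, shape=(h, w))
        vol[z, rr, cc] = value

    # cytosol blobs, present on every slice
    placed_green = []
    for _ in range(int(rng.integers(2, 5))):
        r = float(rng.uniform(4, 8))
        cy, cx = rng.uniform(r + 2, h - r - 2), rng.uniform(r + 2, w - r - 2)
        if any(np.hypot(cy - py, cx - px) < r + pr + 3 for py, px, pr in placed_green):
            continue
        placed_green.append((cy, cx, r))
        value = int(rng.choice([60, 150, 150, 230]))  # mostly inside the window
        for z in range(n_slices):
            draw_disk(green, z, (cy, cx), r, value)

    # nuclei: disks, possibly chained across consecutive slices
    placed = {"blue": [], "red": []}
    for _ in range(int(rng.integers(8, 15))):
        chan = "blue" if rng.uniform() < 0.5 else "red"
        r = float(rng.uniform(2, 5))
        cy, cx = rng.uniform(r + 3, h - r - 3), rng.uniform(r + 3, w - r - 3)
        if any(np.hypot(cy - py, cx - px) < r + pr + 5 for py, px, pr in placed[chan]):
            continue
        placed[chan].append((cy, cx, r))
        k = int(rng.integers(1, 4))
        z0 = int(rng.integers(0, n_slices))
        value = int(rng.choice([80, 150, 150, 150, 220]))
        vol = blue if chan == "blue" else red
        for dz in range(min(k, n_slices - z0)):
            jy, jx = rng.integers(-1, 2, size=2)
            draw_disk(vol, z0 + dz, (cy + jy, cx + jx), r, value)

    # debris strictly below min_area, on the nuclei channels
    for _ in range(int(rng.integers(0, 6))):
        cy, cx = rng.uniform(3, h - 3), rng.uniform(3, w - 3)
        chan = "blue" if rng.uniform() < 0.5 else "red"
        if any(np.hypot(cy - py, cx - px) < 2 + pr + 5 for py, px, pr in placed[chan]):
            continue
        vol = blue if chan == "blue" else red
        draw_disk(vol, int(rng.integers(0, n_slices)), (cy, cx), 1.2, 150)

    return green, blue, red


def arrays_to_stacks(green, blue, red):
    return {
        "msc_cytosol": ChannelStack(slices=list(green), channel_role="msc_cytosol"),
        "live_nuclei": ChannelStack(slices=list(blue), channel_role="live_nuclei"),
        "dead_nuclei": ChannelStack(slices=list(red), channel_role="dead_nuclei"),
    }


def oracle_config(tmp_path_factory=None):
    return RunConfig(
        input_dir=".",
        threshold_min=ORACLE_PARAMS["tmin"],
        threshold_max=ORACLE_PARAMS["tmax"],
        min_area=ORACLE_PARAMS["min_area"],
        roi_dilation=ORACLE_PARAMS["dilation"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_cfg(tmp_path):
    return RunConfig(input_dir=tmp_path)
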