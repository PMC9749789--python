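"""Shared fixtures: programmatically built images, masks and stacks."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from nucleoquant.io import ImageStack
from nucleoquant.segmentation import RegionLabelMap


def make_stack(planes, pixel_size=0.2, frame_interval=0.0, channel_names=None):
    """Build an ImageStack from a (frame, channel, row, col)-shaped array
    or from a single 2D plane / list of channel planes."""
    arr = np.asarray(planes, dtype=float)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[None]  # (channel, row, col) -> one frame
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(arr.shape[1])]
    return ImageStack(
        pixels=arr,
        channel_names=channel_names,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        bit_depth=16,
    )


@pytest.fixture
def two_level_nucleus():
    """One circular nucleus (intensity 50) holding one circular nucleolus
    (intensity 100), with matching ground-truth label maps."""
    shape = (96, 96)
    plane = np.zeros(shape)
    nuc = np.zeros(shape, np.int32)
    foc = np.zeros(shape, np.int32)
    rr, cc = draw_disk((48, 48), 30, shape=shape)
    plane[rr, cc] = 50.0
    nuc[rr, cc] = 1
    rr, cc = draw_disk((48, 48), 9, shape=shape)
    plane[rr, cc] = 100.0
    foc[rr, cc] = 1
    stack = make_stack(plane)
    return stack, RegionLabelMap(nuc, "nucleus"), RegionLabelMap(foc, "nucleolus", parent={1: 1})


@pytest.fixture
def disk_movie():
    """A 12-frame movie of a static bright disk, radius 20 px."""
    shape = (96, 96)
    plane = np.zeros(shape)
    rr, cc = draw_disk((48, 48), 20, shape=shape)
    plane[rr, cc] = 1000.0
    frames = np.repeat(plane[None, None], 12, axis=0)
    return make_stack(frames, pixel_size=0.1, frame_interval=0.25)


def rasterize_ellipse(a, b, pad=8, rotation=0.0):
    """Label image of one ellipse with semi-axes (a, b) in pixels."""
    size = int(2 * a + 2 * pad)
    labels = np.zeros((size, size), np.int32)
    rr, cc = draw_ellipse(size / 2, size / 2, a, b, shape=labels.shape, rotation=rotation)
    labels[rr, cc] = 1
    return labels
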