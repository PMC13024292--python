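import numpy as np
import pytest

from cervtrack.datamodel import LabelMaskSequence, RecordingMeta
from cervtrack.phantom import PhantomConfig, generate


@pytest.fixture(scope="session")
def small_phantom():
    """Clean default-contribution phantom at reduced scale (fast)."""
    cfg = PhantomConfig(n_frames=60, image_size=(256, 256), seed=11)
    return generate(cfg)


@pytest.fixture(scope="session")
def mid_phantom():
    """Clean phantom at 512 px, 100 frames, for tracking tests."""
    cfg = PhantomConfig(n_frames=100, image_size=(512, 512), seed=7)
    return generate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_sequence(frames, label_map=None, **meta_kwargs):
    frames = [np.asarray(f) for f in frames]
    meta = RecordingMeta(**meta_kwargs)
    if label_map is None:
        present = set()
        for f in frames:
            present.update(int(v) for v in np.unique(f) if v != 0)
        label_map = {l: f"C{l - 1}" for l in present} or {1: "C0"}
    return LabelMaskSequence(meta=meta, frames=frames, label_map=label_map)


@pytest.fixture()
def square_pair():
    """Two 100-px-overlap rectangles with known counts for DSC/IoU oracles."""
    a = np.zeros((40, 40), dtype=bool)
    b = np.zeros((40, 40), dtype=bool)
    a[5:15, 5:15] = True  # |A| = 100
    b[5:15, 10:20] = True  # |B| = 100, |A∩B| = 50, |A∪B| = 150
    return a, b
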