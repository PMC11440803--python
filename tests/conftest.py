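import math

import numpy as np
import pytest

from puncta_coloc.puncta_detect import Punctum


def make_punctum(x: float, y: float, r: float, pid: int = 0, channel: str = "red") -> Punctum:
    """A punctum stub with a prescribed equivalent-disk radius."""
    return Punctum(
        id=pid,
        channel=channel,
        centroid_x=x,
        centroid_y=y,
        area=max(1, int(round(math.pi * r * r))),
        radius=r,
        bbox=(0, 0, 1, 1),
        circularity=1.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
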