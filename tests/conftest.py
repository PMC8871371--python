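import numpy as np
import pytest

from omiflim import SceneSpec, TimeAxis, make_irf, make_scene


@pytest.fixture(scope="session")
def axis():
    return TimeAxis()


@pytest.fixture(scope="session")
def irf260(axis):
    return make_irf(260.0, axis)


@pytest.fixture(scope="session")
def delta_irf(axis):
    return make_irf(0.0, axis)


@pytest.fixture(scope="session")
def ten_cell_scene():
    """Well-separated disks on a dark background, mixed TNFa status."""
    spec = SceneSpec(
        shape=(96, 96),
        n_cells=10,
        radius_range=(4.0, 6.0),
        tnfa_labels=(True, False, True, False, False, True, False, False, False, False),
        seed=42,
    )
    return make_scene(spec)


def match_labels_to_truth(segmented: np.ndarray, truth: np.ndarray) -> dict[int, int]:
    """Map each segmented label to the ground-truth cell id with the
    largest pixel overlap."""
    mapping = {}
    for lab in np.unique(segmented[segmented > 0]):
        overlap = truth[segmented == lab]
        overlap = overlap[overlap > 0]
        if overlap.size:
            ids, counts = np.unique(overlap, return_counts=True)
            mapping[int(lab)] = int(ids[np.argmax(counts)])
    return mapping
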