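import logging

import numpy as np
import pytest

from nucyto_loc.imaging.segment import CellCompartments
from nucyto_loc.synthgen.kinetics import Trajectory
from nucyto_loc.synthgen.scene import CellSpec, SyntheticScene, render_timelapse

logging.getLogger("nucyto_loc").setLevel(logging.ERROR)


@pytest.fixture
def flat_trajectory():
    """Single frame with nuclear concentration 2 and cytoplasmic 1."""
    return Trajectory(times_s=np.array([0.0]),
                      nuclear=np.array([2.0]),
                      cytoplasmic=np.array([1.0]))


@pytest.fixture
def single_cell_scene():
    def make(noise=(0.0, 0.0), blur_sigma=0.0, seed=0, gain=100.0,
             background=10.0, nucleus_radius=8.0, cell_radius=14.0):
        return SyntheticScene(
            cells=[CellSpec((24, 24), cell_radius, nucleus_radius)],
            gain=gain, background=background, noise=noise,
            blur_sigma=blur_sigma, seed=seed, shape=(48, 48),
        )
    return make


@pytest.fixture
def noiseless_frame(single_cell_scene, flat_trajectory):
    """Rendered noiseless frame plus truth and true-mask compartments."""
    stack, truth = render_timelapse(single_cell_scene(), flat_trajectory)
    comp = CellCompartments(truth.cell_labels, truth.nucleus_labels,
                            list(truth.cell_ids))
    return stack, truth, comp


def compartments_from_truth(truth) -> CellCompartments:
    return CellCompartments(truth.cell_labels, truth.nucleus_labels,
                            list(truth.cell_ids))
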