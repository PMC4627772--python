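import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucyto_loc.imaging.segment import CellCompartments
from nucyto_loc.imaging.stack import ImageStack
from nucyto_loc.synthgen.kinetics import (
    TranslocationKinetics,
    simulate_kinetics,
)
from nucyto_loc.synthgen.scene import render_timelapse
from nucyto_loc.translocation.ci import compute_ci, measure_frame, track_timelapse

from conftest import compartments_from_truth


class TestComputeCI:
    def test_homogeneous_distribution_is_one(self):
        assert compute_ci(50.0, 50.0, 10.0) == pytest.approx(1.0)

    def test_no_nuclear_signal_is_zero(self):
        assert compute_ci(10.0, 110.0, 10.0) == pytest.approx(0.0)

    def test_formula_evaluation(self):
        assert compute_ci(210.0, 110.0, 10.0) == pytest.approx(2.0)

    def test_small_denominator_marked_invalid(self):
        assert np.isnan(compute_ci(50.0, 10.0, 10.0))
        assert np.isnan(compute_ci(50.0, 9.0, 10.0))

    @settings(max_examples=50, deadline=None)
    @given(
        f_nuc=st.floats(0, 1e4),
        f_cyto=st.floats(0, 1e4),
        bg=st.floats(0, 1e3),
        gain=st.floats(0.01, 100),
        offset=st.floats(-50, 50),
    )
    def test_affine_invariance(self, f_nuc, f_cyto, bg, gain, offset):
        base = compute_ci(f_nuc, f_cyto, bg)
        transformed = compute_ci(gain * f_nuc + offset, gain * f_cyto + offset,
                                 gain * bg + offset, epsilon=0.0)
        if np.isfinite(base) and abs(f_cyto - bg) > 1e-6:
            assert transformed == pytest.approx(base, rel=1e-9)


class TestMeasureFrame:
    def test_uniform_compartments(self, noiseless_frame):
        stack, _, comp = noiseless_frame
        (m,) = measure_frame(stack.frame(0, "reporter"), comp, bg=10.0)
        assert m.f_nuc == pytest.approx(210.0)
        assert m.f_cyto == pytest.approx(110.0)
        assert m.ci == pytest.approx(2.0)
        assert m.valid

    def test_subtraction_identity_on_random_images(self, noiseless_frame):
        # whole-cell-minus-nucleus formulation == direct cytoplasm-mask mean
        _, truth, comp = noiseless_frame
        rng = np.random.default_rng(0)
        for _ in range(20):
            frame = rng.random(truth.cell_labels.shape) * 500.0
            (m,) = measure_frame(frame, comp, bg=0.0)
            direct = frame[comp.cytoplasm_mask(1)].mean()
            assert abs(m.f_cyto - direct) < 1e-10

    def test_noiseless_scene_matches_truth_exactly(self, noiseless_frame):
        stack, truth, comp = noiseless_frame
        (m,) = measure_frame(stack.frame(0, "reporter"), comp,
                             bg=truth.background)
        assert m.ci == truth.true_ci[0, 0]

    def test_invalid_denominator_not_dropped(self):
        cells = np.zeros((6, 6), dtype=np.int32)
        cells[1:5, 1:5] = 1
        nuclei = np.zeros((6, 6), dtype=np.int32)
        nuclei[2:4, 2:4] = 1
        comp = CellCompartments(cells, nuclei, [1])
        frame = np.full((6, 6), 10.0)  # f_cyto == bg
        (m,) = measure_frame(frame, comp, bg=10.0)
        assert not m.valid
        assert np.isnan(m.ci)
        assert m.reason


class TestTrackTimelapse:
    @staticmethod
    def _stack_and_comps(n_frames=4, ratio=2.0):
        shape = (16, 16)
        cells = np.zeros(shape, dtype=np.int32)
        cells[4:12, 4:12] = 1
        nuclei = np.zeros(shape, dtype=np.int32)
        nuclei[6:10, 6:10] = 1
        frame = np.full(shape, 10.0)
        frame[cells == 1] = 110.0
        frame[nuclei == 1] = 10.0 + ratio * 100.0
        data = np.stack([np.stack([frame, frame])] * n_frames)
        stack = ImageStack(data, {"reporter": 0, "nuclear_marker": 1}, 0.5,
                           frame_times_s=np.arange(n_frames) * 60.0)
        comp = CellCompartments(cells, nuclei, [1])
        return stack, [comp] * n_frames

    def test_static_cell_flat_series(self):
        stack, comps = self._stack_and_comps()
        df = track_timelapse(stack, comps, 10.0)
        assert df["ci"].tolist() == pytest.approx([2.0] * 4)
        assert df["t_s"].is_monotonic_increasing

    def test_lost_cell_recorded_as_missing(self):
        stack, comps = self._stack_and_comps()
        empty = CellCompartments(np.zeros((16, 16), dtype=np.int32),
                                 np.zeros((16, 16), dtype=np.int32), [])
        comps = comps[:3] + [empty]
        df = track_timelapse(stack, comps, 10.0)
        last = df[df.frame == 3].iloc[0]
        assert not last["valid"]
        assert last["reason"] == "missing"
        assert np.isnan(last["ci"])

    def test_no_cells_rejected(self):
        stack, _ = self._stack_and_comps()
        empty = CellCompartments(np.zeros((16, 16), dtype=np.int32),
                                 np.zeros((16, 16), dtype=np.int32), [])
        with pytest.raises(ValueError, match="no cells"):
            track_timelapse(stack, [empty] * 4, 10.0)

    def test_stimulus_step_series_rises(self, single_cell_scene):
        kin = TranslocationKinetics(k_in_base=0.05, k_in_stim=0.2, k_out=0.1,
                                    t_stim=300.0)
        times = np.arange(10) * 120.0
        traj = simulate_kinetics(kin, times)
        stack, truth = render_timelapse(single_cell_scene(), traj)
        comp = compartments_from_truth(truth)
        df = track_timelapse(stack, [comp] * 10, truth.background)
        ci = df["ci"].to_numpy()
        assert np.allclose(ci, truth.true_ci[:, 0], rtol=1e-9)
        assert ci[-1] > ci[0]
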