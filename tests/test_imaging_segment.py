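import numpy as np
import pytest

from nucyto_loc.imaging.segment import (
    build_compartments,
    segment_cells,
    segment_nuclei,
)
from nucyto_loc.synthgen.scene import render_timelapse


def disk(shape, center, radius):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def iou(a, b):
    return (a & b).sum() / (a | b).sum()


def two_disk_frame():
    frame = np.full((64, 64), 5.0)
    frame[disk((64, 64), (16, 16), 6)] = 100.0
    frame[disk((64, 64), (44, 44), 6)] = 100.0
    return frame


class TestSegmentNuclei:
    def test_two_bright_disks_give_two_labels(self):
        labels = segment_nuclei(two_disk_frame(), min_area_px=10)
        assert labels.max() == 2
        assert sorted(np.unique(labels)) == [0, 1, 2]

    def test_blank_frame_yields_empty_mask(self, caplog):
        labels = segment_nuclei(np.full((32, 32), 7.0))
        assert labels.max() == 0

    def test_area_filter_drops_specks(self):
        frame = np.full((64, 64), 5.0)
        frame[disk((64, 64), (16, 16), 6)] = 100.0
        frame[30, 30] = 100.0  # single-pixel speck
        labels = segment_nuclei(frame, min_area_px=10)
        assert labels.max() == 1

    def test_holes_are_filled(self):
        frame = np.full((64, 64), 5.0)
        d = disk((64, 64), (32, 32), 10)
        frame[d] = 100.0
        frame[32, 32] = 5.0  # dark hole inside the nucleus
        labels = segment_nuclei(frame, min_area_px=10)
        assert labels[32, 32] == 1

    def test_intensity_scale_invariance(self):
        frame = two_disk_frame()
        a = segment_nuclei(frame, min_area_px=10)
        b = segment_nuclei(frame * 3.7, min_area_px=10)
        assert np.array_equal(a, b)

    def test_iou_against_ground_truth(self, single_cell_scene, flat_trajectory):
        stack, truth = render_timelapse(single_cell_scene(), flat_trajectory)
        labels = segment_nuclei(stack.frame(0, "nuclear_marker"), min_area_px=10)
        assert labels.max() == 1
        assert iou(labels == 1, truth.nucleus_labels == 1) >= 0.9


class TestSegmentCells:
    def test_one_cell_contains_its_nucleus(self, noiseless_frame):
        stack, truth, _ = noiseless_frame
        nuclei = segment_nuclei(stack.frame(0, "nuclear_marker"), min_area_px=10)
        cells = segment_cells(stack.frame(0, "reporter"), nuclei)
        assert cells.max() == 1
        assert (cells[nuclei == 1] == 1).all()
        assert iou(cells == 1, truth.cell_labels == 1) >= 0.9

    def test_touching_cells_split_into_two(self):
        frame = np.full((48, 80), 5.0)
        frame[disk((48, 80), (24, 24), 12)] = 50.0
        frame[disk((48, 80), (24, 48), 12)] = 50.0
        nuclei = np.zeros((48, 80), dtype=np.int32)
        nuclei[disk((48, 80), (24, 24), 4)] = 1
        nuclei[disk((48, 80), (24, 48), 4)] = 2
        cells = segment_cells(frame, nuclei)
        assert set(np.unique(cells)) == {0, 1, 2}
        # the boundary splits the fused foreground near the midline
        assert (cells[nuclei == 1] == 1).all()
        assert (cells[nuclei == 2] == 2).all()
        col_of_1 = np.where(cells == 1)[1].max()
        col_of_2 = np.where(cells == 2)[1].min()
        assert col_of_1 < col_of_2 + 2

    def test_no_nuclei_gives_empty_mask(self):
        cells = segment_cells(two_disk_frame(), np.zeros((64, 64), dtype=int))
        assert cells.max() == 0

    def test_seed_outside_foreground_rejected(self):
        frame = np.full((32, 32), 5.0)
        frame[disk((32, 32), (8, 8), 5)] = 100.0
        nuclei = np.zeros((32, 32), dtype=int)
        nuclei[disk((32, 32), (24, 24), 3)] = 1  # in flat background
        with pytest.raises(ValueError, match="outside"):
            segment_cells(frame, nuclei)


class TestBuildCompartments:
    def test_square_cell_square_nucleus(self):
        cells = np.zeros((9, 9), dtype=int)
        cells[2:7, 2:7] = 1  # 5x5
        nuclei = np.zeros((9, 9), dtype=int)
        nuclei[3:6, 3:6] = 1  # 3x3 centered
        comp = build_compartments(cells, nuclei)
        assert comp.cell_ids == [1]
        assert comp.cytoplasm_mask(1).sum() == 16
        assert comp.nucleus_mask(1).sum() == 9
        # exact set difference
        assert np.array_equal(comp.cytoplasm_mask(1),
                              comp.cell_mask(1) & ~comp.nucleus_mask(1))

    def test_nucleus_equals_cell_flagged_invalid(self):
        cells = np.zeros((6, 6), dtype=int)
        cells[1:4, 1:4] = 1
        comp = build_compartments(cells, cells.copy())
        assert comp.cell_ids == []
        assert "cytoplasm" in comp.exclusions[1]

    def test_nucleus_spanning_two_cells_rejected(self):
        cells = np.zeros((6, 10), dtype=int)
        cells[:, :5] = 1
        cells[:, 5:] = 2
        nuclei = np.zeros((6, 10), dtype=int)
        nuclei[2:4, 3:7] = 1
        with pytest.raises(ValueError, match="spans"):
            build_compartments(cells, nuclei)

    def test_multiple_nuclei_in_one_cell_excluded(self):
        cells = np.zeros((8, 8), dtype=int)
        cells[1:7, 1:7] = 1
        nuclei = np.zeros((8, 8), dtype=int)
        nuclei[2, 2] = 1
        nuclei[5, 5] = 2
        comp = build_compartments(cells, nuclei)
        assert comp.cell_ids == []
        assert "multiple" in comp.exclusions[1]

    def test_synthetic_scene_areas_match_truth(self, noiseless_frame):
        _, truth, _ = noiseless_frame
        comp = build_compartments(truth.cell_labels, truth.nucleus_labels)
        assert comp.cell_ids == [1]
        assert comp.nucleus_mask(1).sum() == (truth.nucleus_labels == 1).sum()
        assert comp.cytoplasm_mask(1).sum() == (
            (truth.cell_labels == 1).sum() - (truth.nucleus_labels == 1).sum())

    def test_disjointness_and_containment_invariants(self, noiseless_frame):
        _, truth, _ = noiseless_frame
        comp = build_compartments(truth.cell_labels, truth.nucleus_labels)
        for cid in comp.cell_ids:
            nuc, cell = comp.nucleus_mask(cid), comp.cell_mask(cid)
            cyto = comp.cytoplasm_mask(cid)
            assert (nuc & ~cell).sum() == 0          # nucleus inside cell
            assert (nuc & cyto).sum() == 0           # disjoint
            assert np.array_equal(nuc | cyto, cell)  # exact partition
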