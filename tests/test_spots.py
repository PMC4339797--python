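"""Component labeling, threshold sweep/selection, counting, intensities,
conglomerates, and colocalization."""

import numpy as np
import pandas as pd
import pytest

from smfish3d import (
    CellROI,
    FilterParams,
    ImageStack,
    VoxelSize,
    classify_conglomerates,
    colocalize,
    count_per_cell,
    label_components,
    log_filter,
    measure_dot_intensities,
    normalize_filtered,
    select_threshold,
    threshold_sweep,
)
from smfish3d.spots import ThresholdSweep

from conftest import spot_stack
from oracles import bfs_component_count


def norm_stack(data, vs=None):
    return ImageStack(data, vs or VoxelSize(0.1, 0.1, 0.1), normalized=True)


class TestLabelComponents:
    def test_single_voxel(self):
        b = np.zeros((3, 3, 3), bool)
        b[1, 1, 1] = True
        _, count = label_components(b, 26)
        assert count == 1

    def test_corner_touch_connectivity(self):
        b = np.zeros((2, 2, 2), bool)
        b[0, 0, 0] = b[1, 1, 1] = True  # touch only at a corner
        assert label_components(b, 26)[1] == 1
        assert label_components(b, 18)[1] == 2
        assert label_components(b, 6)[1] == 2

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError, match="connectivity"):
            label_components(np.zeros((2, 2, 2), bool), 8)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_random_volumes_match_bfs_oracle(self, connectivity):
        rng = np.random.default_rng(42)
        for _ in range(25):
            b = rng.random((8, 8, 8)) < 0.2
            _, count = label_components(b, connectivity)
            assert count == bfs_component_count(b, connectivity)


class TestThresholdSweep:
    def test_all_zero_stack(self):
        sw = threshold_sweep(norm_stack(np.zeros((3, 8, 8))))
        assert len(sw.thresholds) == 100
        assert np.all(sw.counts == 0)

    def test_default_grid_is_100_uniform(self):
        sw = threshold_sweep(norm_stack(np.zeros((2, 4, 4))))
        np.testing.assert_allclose(sw.thresholds, np.arange(1, 101) / 100)

    def test_five_disjoint_dots_have_count_five_run(self, iso_voxel_size):
        stack = spot_stack(
            iso_voxel_size, shape=(9, 64, 64),
            centers=[(4, 10, 10), (4, 10, 40), (4, 40, 10), (4, 40, 40), (4, 25, 25)],
            amplitudes=[1.0] * 5, sigma_um=(0.2, 0.2),
        )
        f = normalize_filtered(log_filter(stack, FilterParams(0.2, 0.2)))
        sw = threshold_sweep(f)
        assert (sw.counts == 5).sum() >= 10  # long stable band at the true count

    def test_requires_normalized(self, iso_voxel_size):
        with pytest.raises(ValueError, match="normalized"):
            threshold_sweep(ImageStack(np.zeros((2, 4, 4)), iso_voxel_size))

    def test_counts_zero_above_image_maximum(self):
        data = np.zeros((2, 6, 6))
        data[0, 2, 2] = 0.42
        sw = threshold_sweep(norm_stack(data))
        assert np.all(sw.counts[sw.thresholds > 0.42] == 0)


def make_sweep(counts):
    n = len(counts)
    return ThresholdSweep(np.arange(1, n + 1) / n, np.asarray(counts))


class TestSelectThreshold:
    def test_plateau_from_worked_example(self):
        counts = [9, 7, 7, 7, 7, 2, 1, 0, 0, 0]
        sel = select_threshold(make_sweep(counts))
        assert sel.selected_count == 7
        # run spans grid indices 1..4; midpoint index 2
        assert sel.selected_threshold == pytest.approx(0.3)

    def test_equal_runs_tie_break_to_lower_threshold(self):
        counts = [0, 5, 5, 5, 0, 3, 3, 3, 0, 0]
        sel = select_threshold(make_sweep(counts))
        assert sel.selected_count == 5

    def test_all_zero_is_no_spots(self):
        sel = select_threshold(make_sweep([0] * 10))
        assert sel.selected_count == 0
        assert sel.selected_threshold is None

    def test_short_runs_fall_back_to_modal_count(self):
        counts = [9, 4, 7, 4, 7, 4, 2, 1, 0, 0]
        sel = select_threshold(make_sweep(counts))
        assert sel.selected_count == 4

    def test_manual_mode(self):
        sel = select_threshold(make_sweep([5, 4, 3, 2, 1, 0, 0, 0, 0, 0]),
                               mode="manual", manual_value=0.2)
        assert sel.selected_count == 4
        assert sel.selection_mode == "manual"

    def test_manual_off_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            select_threshold(make_sweep([1, 0]), mode="manual", manual_value=0.33)


class TestCountPerCell:
    def test_three_separated_spots_counted(self, iso_voxel_size):
        stack = spot_stack(
            iso_voxel_size, shape=(9, 48, 48),
            centers=[(4, 12, 12), (4, 12, 36), (4, 36, 24)],
            amplitudes=[1.0, 1.1, 0.9], sigma_um=(0.2, 0.2),
        )
        f = normalize_filtered(log_filter(stack, FilterParams(0.2, 0.2)))
        roi = CellROI("c1", {z: np.array([[0, 0], [0, 47], [47, 47], [47, 0]], float)
                             for z in range(9)})
        results, table = count_per_cell(f, [roi])
        assert results[0].transcript_count == 3
        assert len(table) == 3
        assert (table["cell_id"] == "c1").all()

    def test_mask_excluding_spots_counts_zero(self, iso_voxel_size):
        stack = spot_stack(iso_voxel_size, shape=(9, 48, 48),
                           centers=[(4, 40, 40)], amplitudes=[1.0], sigma_um=(0.2, 0.2))
        f = normalize_filtered(log_filter(stack, FilterParams(0.2, 0.2)))
        roi = CellROI("far", {4: np.array([[2, 2], [2, 10], [10, 10], [10, 2]], float)})
        results, table = count_per_cell(f, [roi])
        assert results[0].transcript_count == 0
        assert len(table) == 0

    def test_overlapping_rois_warn_first_come(self, iso_voxel_size):
        stack = spot_stack(iso_voxel_size, shape=(9, 48, 48),
                           centers=[(4, 24, 24)], amplitudes=[1.0], sigma_um=(0.2, 0.2))
        f = normalize_filtered(log_filter(stack, FilterParams(0.2, 0.2)))
        big = np.array([[0, 0], [0, 47], [47, 47], [47, 0]], float)
        rois = [CellROI("first", {z: big for z in range(9)}),
                CellROI("second", {z: big for z in range(9)})]
        with pytest.warns(UserWarning, match="first-come"):
            results, _ = count_per_cell(f, rois)
        assert results[0].transcript_count == 1
        assert results[1].transcript_count == 0

    def test_total_count_equals_spot_rows(self, iso_voxel_size):
        stack = spot_stack(
            iso_voxel_size, shape=(9, 64, 64),
            centers=[(4, 16, 16), (4, 16, 48), (4, 48, 16), (4, 48, 48)],
            amplitudes=[1.0, 0.9, 1.1, 1.0], sigma_um=(0.2, 0.2),
        )
        f = normalize_filtered(log_filter(stack, FilterParams(0.2, 0.2)))
        half = np.array([[0, 0], [0, 63], [30, 63], [30, 0]], float)
        other = np.array([[32, 0], [32, 63], [63, 63], [63, 0]], float)
        rois = [CellROI("top", {z: half for z in range(9)}),
                CellROI("bottom", {z: other for z in range(9)})]
        results, table = count_per_cell(f, rois)
        assert sum(r.transcript_count for r in results) == len(table)


class TestDotIntensities:
    def test_flat_component_mean(self):
        data = np.zeros((3, 8, 8))
        data[1, 2:4, 2:4] = 0.6
        table = measure_dot_intensities(norm_stack(data), 0.25)
        assert len(table) == 1
        assert table.loc[0, "mean_intensity"] == pytest.approx(0.6)
        assert table.loc[0, "voxel_count"] == 4

    def test_empty_image_empty_table(self):
        table = measure_dot_intensities(norm_stack(np.zeros((2, 4, 4))), 0.25)
        assert len(table) == 0

    def test_mean_intensity_at_least_threshold(self, iso_voxel_size):
        stack = spot_stack(iso_voxel_size, shape=(9, 32, 32),
                           centers=[(4, 16, 16)], amplitudes=[1.0], sigma_um=(0.2, 0.2))
        f = normalize_filtered(log_filter(stack, FilterParams(0.2, 0.2)))
        table = measure_dot_intensities(f, 0.25)
        assert (table["mean_intensity"] >= 0.25).all()

    def test_component_shrinks_as_threshold_rises(self, iso_voxel_size):
        stack = spot_stack(iso_voxel_size, shape=(9, 32, 32),
                           centers=[(4, 16, 16)], amplitudes=[1.0], sigma_um=(0.2, 0.2))
        f = normalize_filtered(log_filter(stack, FilterParams(0.2, 0.2)))
        sizes = [
            measure_dot_intensities(f, t).loc[0, "voxel_count"]
            for t in (0.2, 0.4, 0.6, 0.8)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_centroid_in_um_uses_voxel_size(self):
        data = np.zeros((3, 8, 8))
        data[1, 3, 5] = 0.9
        table = measure_dot_intensities(norm_stack(data, VoxelSize(0.04, 0.04, 0.3)), 0.25)
        assert table.loc[0, "z_um"] == pytest.approx(0.3)
        assert table.loc[0, "y_um"] == pytest.approx(0.12)
        assert table.loc[0, "x_um"] == pytest.approx(0.2)


class TestConglomerates:
    def test_published_tally_worked_example(self):
        """501 dots at the modal intensity and 2 at twice it: the two bright
        dots are flagged, 0.4% of the total."""
        spots = pd.DataFrame({"mean_intensity": [0.275] * 501 + [0.55] * 2})
        flagged, summary = classify_conglomerates(spots)
        assert summary["n_conglomerates"] == 2
        assert summary["pct_conglomerates"] == 0.4
        assert summary["modal_intensity"] == pytest.approx(0.275)
        assert flagged["conglomerate"].sum() == 2

    def test_all_modal_none_flagged(self):
        spots = pd.DataFrame({"mean_intensity": [0.3] * 50})
        _, summary = classify_conglomerates(spots)
        assert summary["n_conglomerates"] == 0
        assert summary["pct_conglomerates"] == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify_conglomerates(pd.DataFrame({"mean_intensity": []}))


def spot_table(coords_um):
    arr = np.asarray(coords_um, dtype=float)
    return pd.DataFrame({"z_um": arr[:, 0], "y_um": arr[:, 1], "x_um": arr[:, 2]})


class TestColocalize:
    def test_identical_tables_full_efficiency(self):
        t = spot_table([[0, 0, 0], [1, 1, 1], [2, 0, 1]])
        res = colocalize(t, t.copy(), radius_um=0.5)
        assert res.efficiency_ab == 1.0
        assert res.efficiency_ba == 1.0

    def test_all_beyond_radius_zero_efficiency(self):
        a = spot_table([[0, 0, 0], [0, 5, 5]])
        b = spot_table([[10, 10, 10], [12, 0, 0]])
        res = colocalize(a, b, radius_um=0.5)
        assert res.efficiency_ab == 0.0
        assert res.pairs == []

    def test_one_to_one_matching(self):
        # two A dots near one B dot: only one may match
        a = spot_table([[0, 0, 0], [0, 0, 0.2]])
        b = spot_table([[0, 0, 0.1]])
        res = colocalize(a, b, radius_um=0.5)
        assert len(res.pairs) == 1
        assert res.efficiency_ab == 0.5
        assert res.efficiency_ba == 1.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="no reference dots"):
            colocalize(spot_table(np.empty((0, 3))), spot_table([[0, 0, 0]]), 0.5)


def test_plateau_count_invariant_to_amplitude_rescale(iso_voxel_size):
    """Normalization plus plateau selection is jointly scale-free."""
    centers = [(4, 12, 12), (4, 12, 36), (4, 36, 24)]
    roi = CellROI("c", {z: np.array([[0, 0], [0, 47], [47, 47], [47, 0]], float)
                        for z in range(9)})
    counts = []
    for a in (1.0, 37.5):
        stack = spot_stack(iso_voxel_size, shape=(9, 48, 48), centers=centers,
                           amplitudes=[a, 1.2 * a, 0.8 * a], sigma_um=(0.2, 0.2))
        f = normalize_filtered(log_filter(stack, FilterParams(0.2, 0.2)))
        results, _ = count_per_cell(f, [roi])
        counts.append(results[0].transcript_count)
    assert counts[0] == counts[1] == 3
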