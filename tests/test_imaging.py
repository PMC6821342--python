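"""3D object counting, stack padding, nucleus calls, ROI fluorescence."""

import numpy as np
import pytest

from conftest import flood_fill_objects
from rnai_mosaic.imaging import (
    ROI,
    DepthThresholdProfile,
    SizeGate,
    VoxelGrid,
    count_foci_between_nuclei,
    count_objects_3d,
    pad_stack,
    roi_fluorescence,
    score_nuclei,
)
from rnai_mosaic.synthetic import FocusSpec, NucleusSpec, StackSpec, gen_image_stack

VOX = (0.125, 0.1, 0.1)


def grid_of(arr):
    return VoxelGrid(np.asarray(arr, dtype=float), VOX)


class TestPadStack:
    def test_full_stack_unchanged(self):
        arr = np.full((319, 4, 4), 10.0)
        out = pad_stack(grid_of(arr), total_slices=319, noise_floor=1.0)
        assert np.array_equal(out.intensities, arr)

    def test_empty_leading_slices_trimmed_and_padded(self):
        arr = np.zeros((312, 4, 4))
        arr[:7] = 0.5            # sub-floor noise near the coverslip
        arr[7:] = 30.0           # sample content
        out = pad_stack(grid_of(arr), total_slices=319, noise_floor=1.0)
        assert out.n_slices == 319
        assert np.all(out.intensities[:305] == 30.0)
        assert np.all(out.intensities[305:] == 0.0)
        assert out.intensities.sum() == pytest.approx(arr[7:].sum())

    def test_all_empty_grid_behaviour_is_configurable(self):
        empty = grid_of(np.zeros((10, 4, 4)))
        with pytest.raises(ValueError):
            pad_stack(empty, total_slices=319, noise_floor=1.0)
        out = pad_stack(empty, total_slices=319, noise_floor=1.0, allow_empty=True)
        assert out.n_slices == 319 and out.intensities.sum() == 0.0

    def test_overlong_content_rejected(self):
        arr = np.full((30, 4, 4), 10.0)
        with pytest.raises(ValueError):
            pad_stack(grid_of(arr), total_slices=20, noise_floor=1.0)


class TestCountObjects3D:
    def test_all_zero_grid_has_no_objects(self):
        assert count_objects_3d(grid_of(np.zeros((5, 5, 5))), threshold=1.0) == []

    def test_corner_touching_blobs_are_one_object_at_26_connectivity(self):
        arr = np.zeros((3, 5, 5))
        arr[0, 0, 0] = 100.0
        arr[1, 1, 1] = 100.0  # diagonal neighbour in all three axes
        objs26 = count_objects_3d(grid_of(arr), threshold=50)
        objs6 = count_objects_3d(grid_of(arr), threshold=50, connectivity=6)
        assert len(objs26) == 1
        assert len(objs6) == 2

    def test_matches_flood_fill_oracle_on_random_grids(self):
        rng = np.random.default_rng(0)
        for _ in range(150):
            arr = rng.integers(0, 100, size=(10, 10, 10)).astype(float)
            threshold = float(rng.integers(30, 90))
            objs = count_objects_3d(
                VoxelGrid(arr, VOX), threshold, keep_voxels=True
            )
            oracle = flood_fill_objects(arr, threshold)
            assert {o.voxels for o in objs} == set(oracle)

    def test_volume_is_voxel_count_times_voxel_volume(self):
        arr = np.zeros((4, 4, 4))
        arr[1, 1, 1] = arr[1, 1, 2] = arr[1, 2, 1] = 80.0
        (obj,) = count_objects_3d(grid_of(arr), threshold=50)
        assert obj.volume == pytest.approx(3 * 0.125 * 0.1 * 0.1)
        assert obj.n_voxels == 3

    def test_gate_only_removes_and_accounting_is_exact(self):
        rng = np.random.default_rng(1)
        arr = rng.integers(0, 120, size=(12, 12, 12)).astype(float)
        grid = VoxelGrid(arr, VOX)
        gate = SizeGate(min_volume=0.003, max_volume=0.01, threshold=100)
        all_objs = count_objects_3d(grid, 100)
        gated = count_objects_3d(grid, 100, gate=gate)
        gated_labels = {o.label for o in gated}
        assert gated_labels <= {o.label for o in all_objs}
        discarded = [o for o in all_objs if o.label not in gated_labels]
        assert len(gated) + len(discarded) == len(all_objs)
        assert all(gate.passes(o.volume) for o in gated)
        assert not any(gate.passes(o.volume) for o in discarded)

    def test_raising_threshold_never_adds_voxels(self):
        rng = np.random.default_rng(2)
        arr = rng.integers(0, 100, size=(8, 8, 8)).astype(float)
        grid = VoxelGrid(arr, VOX)
        totals = [
            sum(o.n_voxels for o in count_objects_3d(grid, t)) for t in (20, 40, 60, 80)
        ]
        assert all(a >= b for a, b in zip(totals, totals[1:]))


class TestSyntheticStackRecovery:
    def test_planted_in_window_foci_counted_exactly(self):
        in_window = [0.02, 0.05, 0.08, 0.12, 0.18]
        oversize = [0.3, 0.5, 0.25]
        spec = StackSpec(
            shape=(40, 100, 100),
            foci=tuple(
                FocusSpec(center=(2.5, 1.0 + 1.5 * i, 5.0), volume=v)
                for i, v in enumerate(in_window)
            )
            + tuple(
                FocusSpec(center=(2.5, 1.0 + 2.0 * i, 8.0), volume=v)
                for i, v in enumerate(oversize)
            ),
            noise_sd=1.0,
            seed=3,
        )
        grid, truth = gen_image_stack(spec)
        assert truth.n_in_window == 5
        objs = count_objects_3d(grid, 50.0, gate=SizeGate())
        assert len(objs) == 5

    def test_rendered_focus_volume_within_20_percent(self):
        nominal = 0.05
        spec = StackSpec(
            shape=(40, 40, 40),
            foci=(FocusSpec(center=(2.5, 2.0, 2.0), volume=nominal),),
            noise_sd=0.0,
        )
        grid, _ = gen_image_stack(spec)
        # voxel-count oracle: above-threshold voxels x voxel volume
        measured = (grid.intensities >= 50.0).sum() * grid.voxel_volume
        assert measured == pytest.approx(nominal, rel=0.2)


class TestCountFociBetweenNuclei:
    def build(self):
        in_region = [(2.5, 3.0, 3.0), (2.5, 4.5, 4.5), (2.5, 6.0, 3.0)]
        out_region = [(2.5, 12.0, 12.0)]
        spec = StackSpec(
            shape=(40, 160, 160),
            foci=tuple(FocusSpec(center=c, volume=0.05) for c in in_region + out_region),
            noise_sd=0.0,
        )
        grid, _ = gen_image_stack(spec)
        return grid

    def test_counts_only_in_region_foci(self):
        grid = self.build()
        n = count_foci_between_nuclei(
            grid, (2.5, 2.0, 2.0), (2.5, 7.0, 6.0), None, SizeGate()
        )
        assert n == 3

    def test_empty_region_counts_zero(self):
        grid = self.build()
        n = count_foci_between_nuclei(
            grid, (1.0, 14.0, 2.0), (1.5, 15.0, 3.0), None, SizeGate()
        )
        assert n == 0

    def test_focus_inside_nuclear_mask_excluded(self):
        grid = self.build()
        # mask out every voxel of the focus at (2.5, 3.0, 3.0)
        zz, yy, xx = np.nonzero(grid.intensities >= 50.0)
        mask = {
            (z, y, x)
            for z, y, x in zip(zz, yy, xx)
            if abs(y * 0.1 - 3.0) < 1.0 and abs(x * 0.1 - 3.0) < 1.0
        }
        n = count_foci_between_nuclei(
            grid, (2.5, 2.0, 2.0), (2.5, 7.0, 6.0), [mask], SizeGate()
        )
        assert n == 2

    def test_coincident_centroids_rejected(self):
        grid = self.build()
        with pytest.raises(ValueError):
            count_foci_between_nuclei(
                grid, (1.0, 1.0, 1.0), (1.0, 1.0, 1.0), None, SizeGate()
            )


class TestScoreNuclei:
    def stack_with_nucleus(self, peak, z_um):
        spec = StackSpec(
            shape=(319, 60, 60),
            nuclei=(
                NucleusSpec(center=(z_um, 3.0, 3.0), radius=1.0, peak=peak),
            ),
            noise_sd=0.0,
        )
        grid, truth = gen_image_stack(spec)
        return grid, truth.nuclei[0]["slice_index"]

    @pytest.mark.parametrize(
        "peak,z_um,expected",
        [
            (75.0, 10.0, "on"),    # slice ~81 -> threshold 70, peak above
            (75.0, 30.0, "on"),    # slice ~241 -> threshold 20
            (40.0, 10.0, "off"),   # below 70 near the coverslip
            (40.0, 30.0, "on"),    # same blob deep in the stack clears 20
        ],
    )
    def test_depth_dependent_threshold_changes_the_call(self, peak, z_um, expected):
        grid, slice_idx = self.stack_with_nucleus(peak, z_um)
        (call,) = score_nuclei(grid, [("n0", (z_um, 3.0, 3.0), slice_idx)])
        assert call.state == expected
        if expected == "on":
            assert call.supporting_object is not None

    def test_each_object_supports_at_most_one_nucleus(self):
        grid, slice_idx = self.stack_with_nucleus(120.0, 10.0)
        calls = score_nuclei(
            grid,
            [
                ("a", (10.0, 3.0, 3.0), slice_idx),
                ("b", (10.0, 3.5, 3.5), slice_idx),  # same blob, slightly offset
            ],
        )
        states = {c.label: c for c in calls}
        # label order breaks the tie: "a" claims the object, "b" goes unsupported
        assert states["a"].state == "on"
        assert states["b"].state == "off"

    def test_uncovered_slice_is_an_error(self):
        grid, _ = self.stack_with_nucleus(120.0, 10.0)
        profile = DepthThresholdProfile(((1, 100, 70.0),))
        with pytest.raises(ValueError, match="n0"):
            score_nuclei(grid, [("n0", (30.0, 3.0, 3.0), 241)], profile)

    def test_synthetic_truth_recovered_for_well_separated_nuclei(self):
        spec = StackSpec(
            shape=(319, 100, 100),
            nuclei=(
                NucleusSpec((5.0, 2.5, 2.5), 1.0, 150.0, "on"),
                NucleusSpec((5.0, 7.5, 7.5), 1.0, 40.0, "off"),
                NucleusSpec((30.0, 2.5, 7.5), 1.0, 40.0, "on"),
                NucleusSpec((30.0, 7.5, 2.5), 1.0, 10.0, "off"),
            ),
            noise_sd=1.0,
            seed=8,
        )
        grid, truth = gen_image_stack(spec)
        expected = [
            (f"n{i}", n["center"], n["slice_index"]) for i, n in enumerate(truth.nuclei)
        ]
        calls = score_nuclei(grid, expected)
        want = {f"n{i}": n["expected_state"] for i, n in enumerate(truth.nuclei)}
        assert {c.label: c.state for c in calls} == want


class TestRoiFluorescence:
    def test_uniform_image_zero(self):
        img = np.full((10, 10), 7.0)
        mask = np.zeros((10, 10), bool)
        mask[2:5, 2:5] = True
        bg = np.zeros((10, 10), bool)
        bg[7:, 7:] = True
        assert roi_fluorescence(img, ROI(mask, background_mask=bg)) == pytest.approx(0.0)

    def test_printed_formula(self):
        # ROI sum 1000 over 100 px, background mean 2 -> 1000 - 100*2 = 800
        img = np.zeros((20, 20))
        img[:10, :10] = 10.0
        mask = np.zeros((20, 20), bool)
        mask[:10, :10] = True
        value = roi_fluorescence(img, ROI(mask, background_mean=2.0))
        assert value == pytest.approx(1000.0 - 100 * 2.0)

    def test_linearity(self):
        rng = np.random.default_rng(4)
        img = rng.uniform(0, 50, (15, 15))
        mask = np.zeros((15, 15), bool)
        mask[3:8, 3:8] = True
        bg = ~mask
        one = roi_fluorescence(img, ROI(mask, background_mask=bg))
        two = roi_fluorescence(2 * img, ROI(mask, background_mask=bg))
        assert two == pytest.approx(2 * one)

    def test_missing_background_rejected(self):
        img = np.ones((5, 5))
        mask = np.ones((5, 5), bool)
        with pytest.raises(ValueError):
            roi_fluorescence(img, ROI(mask))

    def test_overlapping_background_rejected(self):
        mask = np.ones((5, 5), bool)
        with pytest.raises(ValueError):
            ROI(mask, background_mask=mask)
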