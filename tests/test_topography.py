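"""Preference extraction, gradient quantification, azimuth distributions."""

import numpy as np
import pandas as pd
import pytest

from audenc import synthetic
from audenc.encoding import TuningMatrix, ridge_solve, select_voxels
from audenc.features import octave_bin_centers
from audenc.model_spaces import AZIMUTHS_DEG, build_joint
from audenc.topography import (
    azimuth_distribution,
    gradient_directions,
    laterality_maps,
    preference_table,
    smooth_grid,
    tonotopy_map,
    voxel_preference,
)

FREQ_CENTERS = octave_bin_centers(6)


def _joint_column(f_idx: int, a_idx: int, value: float = 1.0) -> np.ndarray:
    col = np.zeros(42)
    col[a_idx * 6 + f_idx] = value
    return col


class TestVoxelPreference:
    def test_single_positive_entry_is_the_preference(self):
        cf, az, tie = voxel_preference(_joint_column(2, 4))
        assert cf == pytest.approx(FREQ_CENTERS[2])
        assert az == 30.0
        assert not tie

    def test_positive_rescaling_preserves_the_preference(self, rng):
        col = rng.random(42)
        assert voxel_preference(col)[:2] == voxel_preference(7.3 * col)[:2]

    def test_adding_a_constant_preserves_the_preference(self, rng):
        col = rng.random(42)
        assert voxel_preference(col)[:2] == voxel_preference(col + 5.0)[:2]

    def test_constant_weights_tie_resolves_low_freq_central(self):
        cf, az, tie = voxel_preference(np.ones(42))
        assert tie
        assert cf == pytest.approx(FREQ_CENTERS[0])
        assert az == 0.0

    def test_gaussian_tuned_voxel_maps_to_nearest_grid_point(self):
        voxel = synthetic.GroundTruthVoxel(1000.0, -60.0, 0.6, 25.0)
        cf, az, _ = voxel_preference(voxel.tuning_vector())
        nearest = FREQ_CENTERS[np.argmin(np.abs(np.log2(FREQ_CENTERS / 1000.0)))]
        assert cf == pytest.approx(nearest)
        assert az == -60.0

    def test_smoothing_preserves_constants(self):
        assert np.allclose(smooth_grid(np.full((6, 7), 3.3)), 3.3)


class TestTonotopyMap:
    def _fit_selected(self, noise_sd, n_voxels=40, seed=70):
        events = synthetic.generate_sound_set(56, 28, 7, seed=seed)
        voxels = synthetic.random_voxels(
            n_voxels, seed=seed + 1, noise_sd=noise_sd, on_grid=True
        )
        ds = synthetic.generate_responses(events, voxels, seed=seed + 2)
        tuning = ridge_solve(ds.W_true, ds.Y)
        return ds, voxels, tuning

    def test_uniform_ground_truth_gives_constant_map(self):
        events = synthetic.generate_sound_set(28, 7, 7, seed=71)
        voxels = [
            synthetic.GroundTruthVoxel(1000.0, 30.0, 0.7, 30.0) for _ in range(9)
        ]
        ds = synthetic.generate_responses(events, voxels, seed=72)
        tuning = ridge_solve(ds.W_true, ds.Y, lambda_grid=np.array([1e-8]))
        table = preference_table(tuning)
        assert table["cf_hz"].nunique() == 1
        assert table["azimuth_deg"].nunique() == 1

    def test_unselected_voxels_are_absent_from_the_map(self):
        ds, voxels, tuning = self._fit_selected(noise_sd=0.05)
        selection = select_voxels(ds.Y, t_threshold=2.9, cap=20)
        coords = np.column_stack(
            [np.arange(len(voxels)), np.zeros(len(voxels)), np.zeros(len(voxels))]
        ).astype(int)
        pmap = tonotopy_map(tuning, selection, coords, shape=(len(voxels), 1, 1))
        assert set(pmap.table["voxel"]) == set(selection.voxel_ids)
        vol = pmap.volume("cf_hz")
        unselected = np.setdiff1d(np.arange(len(voxels)), selection.voxel_ids)
        assert np.all(np.isnan(vol[unselected, 0, 0]))

    def test_planted_two_cluster_layout_is_recovered(self):
        events = synthetic.generate_sound_set(56, 28, 7, seed=73)
        # response noise at the clean-recovery validation level (SNR ~ 35)
        low = [
            synthetic.GroundTruthVoxel(
                FREQ_CENTERS[1], 0.0, 0.6, 30.0, noise_sd=0.02
            )
            for _ in range(20)
        ]
        high = [
            synthetic.GroundTruthVoxel(
                FREQ_CENTERS[4], 0.0, 0.6, 30.0, noise_sd=0.02
            )
            for _ in range(20)
        ]
        ds = synthetic.generate_responses(events, low + high, seed=74)
        tuning = ridge_solve(ds.W_true, ds.Y)
        table = preference_table(tuning)
        truth = np.array([FREQ_CENTERS[1]] * 20 + [FREQ_CENTERS[4]] * 20)
        match = np.isclose(table["cf_hz"], truth).mean()
        assert match >= 0.95


class TestGradients:
    def _ramp_slice(self, n=12, axis=0):
        idx = np.arange(n, dtype=float)
        ramp = 200.0 * 2.0 ** (0.3 * idx)  # log2-linear tonotopic ramp
        return np.tile(ramp[:, None] if axis == 0 else ramp[None, :], (1, n) if axis == 0 else (n, 1))

    def test_ramp_along_first_axis_gives_zero_degrees(self):
        dist = gradient_directions(self._ramp_slice(axis=0))
        assert np.allclose(dist.angles, 0.0)
        assert dist.peaks.size == 1
        assert dist.peaks[0] == pytest.approx(10.0)  # center of [0, 20) bin

    def test_negated_ramp_gives_180_degrees(self):
        dist = gradient_directions(self._ramp_slice(axis=0)[::-1])
        assert np.allclose(dist.angles, 180.0)

    def test_rotating_the_ramp_rotates_all_angles_90_degrees(self):
        d0 = gradient_directions(self._ramp_slice(axis=0))
        d1 = gradient_directions(self._ramp_slice(axis=1))
        shifted = (d0.angles + 90.0) % 360.0
        assert np.allclose(np.sort(d1.angles), np.sort(shifted))

    def test_mirror_low_high_low_pattern_is_bimodal(self):
        # mirror-symmetric low-high-low frequency pattern: two opposed
        # gradients, like the two tonotopic maps of the auditory thalamus
        n = 12
        idx = np.arange(n, dtype=float)
        up = 200.0 * 2.0 ** (0.4 * idx)
        ramp = np.concatenate([up, up[::-1]])
        map_slice = np.tile(ramp[:, None], (1, 8))
        dist = gradient_directions(map_slice)
        assert dist.peaks.size == 2
        gap = abs(dist.peaks[0] - dist.peaks[1])
        assert min(gap, 360 - gap) == pytest.approx(180.0, abs=20.0)

    def test_histogram_counts_every_voxel_with_a_gradient(self):
        dist = gradient_directions(self._ramp_slice())
        assert dist.histogram.sum() == dist.angles.size

    def test_unmapped_slice_rejected(self):
        with pytest.raises(ValueError, match="gradient|mapped"):
            gradient_directions(np.full((4, 4), np.nan))


class TestAzimuthDistribution:
    def _table(self, azimuths, cfs=None):
        n = len(azimuths)
        return pd.DataFrame(
            {
                "voxel": np.arange(n),
                "cf_hz": cfs if cfs is not None else np.full(n, 1000.0),
                "azimuth_deg": azimuths,
                "tie_flag": False,
            }
        )

    def test_uniform_tuning_gives_one_seventh_shares(self, rng):
        azimuths = rng.choice(AZIMUTHS_DEG, size=700)
        props, _ = azimuth_distribution(self._table(azimuths))
        shares = props[props["stratum"] == "all"]["proportion"].to_numpy()
        # binomial 99% envelope around 1/7 at n = 700
        bound = 2.6 * np.sqrt((1 / 7) * (6 / 7) / 700)
        assert np.all(np.abs(shares - 1 / 7) < bound)

    def test_everything_at_minus90(self):
        props, _ = azimuth_distribution(self._table(np.full(50, -90.0)))
        allp = props[props["stratum"] == "all"].set_index("azimuth_deg")
        assert allp.loc[-90.0, "proportion"] == 1.0
        assert allp["proportion"].drop(-90.0).sum() == 0.0

    def test_cf_split_strata_and_empty_stratum_omitted(self):
        cfs = np.full(50, 400.0)  # all low CF: high stratum empty
        props, _ = azimuth_distribution(self._table(np.full(50, 30.0), cfs))
        strata = set(props["stratum"])
        assert "low_cf" in strata and "high_cf" not in strata

    def test_planted_periphery_excess_is_detected(self, rng):
        tables = []
        for r in range(6):
            azimuths = rng.choice(
                AZIMUTHS_DEG, size=400, p=np.array([2, 1, 1, 1, 1, 1, 2]) / 9
            )
            tables.append(self._table(azimuths))
        _, tests = azimuth_distribution(tables)
        allt = tests[tests["stratum"] == "all"]
        assert allt["significant"].all()


class TestLaterality:
    def test_left_structure_plus30_is_contralateral(self):
        table = pd.DataFrame({"azimuth_deg": [30.0], "cf_hz": [1000.0]})
        out = laterality_maps(table, ["left"])
        assert out["signed_azimuth_deg"].iloc[0] == -30.0
        assert out["laterality"].iloc[0] == "contra"

    def test_right_structure_plus30_is_ipsilateral(self):
        table = pd.DataFrame({"azimuth_deg": [30.0], "cf_hz": [1000.0]})
        out = laterality_maps(table, ["right"])
        assert out["laterality"].iloc[0] == "ipsi"

    def test_zero_azimuth_is_central(self):
        table = pd.DataFrame({"azimuth_deg": [0.0, 0.0], "cf_hz": [500.0, 2000.0]})
        out = laterality_maps(table, ["left", "right"])
        assert (out["laterality"] == "central").all()

    def test_missing_side_label_rejected(self):
        table = pd.DataFrame({"azimuth_deg": [30.0], "cf_hz": [1000.0]})
        with pytest.raises(ValueError, match="side label"):
            laterality_maps(table, ["up"])
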