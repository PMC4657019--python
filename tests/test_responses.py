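"""Noise regressors, HRF deconvolution, and beta estimation."""

import numpy as np
import pandas as pd
import pytest

from audenc import synthetic
from audenc.hrf import double_gamma_hrf
from audenc.responses import (
    VoxelTimeSeries,
    estimate_betas,
    estimate_hrf,
    estimate_noise_regressors,
    estimate_responses,
)

TR = 2.8


@pytest.fixture(scope="module")
def clean_dataset():
    events = synthetic.generate_sound_set(28, 7, 7, seed=21)
    voxels = synthetic.random_voxels(4, seed=22, noise_sd=0.0)
    return synthetic.generate_responses(events, voxels, seed=23)


@pytest.fixture(scope="module")
def clean_series(clean_dataset):
    values, table = synthetic.generate_timeseries(clean_dataset, seed=24)
    return VoxelTimeSeries(values, TR, table)


def _reorder(rm, dataset):
    order = [rm.sound_ids.index(e.sound_id) for e in dataset.events]
    return rm.betas[order]


class TestNoiseRegressors:
    def test_task_driven_noise_free_data_has_no_noise_pool(self, clean_series):
        components = estimate_noise_regressors(clean_series)
        assert components.shape[1] == 0

    def test_planted_global_artifact_is_recovered(self, clean_dataset, rng):
        values, table = synthetic.generate_timeseries(clean_dataset, seed=25)
        artifact = np.cumsum(rng.standard_normal(values.shape[0]))
        artifact -= artifact.mean()
        # artifact-only voxels form the noise pool
        artifact_voxels = np.outer(artifact, rng.uniform(0.5, 1.5, 6))
        artifact_voxels += rng.standard_normal(artifact_voxels.shape) * 0.05
        series = VoxelTimeSeries(
            np.column_stack([values, artifact_voxels]), TR, table
        )
        components = estimate_noise_regressors(series, n_components=2)
        # only the task-orthogonal part of the artifact is identifiable:
        # project it out with the same per-sound design the stage uses
        from audenc.responses import _convolve_columns, _onset_matrix

        onsets, _ = _onset_matrix(table, values.shape[0])
        X = np.column_stack(
            [_convolve_columns(onsets, double_gamma_hrf(TR)),
             np.ones(values.shape[0])]
        )
        coef, *_ = np.linalg.lstsq(X, artifact, rcond=None)
        artifact_orth = artifact - X @ coef
        r = np.corrcoef(components[:, 0], artifact_orth)[0, 1]
        assert abs(r) > 0.9

    def test_zero_components_leave_downstream_fits_unchanged(self, clean_series):
        components = estimate_noise_regressors(clean_series, n_components=0)
        assert components.shape == (clean_series.values.shape[0], 0)
        with_none = estimate_betas(clean_series)
        with_zero = estimate_betas(clean_series, noise_regressors=components)
        assert np.allclose(with_none.betas, with_zero.betas)

    def test_excessive_rank_request_rejected(self, clean_dataset, rng):
        values, table = synthetic.generate_timeseries(clean_dataset, seed=26)
        noise_voxels = rng.standard_normal((values.shape[0], 3))
        series = VoxelTimeSeries(np.column_stack([values, noise_voxels]), TR, table)
        with pytest.raises(ValueError, match="rank"):
            estimate_noise_regressors(series, n_components=50)


class TestHrfEstimation:
    def test_known_kernel_recovered_from_unit_amplitude_series(self, clean_dataset):
        flat = synthetic.SyntheticDataset(
            clean_dataset.events,
            clean_dataset.W_true,
            clean_dataset.R_true,
            np.ones_like(clean_dataset.Y),
            seed=0,
        )
        values, table = synthetic.generate_timeseries(flat, seed=27)
        kernels = estimate_hrf(VoxelTimeSeries(values, TR, table))
        truth = double_gamma_hrf(TR)
        truth = truth / np.max(np.abs(truth))
        assert np.allclose(kernels, truth[:, None], atol=1e-9)

    def test_all_zero_series_gives_all_zero_kernel(self, clean_series):
        zero = VoxelTimeSeries(
            np.zeros_like(clean_series.values), TR, clean_series.event_table
        )
        assert np.all(estimate_hrf(zero) == 0)

    def test_recovery_error_shrinks_with_more_events(self):
        errors = {}
        truth = double_gamma_hrf(TR)
        truth = truth / np.max(np.abs(truth))
        for n_train, n_test in ((14, 7), (70, 14)):
            events = synthetic.generate_sound_set(n_train, n_test, 7, seed=31)
            voxels = synthetic.random_voxels(6, seed=32, noise_sd=0.0)
            ds = synthetic.generate_responses(events, voxels, seed=33)
            flat = synthetic.SyntheticDataset(
                ds.events, ds.W_true, ds.R_true, np.ones_like(ds.Y), seed=0
            )
            values, table = synthetic.generate_timeseries(
                flat, noise_sd=0.3, seed=34
            )
            kernels = estimate_hrf(VoxelTimeSeries(values, TR, table))
            errors[n_train] = np.sqrt(np.mean((kernels - truth[:, None]) ** 2))
        assert errors[70] < errors[14]

    def test_too_few_events_rejected(self, clean_series):
        table = clean_series.event_table.iloc[:3]
        series = VoxelTimeSeries(clean_series.values, TR, table)
        with pytest.raises(ValueError, match="deconvolution window"):
            estimate_hrf(series)


class TestBetaEstimation:
    def test_noise_free_betas_recovered_exactly_with_true_kernel(
        self, clean_dataset, clean_series
    ):
        rm = estimate_betas(clean_series, hrf=double_gamma_hrf(TR))
        assert np.allclose(_reorder(rm, clean_dataset), clean_dataset.Y, atol=1e-10)

    def test_doubling_the_series_doubles_betas(self, clean_series):
        rm1 = estimate_betas(clean_series)
        rm2 = estimate_betas(
            VoxelTimeSeries(2 * clean_series.values, TR, clean_series.event_table)
        )
        assert np.allclose(rm2.betas, 2 * rm1.betas)

    def test_beta_error_grows_with_noise(self, clean_dataset):
        rmse = {}
        for snr_label, noise_sd in (("high", 0.1), ("low", 0.4)):
            values, table = synthetic.generate_timeseries(
                clean_dataset, noise_sd=noise_sd, seed=41
            )
            rm = estimate_betas(
                VoxelTimeSeries(values, TR, table), hrf=double_gamma_hrf(TR)
            )
            rmse[snr_label] = np.sqrt(
                np.mean((_reorder(rm, clean_dataset) - clean_dataset.Y) ** 2)
            )
        assert rmse["high"] < rmse["low"]

    def test_target_and_zero_trials_are_excluded(self, clean_dataset):
        values, table = synthetic.generate_timeseries(clean_dataset, seed=42)
        table = table.copy()
        table["trial_type"] = "sound"
        extra = pd.DataFrame(
            [{"sound_id": "tgt", "split": "train", "azimuth_deg": 0.0,
              "onset_tr": 1, "trial_type": "target"}]
        )
        rm = estimate_betas(
            VoxelTimeSeries(values, TR, pd.concat([table, extra])),
            hrf=double_gamma_hrf(TR),
        )
        assert "tgt" not in rm.sound_ids

    def test_full_path_is_linear_in_the_series(self, clean_series):
        hrfs = estimate_hrf(clean_series)
        a = estimate_betas(clean_series, hrf=hrfs)
        b = estimate_betas(
            VoxelTimeSeries(3 * clean_series.values, TR, clean_series.event_table),
            hrf=hrfs,
        )
        assert np.allclose(b.betas, 3 * a.betas)


class TestRoundTrip:
    def test_full_pipeline_recovers_betas_exactly_at_zero_noise(
        self, clean_dataset, clean_series
    ):
        rm = estimate_responses(clean_series)
        assert np.allclose(_reorder(rm, clean_dataset), clean_dataset.Y, atol=1e-8)

    def test_per_voxel_kernel_variation_round_trips(self, clean_dataset):
        # generate with voxelwise-scaled latencies: taller/narrower kernels
        base = double_gamma_hrf(TR)
        n_vox = clean_dataset.Y.shape[1]
        kernels = np.column_stack(
            [np.roll(base, shift) * s for shift, s in
             zip([0, 1, 0, 1], [1.0, 0.8, 1.2, 0.9])][:n_vox]
        )
        flat = synthetic.SyntheticDataset(
            clean_dataset.events, clean_dataset.W_true, clean_dataset.R_true,
            np.ones_like(clean_dataset.Y), seed=0,
        )
        values, table = synthetic.generate_timeseries(flat, hrf=kernels, seed=43)
        est = estimate_hrf(VoxelTimeSeries(values, TR, table))
        expected = kernels / np.max(np.abs(kernels), axis=0)
        assert np.allclose(est, expected, atol=1e-8)

    def test_beta_errors_are_unbiased_under_noise(self, clean_dataset):
        mean_errors = []
        for seed in range(8):
            values, table = synthetic.generate_timeseries(
                clean_dataset, noise_sd=0.2, seed=50 + seed
            )
            rm = estimate_betas(
                VoxelTimeSeries(values, TR, table), hrf=double_gamma_hrf(TR)
            )
            mean_errors.append(
                np.mean(_reorder(rm, clean_dataset) - clean_dataset.Y)
            )
        mean_errors = np.array(mean_errors)
        ci = 3 * mean_errors.std(ddof=1) / np.sqrt(mean_errors.size)
        assert abs(mean_errors.mean()) < max(ci, 1e-3)
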