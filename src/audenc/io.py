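"""File formats: WAV audio, event TSVs, labelled matrix containers, YAML config.

Matrices travel as compressed ``.npz`` containers holding the values plus
their feature labels, with a TSV export for interoperability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .encoding import TuningMatrix
from .model_spaces import FeatureMatrix


def read_wav(path):
    """Load a WAV file as (fs, float array in [-1, 1]); stereo stays (n, 2)."""
    fs, data = wavfile.read(path)
    if data.dtype.kind == "i":
        data = data.astype(float) / np.iinfo(data.dtype).max
    elif data.dtype.kind == "u":
        info = np.iinfo(data.dtype)
        data = (data.astype(float) - info.max / 2) / (info.max / 2)
    else:
        data = data.astype(float)
    return fs, data


def write_wav(path, fs: float, data: np.ndarray) -> None:
    """Write float audio as 16-bit PCM WAV."""
    data = np.asarray(data, dtype=float)
    peak = np.max(np.abs(data))
    if peak > 1.0:
        data = data / peak
    wavfile.write(path, int(fs), (data * 32767).astype(np.int16))


def write_events_tsv(path, events) -> None:
    """Event TSV with columns sound_id, split, azimuth_deg, onset_tr."""
    pd.DataFrame(
        [
            {
                "sound_id": e.sound_id,
                "split": e.split,
                "azimuth_deg": e.azimuth_deg,
                "onset_tr": -1 if e.onset_tr is None else e.onset_tr,
            }
            for e in events
        ]
    ).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_feature_matrix(path, fm: FeatureMatrix) -> None:
    np.savez_compressed(
        path,
        values=fm.values,
        model_kind=np.array(fm.model_kind),
        label_frequency=fm.label_frequency,
        label_azimuth=fm.label_azimuth,
    )


def load_feature_matrix(path) -> FeatureMatrix:
    with np.load(path, allow_pickle=False) as z:
        return FeatureMatrix(
            z["values"],
            str(z["model_kind"]),
            z["label_frequency"],
            z["label_azimuth"],
        )


def save_tuning_matrix(path, tm: TuningMatrix) -> None:
    np.savez_compressed(
        path,
        weights=tm.weights,
        lambdas=tm.lambdas,
        model_kind=np.array(tm.model_kind),
        label_frequency=np.asarray(tm.label_frequency, dtype=float),
        label_azimuth=np.asarray(tm.label_azimuth, dtype=float),
        w_means=tm.w_means if tm.w_means is not None else np.zeros(0),
        y_means=tm.y_means if tm.y_means is not None else np.zeros(0),
    )


def load_tuning_matrix(path) -> TuningMatrix:
    with np.load(path, allow_pickle=False) as z:
        w_means = z["w_means"] if z["w_means"].size else None
        y_means = z["y_means"] if z["y_means"].size else None
        return TuningMatrix(
            z["weights"],
            z["lambdas"],
            str(z["model_kind"]),
            z["label_frequency"],
            z["label_azimuth"],
            w_means=w_means,
            y_means=y_means,
        )


def save_matrix(path, values: np.ndarray) -> None:
    np.savez_compressed(path, values=np.asarray(values, dtype=float))


def load_matrix(path) -> np.ndarray:
    with np.load(path, allow_pickle=False) as z:
        return z["values"]


def feature_matrix_to_tsv(path, fm: FeatureMatrix) -> None:
    """TSV export with a header row of feature labels (freq@azimuth)."""
    labels = []
    for f, a in zip(fm.label_frequency, fm.label_azimuth):
        parts = []
        if np.isfinite(f):
            parts.append(f"f{f:.1f}")
        if np.isfinite(a):
            parts.append(f"az{a:+.0f}")
        labels.append("@".join(parts) if parts else "col")
    pd.DataFrame(fm.values, columns=labels).to_csv(path, sep="\t", index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_nifti_series(series_path, mask_path=None):
    """Load a 4D NIfTI series as (TRs x voxels) plus voxel grid coordinates.

    ``mask_path`` optionally restricts to nonzero mask voxels.  Returns
    ``(values, coordinates, affine)`` with coordinates as (V, 3) indices.
    """
    import nibabel as nib

    img = nib.load(str(series_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError("expected a 4D NIfTI series")
    if mask_path is not None:
        mask = np.asanyarray(nib.load(str(mask_path)).dataobj) != 0
        if mask.shape != data.shape[:3]:
            raise ValueError("mask geometry does not match the series")
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    coords = np.argwhere(mask)
    values = data[mask].T.astype(float)  # TRs x voxels
    return values, coords, img.affine


def save_beta_maps(path, betas: np.ndarray, coordinates: np.ndarray,
                   shape, affine=None) -> None:
    """Write a (sounds x voxels) beta matrix as a 4D NIfTI volume."""
    import nibabel as nib

    betas = np.atleast_2d(np.asarray(betas, dtype=float))
    vol = np.zeros((*shape, betas.shape[0]), dtype=np.float32)
    for v, (i, j, k) in enumerate(np.asarray(coordinates, dtype=int)):
        vol[i, j, k, :] = betas[:, v]
    nib.save(
        nib.Nifti1Image(vol, affine if affine is not None else np.eye(4)),
        str(path),
    )
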