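"""Dataset and result serialisation.

A dataset on disk is a directory with one ``subject_<id>.npz`` array
container per subject (arrays: ``data`` with shape trials x channels x
samples, ``channels``, ``fs``), a ``ratings.csv`` with columns
subject,trial,valence,arousal, and optionally a ``ground_truth.csv``
with the configured coupling per category.  Connectivity matrices can be
written as labelled plain-text square tables.  EDF reading (one trial
per file) is available when :mod:`mne` is installed.
"""

from __future__ import annotations

import re
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import HemisymError, MontageError, ValidationError
from .montage import Montage, deap_montage
from .preprocess import EEGDataset, TrialRecording
from .synthetic import GroundTruth

RATINGS_COLUMNS = ["subject", "trial", "valence", "arousal"]


def save_dataset(dataset: EEGDataset, outdir, ground_truth: GroundTruth | None = None
                 ) -> Path:
    """Write a dataset directory; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for subject, arr in sorted(dataset.data.items()):
        np.savez_compressed(
            outdir / f"subject_{subject:02d}.npz",
            data=arr.astype(np.float32),
            channels=np.array(dataset.channels),
            fs=np.array(dataset.fs),
        )
    dataset.ratings[RATINGS_COLUMNS].to_csv(outdir / "ratings.csv", index=False)
    if ground_truth is not None:
        ground_truth.kappas.to_csv(outdir / "ground_truth.csv", index=False)
    return outdir


def load_ratings(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"ratings file not found: {path}")
    ratings = pd.read_csv(path)
    missing = set(RATINGS_COLUMNS) - set(ratings.columns)
    if missing:
        raise ValidationError(f"ratings file {path} missing columns {sorted(missing)}")
    return ratings


def load_subject(path, ratings: pd.DataFrame | None = None,
                 montage: Montage | None = None
                 ) -> tuple[list[TrialRecording], pd.DataFrame]:
    """Load one subject's array container as a list of trial recordings.

    Trials come back in presentation order with the broadband tag.  The
    subject id is parsed from the ``subject_<id>.npz`` file name.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"subject container not found: {path}")
    montage = montage or deap_montage()
    m = re.search(r"subject_(\d+)", path.stem)
    subject = int(m.group(1)) if m else 0
    try:
        with np.load(path, allow_pickle=False) as npz:
            data = np.asarray(npz["data"], dtype=float)
            channels = [str(c) for c in npz["channels"]]
            fs = float(npz["fs"])
    except (OSError, KeyError, ValueError, zipfile.BadZipFile) as exc:
        raise HemisymError(f"corrupt subject container {path}: {exc}") from exc
    order = montage.resolve(channels)  # raises MontageError with names
    trials = [
        TrialRecording(data[k][order], fs, subject=subject, trial=k,
                       channels=montage.channels)
        for k in range(data.shape[0])
    ]
    if ratings is not None:
        ratings = ratings[ratings["subject"] == subject].reset_index(drop=True)
    else:
        ratings = pd.DataFrame(columns=RATINGS_COLUMNS)
    return trials, ratings


def load_dataset(directory, montage: Montage | None = None) -> EEGDataset:
    """Load a dataset directory written by :func:`save_dataset`."""
    directory = Path(directory)
    montage = montage or deap_montage()
    ratings = load_ratings(directory / "ratings.csv")
    files = sorted(directory.glob("subject_*.npz"))
    if not files:
        raise ValidationError(f"no subject_*.npz containers in {directory}")
    data: dict[int, np.ndarray] = {}
    fs = None
    for f in files:
        trials, _ = load_subject(f, montage=montage)
        subject = trials[0].subject
        fs = trials[0].fs
        data[subject] = np.stack([t.data for t in trials])
    return EEGDataset(data, montage.channels, fs, ratings)


def load_ground_truth(directory) -> GroundTruth | None:
    path = Path(directory) / "ground_truth.csv"
    if not path.exists():
        return None
    return GroundTruth(pd.read_csv(path))


def load_edf_trial(path, montage: Montage | None = None,
                   subject: int = 0, trial: int = 0) -> TrialRecording:
    """Read one trial from an EDF file (requires :mod:`mne`).

    All montage channels must be present among the EDF signals; extra
    signals are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"EDF file not found: {path}")
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise HemisymError("EDF reading requires the optional 'mne' package") from exc
    montage = montage or deap_montage()
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = raw.ch_names
    order = montage.resolve(names)
    data = raw.get_data()[order] * 1e6  # mne loads volts; analysis uses uV
    return TrialRecording(data, float(raw.info["sfreq"]), subject=subject,
                          trial=trial, channels=montage.channels)


def write_connectivity_table(values: np.ndarray, channels, path) -> Path:
    """Write a labelled square connectivity table as TSV."""
    path = Path(path)
    df = pd.DataFrame(np.asarray(values, dtype=float),
                      index=list(channels), columns=list(channels))
    df.to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_connectivity_table(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


__all__ = [
    "save_dataset", "load_dataset", "load_subject", "load_ratings",
    "load_ground_truth", "load_edf_trial", "write_connectivity_table",
    "read_connectivity_table",
]
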