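"""Loading, referencing, band decomposition and emotion categorisation.

The analysis consumes trial-structured multichannel EEG already sampled
at the target rate (128 Hz for DEAP-style data).  Preprocessing here is
deliberately minimal: common average reference, zero-phase FIR band-pass
into the four classical bands (theta 4-7, alpha 8-13, beta 14-30,
gamma 31-45 Hz), assignment of each trial to one quadrant of the
valence-arousal plane, and removal of subjects that lack trials in any
quadrant.  Artifact removal and resampling are out of scope; inputs are
assumed clean and at the analysis rate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import BandError, ValidationError
from .montage import Montage, deap_montage

logger = logging.getLogger(__name__)

#: The four analysis bands (Hz).
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
    "gamma": (31.0, 45.0),
}

#: The four emotion categories: quadrants of the valence-arousal plane.
CATEGORIES: tuple[str, ...] = ("HAHV", "LAHV", "LALV", "HALV")


@dataclass(frozen=True)
class BandSpec:
    """A frequency band with inclusive edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high):
            raise BandError(f"band {self.name!r}: need 0 < low < high, got "
                            f"({self.low}, {self.high})")

    def validate_against(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise BandError(
                f"band {self.name!r} upper edge {self.high} Hz is at or above "
                f"Nyquist ({fs / 2} Hz)"
            )


def band_spec(name: str) -> BandSpec:
    """Look up one of the four standard bands by name."""
    try:
        low, high = BANDS[name]
    except KeyError:
        raise BandError(f"unknown band {name!r}; expected one of {list(BANDS)}") from None
    return BandSpec(name, low, high)


@dataclass
class TrialRecording:
    """One trial: channels x samples, with sampling rate and band tag."""

    data: np.ndarray
    fs: float
    subject: int = 0
    trial: int = 0
    band: str = "broadband"
    channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("trial data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("trial data contains non-finite values")
        if self.channels and len(self.channels) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} rows"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EEGDataset:
    """Trial-structured multichannel EEG for several subjects.

    ``data`` maps subject id to an array of shape
    (n_trials, n_channels, n_samples); ``ratings`` holds one row per
    presented trial with columns subject, trial, valence, arousal.
    """

    data: dict[int, np.ndarray]
    channels: tuple[str, ...]
    fs: float
    ratings: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"subject", "trial", "valence", "arousal"}
        missing = need - set(self.ratings.columns)
        if missing:
            raise ValidationError(f"ratings table missing columns {sorted(missing)}")

    @property
    def subjects(self) -> list[int]:
        return sorted(self.data)

    def trial_recording(self, subject: int, trial: int) -> TrialRecording:
        return TrialRecording(self.data[subject][trial], self.fs,
                              subject=subject, trial=trial,
                              channels=self.channels)


# ---------------------------------------------------------------------------
# Referencing and filtering
# ---------------------------------------------------------------------------

def common_average_reference(trial: TrialRecording) -> TrialRecording:
    """Re-reference to the common average.

    Subtracts, at every sample, the mean over channels, so the channel
    mean of the output is zero everywhere.  Idempotent and linear.
    """
    return replace(trial, data=car_array(trial.data))


def car_array(data: np.ndarray) -> np.ndarray:
    """Common average reference on a (..., channels, samples) array."""
    data = np.asarray(data, dtype=float)
    return data - data.mean(axis=-2, keepdims=True)


def design_fir(band: BandSpec, fs: float) -> np.ndarray:
    """Hamming-window linear-phase band-pass FIR taps.

    Transition width is min(2 Hz, low/2); the tap count follows the
    usual Hamming estimate 3.3/(transition/fs), forced odd so the filter
    has an exact centre tap.
    """
    band.validate_against(fs)
    transition = min(2.0, band.low / 2.0)
    numtaps = int(np.ceil(3.3 * fs / transition))
    if numtaps % 2 == 0:
        numtaps += 1
    return signal.firwin(numtaps, [band.low, band.high], pass_zero=False,
                         window="hamming", fs=fs)


def zero_phase_filter(taps: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Forward-backward FIR filtering along the last axis.

    Equivalent to running the linear-phase filter forward then backward
    (so the net phase delay is zero and the magnitude response is
    squared).  Implemented as a single FFT convolution with the
    autocorrelation kernel of the taps, with odd-reflection padding of
    length 3 x numtaps at each end; agrees with a direct
    forward-backward pass away from the padded edges.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[-1]
    # symmetric kernel = taps convolved with their own reversal
    kernel = np.convolve(taps, taps[::-1])
    pad = min(n - 1, 3 * len(taps))
    if pad < 1:
        raise ValidationError("signal too short to filter")
    left = 2.0 * data[..., :1] - data[..., pad:0:-1]
    right = 2.0 * data[..., -1:] - data[..., -2:-pad - 2:-1]
    padded = np.concatenate([left, data, right], axis=-1)
    shape = (1,) * (data.ndim - 1) + (len(kernel),)
    out = signal.fftconvolve(padded, kernel.reshape(shape), mode="same", axes=-1)
    return out[..., pad:pad + n]


def bandpass_fir(trial: TrialRecording, band: BandSpec | str) -> TrialRecording:
    """Zero-phase FIR band-pass; output is tagged with the band name."""
    if isinstance(band, str):
        band = band_spec(band)
    taps = design_fir(band, trial.fs)
    return replace(trial, data=zero_phase_filter(taps, trial.data), band=band.name)


def bandpass_array(data: np.ndarray, band: BandSpec | str, fs: float) -> np.ndarray:
    """Band-pass a (..., channels, samples) array; batch form of
    :func:`bandpass_fir`."""
    if isinstance(band, str):
        band = band_spec(band)
    return zero_phase_filter(design_fir(band, fs), data)


# ---------------------------------------------------------------------------
# Emotion categorisation and subject exclusion
# ---------------------------------------------------------------------------

def categorize_trial(valence: float, arousal: float, threshold: float = 5.0,
                     boundary: str = "gt") -> str:
    """Assign a trial's ratings to a valence-arousal quadrant.

    "High" means rating > threshold under the default strict rule
    (``boundary='gt'``); ``boundary='ge'`` counts the threshold itself
    as high.  The scale midpoint 5 is the conventional threshold.
    """
    for label, v in (("valence", valence), ("arousal", arousal)):
        if not np.isfinite(v) or not (1.0 <= v <= 9.0):
            raise ValidationError(f"{label} rating {v} outside the 1-9 scale")
    if boundary == "gt":
        hi_v, hi_a = valence > threshold, arousal > threshold
    elif boundary == "ge":
        hi_v, hi_a = valence >= threshold, arousal >= threshold
    else:
        raise ValidationError(f"boundary must be 'gt' or 'ge', got {boundary!r}")
    if hi_a:
        return "HAHV" if hi_v else "HALV"
    return "LAHV" if hi_v else "LALV"


def categorize_ratings(ratings: pd.DataFrame, threshold: float = 5.0,
                       boundary: str = "gt") -> pd.DataFrame:
    """Add a ``category`` column to a ratings table."""
    out = ratings.copy()
    out["category"] = [
        categorize_trial(v, a, threshold, boundary)
        for v, a in zip(out["valence"], out["arousal"])
    ]
    return out


def exclude_incomplete_subjects(
    ratings: pd.DataFrame,
    categories: tuple[str, ...] = CATEGORIES,
) -> tuple[pd.DataFrame, dict[int, list[str]]]:
    """Drop subjects lacking at least one trial in every category.

    A subject whose ratings fall into only three (or fewer) of the four
    quadrants cannot contribute to within-subject comparisons across all
    categories and is removed, mirroring standard practice.  Returns the
    filtered table and a mapping of removed subject -> empty categories.
    """
    if "category" not in ratings.columns:
        raise ValidationError("ratings must be categorized first")
    removed: dict[int, list[str]] = {}
    keep: list[int] = []
    for subject, grp in ratings.groupby("subject"):
        present = set(grp["category"])
        empty = [c for c in categories if c not in present]
        if empty:
            removed[int(subject)] = empty
            logger.info("excluding subject %s: no trials in %s", subject, empty)
        else:
            keep.append(subject)
    out = ratings[ratings["subject"].isin(keep)].reset_index(drop=True)
    if out.empty:
        warnings.warn("all subjects excluded: every subject lacks at least one "
                      "emotion category", stacklevel=2)
    return out, removed


def apply_exclusion(dataset: EEGDataset, threshold: float = 5.0,
                    boundary: str = "gt") -> tuple[EEGDataset, dict[int, list[str]]]:
    """Categorize a dataset's ratings and drop incomplete subjects."""
    cat = categorize_ratings(dataset.ratings, threshold, boundary)
    kept, removed = exclude_incomplete_subjects(cat)
    data = {s: arr for s, arr in dataset.data.items() if s not in removed}
    return EEGDataset(data, dataset.channels, dataset.fs, kept), removed


def drop_baseline(data: np.ndarray, fs: float, seconds: float) -> np.ndarray:
    """Remove a pre-trial baseline from the start of each trial.

    DEAP-style preprocessed arrays carry a 3 s pre-trial segment; the
    analysis window is the stimulus period only.
    """
    n = int(round(seconds * fs))
    return data[..., n:] if n > 0 else data


__all__ = [
    "BANDS", "CATEGORIES", "BandSpec", "band_spec", "TrialRecording",
    "EEGDataset", "common_average_reference", "car_array", "design_fir",
    "zero_phase_filter", "bandpass_fir", "bandpass_array",
    "categorize_trial", "categorize_ratings", "exclude_incomplete_subjects",
    "apply_exclusion", "drop_baseline", "Montage", "deap_montage",
]
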