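"""Synthetic lateralized-EEG generator with known phase-coupling ground truth.

Emulates the shape of DEAP-style affective-EEG experiments (subjects x
trials x 32 channels x samples at 128 Hz, with per-trial valence/arousal
ratings) while giving full control over hemispheric phase coupling, so
that parameter-recovery and type-I-error behaviour of the analysis
pipeline can be tested against a known truth.

Signal model, per trial and per frequency band with centre frequency f:

    x_c(t) = cos(2 pi f t + o_c + W_h(c)(t) + z_{h,m(c)}(t) + e_c(t)) + noise

* ``o_c`` is a per-channel phase offset: a fixed evenly spaced "slot"
  within the channel's module spanning [pi/8, 7pi/8], plus a small
  per-trial uniform jitter.  Offsets guarantee a fixed *nonzero* lag
  between channels (so perfect locking yields a phase-lag index of 1
  rather than 0 — the PLI is blind to zero-lag coupling), and the even
  spacing keeps every within-module lag away from both 0 and pi, so
  that when coupling is tight *all* within-module edges are strong and
  the thresholded network closes triangles.  (Offsets drawn uniformly
  at random would instead make strong edges anti-transitive: two large
  lags A-B and B-C force the A-C lag towards 0 mod pi, suppressing
  exactly the triangles that distinguish a coupled hemisphere.)
* ``W_h(t)`` is a slow random-walk phase shared by all channels of one
  hemisphere.  Within a hemisphere it cancels in every phase
  difference; across hemispheres the two independent walks decohere the
  signals, so interhemispheric PLI decays to zero unless
  ``kappa_inter`` ties the pools together.
* ``z_{h,m}(t)`` is a per-module pool jitter.  Each hemisphere's lateral
  channels are grouped into three spatial modules (frontal, central,
  posterior); the jitter is blockwise von Mises with concentration
  ``module_coupling_ratio x kappa``, so within-module pairs lock more
  tightly than between-module pairs.  This is what gives a strongly
  coupled hemisphere its *clustered* (modular) network topology rather
  than a uniformly strong one.
* ``e_c(t)`` is per-channel wrapped phase noise: von Mises(0, kappa)
  innovations held constant over short blocks.  Large kappa means tight
  within-hemisphere locking; kappa = 0 means uniform phase noise and no
  coupling; kappa = inf is exact locking (every within-hemisphere pair
  reaches PLI = 1).  Midline channels follow the circular mean of the
  two hemispheres' module pools with the mean concentration.

One oscillatory component is generated per band per trial; spectra are
otherwise flat (no 1/f background, no artifacts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .montage import Montage, deap_montage
from .preprocess import CATEGORIES, EEGDataset, TrialRecording

#: Default band-centre frequencies (Hz), one oscillator per band.
DEFAULT_BAND_CENTERS: dict[str, float] = {
    "theta": 5.5, "alpha": 10.5, "beta": 22.0, "gamma": 38.0,
}

#: Spatial coupling modules: anterior-to-posterior groups of homologous
#: lateral channels, with each midline channel attached to the nearest
#: group.  Module membership is mirror-symmetric across hemispheres.
MODULES: dict[str, tuple[str, ...]] = {
    "frontal": ("Fp1", "AF3", "F7", "F3", "FC5",
                "Fp2", "AF4", "F8", "F4", "FC6", "Fz"),
    "central": ("FC1", "T7", "C3", "CP5", "CP1",
                "FC2", "T8", "C4", "CP6", "CP2", "Cz"),
    "posterior": ("P7", "P3", "PO3", "O1",
                  "P8", "P4", "PO4", "O2", "Pz", "Oz"),
}

#: Ratings are drawn strictly inside the intended quadrant, away from the
#: category threshold at 5, so the boundary tie rule never triggers.
_QUADRANTS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    # category: ((valence low, high), (arousal low, high))
    "HAHV": ((6.0, 9.0), (6.0, 9.0)),
    "LAHV": ((6.0, 9.0), (1.0, 4.0)),
    "LALV": ((1.0, 4.0), (1.0, 4.0)),
    "HALV": ((1.0, 4.0), (6.0, 9.0)),
}


def _as_category_map(value, name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        out = {c: float(value.get(c, 0.0)) for c in CATEGORIES}
    else:
        out = {c: float(value) for c in CATEGORIES}
    for c, v in out.items():
        if not (v >= 0.0):  # also rejects NaN
            raise ValidationError(f"{name}[{c}] must be >= 0, got {v}")
    return out


@dataclass
class SyntheticConfig:
    """Generator settings.

    Defaults mirror the DEAP study conditions: 32 subjects, 40 one-minute
    trials (10 per emotion quadrant) at 128 Hz.  ``kappa_left`` and
    ``kappa_right`` set the within-hemisphere von Mises concentration in
    the ``coupling_band`` and may be a scalar or a per-category mapping;
    other bands use the symmetric ``kappa_baseline``.
    """

    n_subjects: int = 32
    n_trials_per_category: int = 10
    fs: float = 128.0
    duration: float = 60.0
    bands: tuple[str, ...] = ("theta", "alpha", "beta", "gamma")
    band_centers: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_CENTERS))
    coupling_band: str = "gamma"
    kappa_left: float | Mapping[str, float] = 4.0
    kappa_right: float | Mapping[str, float] = 4.0
    kappa_baseline: float = 2.0
    kappa_inter: float = 0.0
    module_coupling_ratio: float = 0.2
    noise_sd: float = 0.5
    pool_walk_sd: float = 0.15      # rad per sample, hemisphere pool random walk
    coupling_refresh: int = 8       # samples per phase-noise innovation block
    offset_range: tuple[float, float] = (math.pi / 8, 7 * math.pi / 8)
    offset_jitter: float = math.pi / 30   # per-trial jitter around the slots
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValidationError("n_subjects must be >= 2")
        if self.n_trials_per_category < 1:
            raise ValidationError("n_trials_per_category must be >= 1")
        if self.fs <= 0 or self.duration <= 0:
            raise ValidationError("fs and duration must be positive")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValidationError(
                f"duration x fs = {n} is not an integer number of samples")
        for b in self.bands:
            if b not in self.band_centers:
                raise ValidationError(f"no band centre for band {b!r}")
        if self.coupling_band not in self.bands:
            raise ValidationError(
                f"coupling_band {self.coupling_band!r} not among bands {self.bands}")
        for name in ("kappa_baseline", "kappa_inter", "noise_sd",
                     "pool_walk_sd", "module_coupling_ratio"):
            v = getattr(self, name)
            if not (v >= 0.0):
                raise ValidationError(f"{name} must be >= 0, got {v}")
        if self.coupling_refresh < 1:
            raise ValidationError("coupling_refresh must be >= 1")
        # normalise kappas to per-category maps (validates non-negativity)
        self.kappa_left = _as_category_map(self.kappa_left, "kappa_left")
        self.kappa_right = _as_category_map(self.kappa_right, "kappa_right")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def coupling_for(self, category: str) -> dict[str, float]:
        return {"left": self.kappa_left[category],
                "right": self.kappa_right[category]}


@dataclass
class GroundTruth:
    """Configured coupling per category and the implied asymmetry sign.

    ``expected_sign`` is the sign of the expected asymmetry score for
    cohesion-type properties (clustering, efficiencies): negative
    (leftward) when the left hemisphere is more tightly coupled,
    positive (rightward) when the right is.
    """

    kappas: pd.DataFrame  # columns: category, kappa_left, kappa_right

    @property
    def expected_sign(self) -> dict[str, int]:
        out = {}
        for _, row in self.kappas.iterrows():
            diff = row["kappa_right"] - row["kappa_left"]
            out[row["category"]] = int(np.sign(diff))
        return out


def base_offsets(config: SyntheticConfig, montage: Montage | None = None
                 ) -> np.ndarray:
    """Deterministic per-channel phase-offset slots.

    Within each module, homologous lateral pairs share evenly spaced
    slots across ``offset_range`` (pairwise lags stay well away from 0
    and pi, so tight coupling produces uniformly strong within-module
    edges); midline channels sit on the slot boundaries; each module's
    grid is staggered slightly so equal ranks in different modules do
    not align at zero lag.
    """
    montage = montage or deap_montage()
    lo, hi = config.offset_range
    span = hi - lo
    offsets = np.empty(montage.n_channels)
    left_set = set(montage.left_lateral)
    right_set = set(montage.right_lateral)
    homolog = dict(montage.homologous_pairs)
    for mi, members in enumerate(MODULES.values()):
        lat_left = [ch for ch in members if ch in left_set]
        mids = [ch for ch in members
                if ch not in left_set and ch not in right_set]
        q = len(lat_left)
        stagger = mi * span / (3 * q)
        for k, ch in enumerate(lat_left):
            val = lo + (k + 0.5) * span / q + stagger
            offsets[montage.index(ch)] = val
            offsets[montage.index(homolog[ch])] = val
        for k, ch in enumerate(mids):
            offsets[montage.index(ch)] = lo + (k + 1.0) * span / q + stagger
    return offsets


def _von_mises_blocks(rng: np.random.Generator, kappa: float, n_channels: int,
                      n_samples: int, block: int) -> np.ndarray:
    """Block-constant von Mises(0, kappa) phase noise, (channels, samples).

    Holding each innovation over ``block`` samples keeps the phase noise
    band-limited so the oscillator stays inside its frequency band.
    kappa = inf gives exactly zero noise (perfect locking);
    kappa = 0 gives uniform phases (no coupling).
    """
    n_blocks = -(-n_samples // block)
    if np.isinf(kappa):
        return np.zeros((n_channels, n_samples))
    draws = rng.vonmises(0.0, kappa, size=(n_channels, n_blocks))
    return np.repeat(draws, block, axis=1)[:, :n_samples]


def generate_trial(config: SyntheticConfig,
                   hemisphere_coupling: Mapping[str, float],
                   rng: np.random.Generator,
                   montage: Montage | None = None,
                   return_phases: bool = False):
    """Generate one trial of 32-channel synthetic EEG.

    ``hemisphere_coupling`` maps 'left'/'right' to the von Mises
    concentration of within-hemisphere coupling in the coupling band.
    With ``return_phases=True`` also returns the per-band ground-truth
    phase arrays (channels x samples), useful as an oracle for
    connectivity estimates.
    """
    montage = montage or deap_montage()
    for side in ("left", "right"):
        if not (hemisphere_coupling[side] >= 0.0):
            raise ValidationError(f"kappa_{side} must be >= 0")
    n = config.n_samples
    t = np.arange(n) / config.fs
    nch = montage.n_channels
    left_set = set(montage.left_lateral)
    right_set = set(montage.right_lateral)
    module_of = {ch: m for m, chans in MODULES.items() for ch in chans}
    module_names = list(MODULES)
    slots = base_offsets(config, montage)

    data = np.zeros((nch, n))
    phases: dict[str, np.ndarray] = {}
    for band in config.bands:
        f = config.band_centers[band]
        if band == config.coupling_band:
            k_left = float(hemisphere_coupling["left"])
            k_right = float(hemisphere_coupling["right"])
        else:
            k_left = k_right = config.kappa_baseline
        k_mid = 0.5 * (k_left + k_right)
        r = config.module_coupling_ratio

        # hemisphere-wide walk phases: the right hemisphere either follows
        # its own walk (kappa_inter = 0 -> hemispheres decohere) or tracks
        # the left one with wrapped von Mises jitter
        walk_left = np.cumsum(rng.normal(0.0, config.pool_walk_sd, n))
        walk_right = np.cumsum(rng.normal(0.0, config.pool_walk_sd, n))
        if config.kappa_inter > 0:
            jitter = _von_mises_blocks(rng, config.kappa_inter, 1, n,
                                       config.coupling_refresh)[0]
            walk_right = walk_left + jitter

        # per-module pool phases: hemisphere walk plus module jitter whose
        # concentration scales with the hemisphere's kappa
        pools: dict[tuple[str, str], np.ndarray] = {}
        for m in module_names:
            zl = _von_mises_blocks(rng, r * k_left, 1, n,
                                   config.coupling_refresh)[0]
            zr = _von_mises_blocks(rng, r * k_right, 1, n,
                                   config.coupling_refresh)[0]
            pools[("left", m)] = walk_left + zl
            pools[("right", m)] = walk_right + zr

        offsets = slots + rng.uniform(-config.offset_jitter,
                                      config.offset_jitter, size=nch)
        phase = np.empty((nch, n))
        base = 2 * np.pi * f * t
        for c, name in enumerate(montage.channels):
            m = module_of[name]
            if name in left_set:
                pool, kappa = pools[("left", m)], k_left
            elif name in right_set:
                pool, kappa = pools[("right", m)], k_right
            else:  # midline: circular mean of the two hemispheres' pools
                pool = np.angle(np.exp(1j * pools[("left", m)])
                                + np.exp(1j * pools[("right", m)]))
                kappa = k_mid
            nu = _von_mises_blocks(rng, kappa, 1, n, config.coupling_refresh)[0]
            phase[c] = base + offsets[c] + pool + nu
        data += np.cos(phase)
        if return_phases:
            phases[band] = phase

    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=data.shape)

    trial = TrialRecording(data, config.fs, channels=montage.channels)
    if return_phases:
        return trial, phases
    return trial


def _trial_rng(seed: int, subject: int, trial: int,
               stream: int = 0) -> np.random.Generator:
    """Counter-based per-trial RNG stream.

    Streams are derived from the root seed via a SeedSequence spawn key
    (subject, trial, stream), so any trial can be regenerated
    independently and in any order.
    """
    ss = np.random.SeedSequence(seed, spawn_key=(subject, trial, stream))
    return np.random.Generator(np.random.PCG64(ss))


def generate_dataset(config: SyntheticConfig,
                     montage: Montage | None = None
                     ) -> tuple[EEGDataset, GroundTruth]:
    """Generate a full dataset: every subject gets ``n_trials_per_category``
    trials in each of the four emotion quadrants, with ratings drawn
    strictly inside the matching quadrant.

    Trials are ordered by category block (HAHV, LAHV, LALV, HALV) within
    each subject.  Deterministic given (config, seed).
    """
    montage = montage or deap_montage()
    n_trials = 4 * config.n_trials_per_category
    data: dict[int, np.ndarray] = {}
    rows = []
    for s in range(config.n_subjects):
        arr = np.empty((n_trials, montage.n_channels, config.n_samples))
        k = 0
        for category in CATEGORIES:
            coupling = config.coupling_for(category)
            (v_lo, v_hi), (a_lo, a_hi) = _QUADRANTS[category]
            for _ in range(config.n_trials_per_category):
                rng = _trial_rng(config.seed, s, k)
                arr[k] = generate_trial(config, coupling, rng, montage).data
                rrng = _trial_rng(config.seed, s, k, stream=1)
                rows.append({
                    "subject": s, "trial": k,
                    "valence": float(rrng.uniform(v_lo, v_hi)),
                    "arousal": float(rrng.uniform(a_lo, a_hi)),
                })
                k += 1
        data[s] = arr
    ratings = pd.DataFrame(rows)
    kappas = pd.DataFrame([
        {"category": c, "kappa_left": config.kappa_left[c],
         "kappa_right": config.kappa_right[c]}
        for c in CATEGORIES
    ])
    dataset = EEGDataset(data, montage.channels, config.fs, ratings)
    return dataset, GroundTruth(kappas)


__all__ = [
    "SyntheticConfig", "GroundTruth", "DEFAULT_BAND_CENTERS",
    "generate_trial", "generate_dataset",
]
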