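"""Ground-truth behaviour of the synthetic lateralized-EEG generator."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hemisym.exceptions import ValidationError
from hemisym.synthetic import (SyntheticConfig, _trial_rng, base_offsets,
                               generate_dataset, generate_trial)


def small_config(**kw):
    defaults = dict(n_subjects=2, n_trials_per_category=1, duration=4.0,
                    bands=("gamma",), seed=0)
    defaults.update(kw)
    return SyntheticConfig(**defaults)


def true_pli(phases, i, j):
    return abs(np.mean(np.sign(np.sin(phases[i] - phases[j]))))


def mean_within_pli(phases, montage, side):
    idx = montage.indices(getattr(montage, f"{side}_lateral"))
    vals = [true_pli(phases, a, b) for a, b in itertools.combinations(idx, 2)]
    return np.mean(vals)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(n_subjects=1),
        dict(duration=-1.0),
        dict(fs=0.0),
        dict(duration=1.005),            # non-integer sample count
        dict(kappa_left=-2.0),
        dict(kappa_inter=-0.1),
        dict(noise_sd=-1.0),
        dict(coupling_band="alpha"),     # not among simulated bands
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValidationError):
            small_config(**kw)

    def test_scalar_kappa_broadcast_to_categories(self):
        cfg = small_config(kappa_left=3.0)
        assert cfg.kappa_left == {c: 3.0 for c in
                                  ("HAHV", "LAHV", "LALV", "HALV")}


class TestGenerateTrial:
    def test_perfect_locking_gives_unit_pli_within_hemisphere(self, montage):
        cfg = small_config(noise_sd=0.0)
        _, phases = generate_trial(cfg, {"left": np.inf, "right": np.inf},
                                   _trial_rng(0, 0, 0), return_phases=True)
        p = phases["gamma"]
        for side in ("left", "right"):
            idx = montage.indices(getattr(montage, f"{side}_lateral"))
            for a, b in itertools.combinations(idx, 2):
                assert true_pli(p, a, b) == 1.0

    def test_zero_kappa_pli_vanishes_with_samples(self, montage):
        """With kappa = 0 the mean pairwise PLI obeys the null scaling
        |mean sign| ~ sqrt(2/(pi n_eff)); n_eff is estimated from an
        independent simulation of block-held uniform phase noise."""
        cfg = small_config(duration=16.0, noise_sd=0.0)
        _, phases = generate_trial(cfg, {"left": 0.0, "right": 0.0},
                                   _trial_rng(0, 0, 1), return_phases=True)
        measured = mean_within_pli(phases["gamma"], montage, "left")
        # oracle: mean |sign sin| of differences of two block-held uniform
        # phase-noise series of the same length and block size
        r = np.random.default_rng(99)
        n, block = cfg.n_samples, cfg.coupling_refresh
        sims = []
        for _ in range(300):
            a = np.repeat(r.uniform(-np.pi, np.pi, n // block), block)
            b = np.repeat(r.uniform(-np.pi, np.pi, n // block), block)
            sims.append(abs(np.mean(np.sign(np.sin(a - b)))))
        oracle_mean = np.mean(sims)       # ~ sqrt(2/(pi n_eff))
        assert measured < 3 * oracle_mean

    def test_fixed_seed_bitwise_deterministic(self):
        cfg = small_config()
        coupling = {"left": 4.0, "right": 2.0}
        a = generate_trial(cfg, coupling, _trial_rng(7, 1, 2)).data
        b = generate_trial(cfg, coupling, _trial_rng(7, 1, 2)).data
        assert np.array_equal(a, b)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValidationError):
            generate_trial(small_config(), {"left": -1.0, "right": 1.0},
                           _trial_rng(0, 0, 0))

    def test_pli_monotone_in_kappa(self, montage):
        """Mean within-hemisphere PLI is non-decreasing in kappa over a
        grid, within twice the Monte-Carlo standard error."""
        cfg = small_config(duration=4.0, noise_sd=0.0)
        kappas = [0.0, 1.0, 3.0, 8.0, 30.0]
        means, errs = [], []
        for k in kappas:
            vals = []
            for rep in range(20):
                _, ph = generate_trial(cfg, {"left": k, "right": k},
                                       _trial_rng(11, rep, 0),
                                       return_phases=True)
                vals.append(mean_within_pli(ph["gamma"], montage, "left"))
            means.append(np.mean(vals))
            errs.append(np.std(vals, ddof=1) / np.sqrt(len(vals)))
        for lo, hi in zip(range(len(kappas) - 1), range(1, len(kappas))):
            tol = 2 * np.hypot(errs[lo], errs[hi])
            assert means[hi] >= means[lo] - tol, (
                f"PLI not monotone: kappa {kappas[lo]}->{kappas[hi]} "
                f"gave {means[lo]:.3f}->{means[hi]:.3f}")

    def test_lateralized_coupling_orders_hemispheres(self, montage):
        cfg = small_config(duration=8.0)
        lefts, rights = [], []
        for rep in range(5):
            _, ph = generate_trial(cfg, {"left": 8.0, "right": 1.0},
                                   _trial_rng(5, rep, 0), return_phases=True)
            lefts.append(mean_within_pli(ph["gamma"], montage, "left"))
            rights.append(mean_within_pli(ph["gamma"], montage, "right"))
        assert np.mean(lefts) > np.mean(rights)

    def test_offsets_stay_clear_of_zero_and_pi(self, montage):
        offs = base_offsets(small_config(), montage)
        assert np.all(offs > 0) and np.all(offs < np.pi)


class TestGenerateDataset:
    def test_shapes_ratings_and_ground_truth(self):
        cfg = small_config(n_subjects=3, n_trials_per_category=2)
        ds, truth = generate_dataset(cfg)
        assert sorted(ds.data) == [0, 1, 2]
        assert ds.data[0].shape == (8, 32, cfg.n_samples)
        assert len(ds.ratings) == 24
        assert ds.ratings["valence"].between(1, 9).all()
        assert ds.ratings["arousal"].between(1, 9).all()
        assert set(truth.kappas["category"]) == {"HAHV", "LAHV", "LALV",
                                                 "HALV"}

    def test_ratings_fall_strictly_inside_quadrants(self):
        from hemisym.preprocess import categorize_ratings
        cfg = small_config(n_subjects=2, n_trials_per_category=3)
        ds, _ = generate_dataset(cfg)
        cat = categorize_ratings(ds.ratings)
        # block order: HAHV, LAHV, LALV, HALV per subject
        expected = (["HAHV"] * 3 + ["LAHV"] * 3 + ["LALV"] * 3
                    + ["HALV"] * 3) * 2
        assert list(cat["category"]) == expected
        assert ((ds.ratings["valence"] < 4.5)
                | (ds.ratings["valence"] > 5.5)).all()

    def test_single_trial_per_category_keeps_every_subject(self):
        from hemisym.preprocess import apply_exclusion
        ds, _ = generate_dataset(small_config(n_subjects=3))
        kept, removed = apply_exclusion(ds)
        assert not removed and sorted(kept.data) == [0, 1, 2]

    def test_dataset_deterministic_given_seed(self):
        cfg = small_config(n_subjects=2)
        a, _ = generate_dataset(cfg)
        b, _ = generate_dataset(cfg)
        for s in a.data:
            assert np.array_equal(a.data[s], b.data[s])
        pd.testing.assert_frame_equal(a.ratings, b.ratings)

    def test_expected_sign_reflects_configured_lateralization(self):
        cfg = small_config(
            kappa_left={"HAHV": 8.0, "LAHV": 2.0, "LALV": 2.0, "HALV": 1.0},
            kappa_right={"HAHV": 1.0, "LAHV": 2.0, "LALV": 2.0, "HALV": 8.0})
        _, truth = generate_dataset(cfg)
        signs = truth.expected_sign
        assert signs["HAHV"] == -1 and signs["HALV"] == 1
        assert signs["LAHV"] == 0 and signs["LALV"] == 0

    def test_symmetric_config_has_no_mean_asymmetry(self, montage):
        """Monte-Carlo check of hemispheric exchangeability: over many
        symmetric-config trials the left-minus-right mean within-
        hemisphere PLI difference is centred on zero."""
        cfg = small_config(duration=4.0)
        diffs = []
        for rep in range(60):
            _, ph = generate_trial(cfg, {"left": 4.0, "right": 4.0},
                                   _trial_rng(17, rep, 0), return_phases=True)
            diffs.append(mean_within_pli(ph["gamma"], montage, "left")
                         - mean_within_pli(ph["gamma"], montage, "right"))
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se + 1e-3
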