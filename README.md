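# hemisym

Hemispheric asymmetry of EEG functional brain networks.

Emotions engage the two cerebral hemispheres unevenly, and one way to
quantify that is to compare the *topology* of left- and right-hemisphere
functional networks rather than raw power or amplitude. `hemisym`
implements that analysis end-to-end for trial-structured, 32-channel
(10–20 montage) EEG with per-trial valence/arousal ratings, such as
affective music-video experiments:

1. trials are sorted into the four quadrants of the valence–arousal
   plane (HAHV, LAHV, LALV, HALV) at the rating threshold 5;
2. each trial is common-average referenced and band-passed into
   θ (4–7), α (8–13), β (14–30) and γ (31–45 Hz);
3. phase-lag-index (PLI) connectivity is computed between all channel
   pairs from analytic-signal phases,
   `PLI = |⟨sign sin(φ_i − φ_j)⟩| ∈ [0, 1]`, which ignores zero-lag
   (volume-conducted) coupling;
4. two 18-node hemispheric networks (14 lateral + 4 midline electrodes,
   interhemispheric edges removed) are proportionally thresholded at
   sparsities 5–40% and characterised by clustering coefficient `C_p`,
   characteristic path length `L_p`, global/local efficiency
   `E_g`/`E_loc`, small-world index `σ` and nodal efficiency
   `E_nodal(i)`;
5. each metric's area under the sparsity curve is averaged within
   subject × category and compared between hemispheres: paired t-tests,
   one-sample t-tests of the asymmetry score
   `AS(X) = 100·(X_R − X_L)/(X_R + X_L)` (positive = rightward), and
   FDR-corrected tests across the 14 homologous electrode pairs.

Because real affective-EEG datasets are access-restricted, the package
ships a first-class synthetic generator that emulates their shape
(subjects × trials × 32 channels × samples at 128 Hz, plus ratings)
with a controllable von Mises phase-coupling ground truth per
hemisphere and per category — the basis for the package's
parameter-recovery and false-positive-rate validation. See
`docs/methods.md` for the model and its limits.

## Worked example

Simulate a small left-lateralized dataset (tight gamma-band coupling in
the left hemisphere for high-arousal/high-valence trials) and analyse
it:

```bash
hemisym simulate --out demo/data --n-subjects 8 --n-trials-per-category 4 \
    --duration 10 --bands gamma --kappa-left 12 --kappa-right 0.5 --seed 1
hemisym analyze --data demo/data --out demo/results \
    --bands gamma --metrics Cp,Lp,Eg,Eloc --threshold-step 5 --no-nodal --seed 1
hemisym report --results demo/results --no-plots
```

which prints (abridged; values are per-subject means of the AUC of
each metric over sparsity 5–40%):

```
== gamma / HAHV (per-subject sparsity-AUC means) ==
      Cp: L=0.1362 R=0.0814  t=+11.823 p=0.0000 ***
      Eg: L=0.1336 R=0.1722  t=-82.590 p=0.0000 ***
    Eloc: L=0.1632 R=0.1066  t=+11.959 p=0.0000 ***
      Lp: L=0.6243 R=0.7375  t=-16.230 p=0.0000 ***
```

The tightly coupled left hemisphere forms a more clustered, locally
efficient network — higher `C_p` and `E_loc` with positive t
(left > right, a leftward asymmetry; `asymmetry_global.csv` reports the
matching AS(C_p) = −25.2 and AS(E_loc) = −21.0) — and shorter
characteristic paths (lower `L_p` AUC). Its modular topology is *less*
globally integrated, so `E_g` moves the other way; see
`docs/methods.md` for why segregation and integration metrics
dissociate under modular coupling. `demo/results/` also contains the
per-subject AUC tables and a `manifest.json` from which the run can be
reproduced byte-for-byte. (The scalar `--kappa-left/right` flags
lateralize every category; per-category coupling is available through
the YAML config.)

The same analysis is available as a library:

```python
from hemisym import SyntheticConfig, generate_dataset, AnalysisConfig, run_full_analysis

dataset, truth = generate_dataset(SyntheticConfig(n_subjects=8, seed=1))
result = run_full_analysis(dataset, AnalysisConfig())
print(result.asymmetry_global.head())
```

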