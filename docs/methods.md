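# Methods

## Overview

`hemisym` quantifies hemispheric asymmetry of EEG functional brain
networks across emotion categories. The chain is:

1. **Categorisation.** Each trial's valence/arousal ratings (1–9) are
   assigned to a quadrant of the valence–arousal plane at threshold 5:
   HAHV, LAHV, LALV, HALV. "High" means strictly `> 5` by default; the
   tie rule is configurable (`rating_boundary: gt|ge`) because a rating
   of exactly 5 is genuinely ambiguous at the scale midpoint. Subjects
   lacking at least one trial in any quadrant are excluded (they cannot
   contribute to within-subject contrasts across all categories).
2. **Preprocessing.** Common average reference, then zero-phase FIR
   band-pass into θ (4–7), α (8–13), β (14–30) and γ (31–45 Hz).
   The filter is a Hamming-window linear-phase design with transition
   width `min(2 Hz, low/2)` applied forward–backward, implemented as a
   single FFT convolution with the kernel `taps ⋆ reversed(taps)` and
   odd-reflection padding; this equals a literal two-pass application
   away from the edges (asserted to 1e-8 in tests) and is an order of
   magnitude faster on trial batches. Inputs must already be at the
   analysis rate; resampling and artifact removal are out of scope.
3. **Connectivity.** Instantaneous phase from the analytic signal
   `x + i·H[x]`; the phase lag index between channels i and j is
   `PLI = |⟨sign(sin(φ_i − φ_j))⟩|`. PLI is 0 for no coupling *and* for
   coupling at 0 mod π lag (volume-conduction safe), 1 for perfect
   locking at a nonzero lag. `sign(0)` contributes 0, so a channel with
   itself scores exactly 0. The first/last 64 samples (0.5 s at 128 Hz)
   after the Hilbert transform are discarded to bound FFT edge
   artifacts (configurable `trim`). A weighted variant (wPLI,
   `|mean Im S_ij| / mean |Im S_ij|`, 0/0 := 0) is available under a
   separate method tag and never mixed with PLI output.
4. **Hemispheric networks.** From each 32×32 matrix, two 18-node
   networks: 14 lateral electrodes of one side plus the 4 midline
   electrodes; interhemispheric lateral entries are discarded. Node i
   of the left network is the mirror homolog of node i of the right.
5. **Thresholding and metrics.** Proportional threshold: the strongest
   `round(S/100 × 153)` edges are retained and binarised, for S = 5…40%
   in 1% steps (inclusive; 36 levels). Rounding is half-away-from-zero;
   ties break by ascending (row, column) index so runs are
   deterministic. On each binary graph: clustering coefficient Cp,
   characteristic path length Lp (disconnected pairs excluded, with a
   warning), global efficiency Eg (1/∞ = 0), local efficiency Eloc,
   per-node efficiency Enodal, and the small-world index
   σ = (Cp/Crandom)/(Lp/Lrandom) against 100 degree-preserving rewired
   surrogates (10×|E| attempted double-edge swaps each, seeded). A
   `weighted` switch computes Onnela clustering and 1/weight path
   lengths instead; σ stays binary-only because its null is a binary
   construct.
6. **Aggregation and statistics.** Each metric's threshold curve is
   summarised by its trapezoidal AUC on the fractional threshold axis,
   averaged over a subject's trials within one category. Per band ×
   category: paired t-tests of left vs right per-subject AUCs
   (positive t = left > right); one-sample t-tests of the asymmetry
   score `AS = 100(R − L)/(R + L)` against 0 (positive = rightward);
   Shapiro–Wilk normality flags attached; and per homologous pair the
   same two tests on Enodal with Benjamini–Hochberg FDR at q = 0.05
   (configurable) across the 14 pairs within one band × category — the
   narrowest natural family. Global-property tests are reported
   uncorrected by default; `correct_global: true` applies the same BH
   correction across the global metrics within each band × category.

## Degenerate inputs and sentinels

Zero-variance paired differences and constant asymmetry samples return
NaN sentinels with warnings (identical hemispheres return t = 0,
p = 1). An empty graph has undefined Lp (NaN + warning) and Eg = 0.
Both-zero property pairs make AS undefined (NaN + warning). NaN
p-values are excluded from the FDR family and never rejected.

## The synthetic generator

The generator emulates the *shape* of DEAP-style affective-EEG studies
(default 32 subjects, 10 trials per quadrant, 32 channels, 60 s at
128 Hz, ratings drawn strictly inside the intended quadrant) with a
controllable phase-coupling ground truth. Per band, each channel is a
unit cosine at the band centre whose phase carries four components:

* a fixed per-channel offset (see below),
* a hemisphere-wide random-walk phase (sd 0.15 rad/sample) that cancels
  within a hemisphere but decoheres the two hemispheres
  (`kappa_inter > 0` ties the right walk to the left with wrapped
  von Mises jitter),
* a per-module pool jitter — lateral channels are grouped into three
  mirror-symmetric spatial modules (frontal/central/posterior, midline
  channels attached to the nearest group) whose von Mises concentration
  is `module_coupling_ratio × kappa` (default 0.2× — between-module
  locking five times looser than within-module, calibrated once so that
  tight coupling produces a distinctly modular topology; at ratios
  ≳ 0.3 the between-module edges catch up and the clustering signature
  washes out),
* per-channel von Mises(0, κ) phase noise held constant over 8-sample
  blocks (block-holding keeps the noise band-limited so the oscillator
  survives its own band-pass filter).

κ per hemisphere (optionally per category) is the lateralization dial:
κ = 0 gives uniform phases and no coupling, κ = ∞ exact locking with
PLI = 1 on every within-hemisphere pair. Midline channels follow the
circular mean of the two hemispheres' module pools with the mean
concentration, so a symmetric configuration is exactly exchangeable
under left–right reflection — the basis of the type-I-error test.

**Why structured offsets.** Per-channel lags are evenly spaced "slots"
within each module spanning [π/8, 7π/8] (homologs share slots, module
grids staggered, small per-trial jitter). Offsets drawn uniformly at
random would make strong edges anti-transitive — two large lags A–B and
B–C force the A–C lag toward 0 mod π, where PLI is blind — so a tightly
coupled hemisphere would paradoxically *lose* triangles and show lower
clustering. Even spacing keeps every within-module lag away from 0 and
π, so tight coupling yields uniformly strong within-module edges and a
clustered, modular topology; weak coupling yields a noise graph.

**What lateralized coupling produces.** Tightening one hemisphere's κ
raises its within-module PLI above everything else, so the proportional
threshold concentrates edges inside modules: higher Cp and Eloc, lower
Lp (segregation). Because the modular graph is *less* globally
integrated at low sparsity than a same-density noise graph, Eg can move
the other way; the generator's sign guarantee therefore covers the
segregation metrics (Cp, Eloc), which is what the recovery test checks.

**What the generator does not emulate:** 1/f background spectra,
artifacts, volume conduction (zero-lag mixing), per-subject anatomy,
within-band multi-oscillator dynamics. Passing tests therefore show
that the pipeline recovers phase-coupling asymmetry with correct signs
and calibrated false-positive rates under this model — not that it
would detect any particular effect in recorded EEG.

RNG streams are counter-based: every (subject, trial, purpose) gets a
`SeedSequence(seed, spawn_key=...)` generator, so datasets are
reproducible trial-by-trial and byte-identical across runs.

## Validation scales

The test suite runs the pipeline end-to-end at reduced problem sizes,
chosen to keep the full suite in the tens of minutes: the
type-I-error calibration uses 200 replicate symmetric datasets of 30
subjects × 4 trials/category × 10 s, analysed in the gamma band for the
HAHV category with Cp over thresholds 5–40% in 5% steps; the recovery
test uses 50 replicates of 12 subjects with the HAHV left-lateralized
at κ_left = 12 vs κ_right = 0.5 (frozen calibration), checking
negative, significantly paired-tested AS(Cp) and AS(Eloc) in ≥ 80% of
replicates. Metric implementations are checked against independent
brute-force BFS/enumeration oracles to 1e-12 on 200 random 18-node
graphs spanning the sparsity range.

## Known limitations

* Whole-trial PLI only; no epoching within trials.
* Binary metrics are the default reading of the threshold procedure;
  the weighted variants are provided but σ has no weighted null.
* The paired/one-sample t-tests assume approximately normal per-subject
  values; normality flags are attached but the analysis does not switch
  to nonparametric alternatives.
* Effect sizes in the synthetic ground truth are calibration choices,
  not estimates of any empirical effect.
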