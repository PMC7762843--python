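# Methods

This note documents the models and procedures implemented in `megdecode`:
what each analysis computes, the assumptions it rests on, what the
synthetic-data generator does and does not emulate, and the numerical and
design choices that were genuinely open.

## The analysis chain

### Region-based pattern classification

The decoding unit is one subject × cortical region, represented as source
epochs `(n_vertices × n_times × n_trials)` per condition. The chain is:

1. **Windowing and downsampling.** Epochs are restricted to the
   post-stimulus analysis window (default 0–500 ms) and averaged into
   10 ms bins (51 bins by default). `PipelineConfig.downsample_ratio` is
   expressed in ms per bin at a 1 kHz reference, so data stored at any
   sampling step ends up at the same 10 ms resolution. Binning by
   averaging (not decimation) acts as a crude low-pass filter and is
   deterministic.
2. **Pseudo-trials.** The trials of each condition (75 by default) are
   randomly partitioned into `k = 10` disjoint, near-equal groups and each
   group is averaged; with 50–80 trials the groups hold 5–8 trials.
   Conditions with fewer than 50 usable trials raise `ConditionExcluded`
   and drop the subject from that per-category analysis. The partition is
   drawn once per (run seed, subject, condition) and shared across
   regions, because a recorded trial spans all regions at once.
3. **PC features.** One PCA basis per subject × region is fit on the
   pooled pseudo-trials of *all* conditions at *all* analysis bins, and
   the three leading components are kept. A single shared basis (rather
   than one per time bin) is essential: the power, angle and temporal
   generalization analyses all compare patterns across time points and
   conditions, which is meaningful only in a common space.
4. **Pairwise LDA.** For each of the 28 condition pairs and each time bin,
   a Fisher discriminant `w ∝ Σ⁻¹(μ_A − μ_B)` is trained with a small
   ridge (`10⁻⁶·tr(Σ)/d`) on the pooled covariance; the boundary sits
   midway between projected class means, ties resolving to the first
   class. Accuracy is the mean over all `k² = 100` leave-one-per-class
   train/test splits, computed by downdating the class sums so all folds
   are solved in one batched operation (a brute-force double loop serves
   as the oracle in the test suite).

### RSA and the RDM profile

The 28 pairwise accuracies form the empirical RDM. The binary model RDM
codes "high dissimilarity" (1) for every pair crossing the
recognized/unrecognized boundary — post-state objects vs nonsense (RN),
same object pre vs post (sRU), different objects pre vs post (dRU); 12
entries — and 0 elsewhere, grouping pre-state (naively unrecognizable)
objects with nonsense. Empirical and model RDMs are compared by Spearman
correlation with average ranks; coefficients are Fisher-transformed
(`atanh`, with |ρ| clipped to 1−10⁻⁶) before parametric testing.
Zero-variance empirical RDMs get ρ := 0 with a degeneracy flag and are
excluded from group tests.

Per region × time bin, the Fisher-z values are tested against zero across
subjects (two-sided one-sample t) and corrected with Benjamini–Hochberg
FDR over **all** region × bin cells of one category analysis jointly. A
window summary flags a region when at least half of the window's bins are
FDR-significant.

The 9-component profile averages RDM entries by comparison role
(dU, dR, dN, dNa, sNa, UN, RN, sRU, dRU) with entry counts
(1, 1, 2, 2, 2, 8, 8, 2, 2); low/high weighted averages use weights 16/28
and 12/28. Profile contrasts (dR−dU, dNa−dN, sNa vs chance, RN−UN,
sRU−sNa) are one-sample t-tests on per-subject contrast values.

### Power vs pattern dissociation

Two measures separate "the same process got stronger" from "the process
reorganised":

- **RMS power** of the three PC projections, per pseudo-trial and bin,
  then averaged over pseudo-trials. Projections are *uncentred* (the PCA
  mean offset is added back): power quantifies the response amplitude
  itself, whereas the RMS of centred scores would cancel exactly the
  condition-average response it is meant to measure. Window-averaged RMS
  cells (session × group) enter a repeated-measures ANOVA; a genuine power
  effect shows a session × group interaction.
- **Alpha angle** between the discriminant normals of the (pre-object vs
  session-1 nonsense) and (post-object vs session-2 nonsense) classifiers,
  per time bin, averaged over the four (object, nonsense) exemplar
  choices within subject. Orientation is preserved (no folding to ≤90°);
  both classifiers put the object class first so the angle is comparable.
  The baseline is the same computation on pre-stimulus bins, where
  discriminant directions are noise-driven and alpha is at its ~90°
  chance level.

A pure power gain leaves patterns intact: alpha drops far below baseline
in the effect window (≈40° below at the default settings), and subjects
with a larger power increase gain more decoding, so the across-subject
Spearman correlation between decoding gain (RN − UN accuracy) and power
change (post − pre RMS) is positive. A pure rotation leaves power and the
correlation at their null levels while producing a model-RDM effect.

One geometric point deserves emphasis: because the two discriminant
normals share the nonsense reference with the same sign, their expected
correlation is non-negative for any pattern rotation of ≤90°, so the
expected window alpha cannot *exceed* the ~90° baseline under this
simulator. The dissociation therefore operates on the *size of the alpha
deficit* (large under power gain, small under rotation), and the injected
rotation angle itself is recovered by the direct angle between the two
conditions' mean feature patterns (`condition_pattern_angle`), which
returns θ to within a degree at high SNR and within a few degrees at the
default SNR.

### Temporal generalization

A classifier trained on a pair of stimulus groups at train time T1 is
tested on a (possibly different) pair at every test time T2. One exemplar
per group is chosen for the training and for the testing pair; for every
group shared between the two sides, combinations re-using the same
exemplar are excluded, and results are averaged over the surviving
combinations. The delayed-component analysis always trains and tests on
*different* exemplars (both orders averaged), so generalization can only
flow through components shared across exemplars, never through
stimulus-specific patterns.

Group inference uses a sign-flip permutation test on the maximal
4-connected cluster size: cell-wise one-sample t of (accuracy − 0.5),
thresholded at the two-sided cluster-definition p (default 0.05, a
convention — the threshold itself is configurable), clusters scored by
cell count, and a null built from 10,000 (default) random whole-matrix
sign flips per subject. Clusters beating the 95th percentile of the
max-size null are significant. Sign-flipping whole matrices preserves the
within-subject correlation structure that makes neighbouring cells
dependent.

### Statistical kernel

Fisher transform, one-sample/paired t (zero-variance inputs flagged
degenerate), BH-FDR (statsmodels), and a balanced fully-within-subject
ANOVA for up to three factors with subject as random factor; each
effect's error term is its interaction with subject, sums of squares come
from inclusion–exclusion over marginal means, and no sphericity
correction is applied (two-level factors do not need one; the nine-level
profile factor is reported uncorrected). The implementation is
cross-checked against statsmodels `AnovaRM` and a hand-computed oracle in
the tests.

## The synthetic-data generator

The generator emulates the pre/post-training design at the level the
analysis consumes. Per subject × region:

- A random orthonormal basis `W` spans a low-dimensional **functional
  subspace** (`signal_dim = 3`). All stimulus patterns, rotations and
  shared components live in it, and a fraction of the noise variance
  (`latent_noise_fraction = 0.3`) does too — ongoing activity occupying
  the same components as evoked activity. This matches the analysis
  premise that three PCs carry the region's discriminative signal; with
  isotropic high-dimensional patterns the fitted basis is owned by noise
  eigendirections and pattern geometry is invisible to the analysis.
- Stimulus patterns are unit vectors clustered around a common
  evoked-response **anchor** (`pattern_spread = 0.5`, pairwise cosine
  ≈ 0.75): in the emulated effect regions, pre-training object patterns
  are nonsense-like. They **evolve smoothly over time**
  (`pattern_timescale_ms = 40`), so classifiers generalise only across
  nearby time points, as in real decoding data.
- Session 2 patterns of *every* stimulus (post-state objects and
  second-session nonsense alike) are perturbed by `session_drift = 0.2`,
  so same-stimulus decoding across sessions (sNa, and sRU absent any
  recognition effect) is slightly above chance and equal in expectation.
- Trials are `envelope × pattern + noise`, the envelope a gamma-shaped
  bump peaking at 120 ms (`shape = 2`, sustaining appreciable amplitude
  through 300 ms), the noise spatially correlated (power-law eigenvalue
  spectrum, exponent 0.5) and temporally smoothed (3-bin kernel), scaled
  so that signal RMS / noise RMS at the envelope peak equals `snr`.
- `snr = 0.4` was fixed so that pairwise decoding of distinct stimuli and
  of injected effects lands in the 0.6–0.8 band typical of source-space
  MEG decoding; this is a one-time calibration of the simulation regime,
  not a fit to any particular result.

Injected effects (per region, window, target category, with log-normal
unit-mean between-subject magnitude heterogeneity, `subject_sd = 0.6` by
default — without genuine heterogeneity an across-subject decoding–power
correlation could not exist even for a true power effect):

- `power_gain` — post-state amplitude ×(1+β) inside the window, pattern
  untouched (demo β = 0.5).
- `pattern_rotation` — post-state pattern rotated by θ degrees (exact
  per-bin Givens rotation toward a direction orthogonal to the pattern
  within the functional subspace; demo θ = 60°). Rotation preserves the
  norm, and moves the pattern away from the whole baseline cluster, which
  is what the model RDM codes.
- `delayed_shared_pattern` — one shared category-level component (a
  raised-cosine bump, amplitude 2 in the demo, an N170m-like strong
  component with moderate `subject_sd = 0.3`) added to pre-state objects
  in the window and to post-state objects in the window shifted by Δt ms
  (demo Δt = 100, window 120–200 ms).

What the generator does **not** emulate: sensor-level physics and inverse
modelling (no leakage between regions, no depth bias), physiological
artifacts, trial-to-trial latency jitter, cross-subject anatomical
alignment (patterns are re-drawn per subject, which the region-based
analysis does not need), reaction-time coupling, and any behavioural
component of the design. Passing tests therefore show that the analysis
chain recovers the *kinds* of effects it claims to dissociate under
realistic noise geometry — not that real cortical dynamics behave like
the generator.

## Numerical choices and degenerate cases

- LDA ridge `10⁻⁶·tr(Σ)/d`; decision-boundary ties go to the first class.
- Spearman ties use average ranks (the binary model makes ties
  structural); `atanh` inputs are clipped at 1−10⁻⁶.
- Degenerate (zero-variance) empirical RDMs and zero-variance t-test
  inputs are flagged rather than propagated as NaN/∞.
- Spearman p-values: exact permutation for n ≤ 8 subjects,
  t-approximation above.
- Cluster connectivity is 4-neighbour; only above-chance (positive-t)
  cells form clusters; cluster p = (1 + #{null ≥ size}) / (n_perm + 1).
- The RMS aggregation order is per-pseudo-trial RMS then mean across
  pseudo-trials (robust to across-trial pattern cancellation); alpha is
  averaged over exemplar choices within subject before the group test.

## Problem sizes

Default analyses run at the full design (16 subjects, 50 vertices, 75
trials, 51 bins). The test-suite calibration uses 200 effect-free
replicates at 4 subjects × 1 region × 16 vertices; effect recovery uses
20 replicates per scenario at 16 subjects × 1 region; the acceptance
script uses 50 null and 8 + 8 + 6 recovery replicates at the same
per-replicate geometry. These sizes give binomial confidence intervals
tight enough to distinguish nominal from broken calibration while keeping
each run in the minutes range.

## Known limitations

- With only two exemplars per category, exemplar-level generalisation
  statistics rest on two cross-pairings; the design mirrors the emulated
  experiment rather than a power-optimal simulation.
- The alpha baseline is estimated from pre-stimulus bins of the same
  epochs; slow drifts that correlate baseline and window estimates are
  not modelled.
- The within-subject ANOVA applies no sphericity correction.
- The cluster-definition threshold and 4-connectivity are conventions;
  cluster-mass and TFCE variants are out of scope.
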