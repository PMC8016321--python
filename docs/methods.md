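# Methods

`gaitprint` reproduces, end to end, a gait-individuality analysis: train a
shallow neural network to assign running stride patterns to individuals,
decompose its decisions with layer-wise relevance propagation (LRP), and
measure which movement variables and stance time points carry identity
information by re-evaluating the fixed network on relevance-ranked variable
subsets.  Because no participant data ship with the package, a synthetic
gait generator with *planted*, exactly known discriminative structure
stands in for the study population; every claim a test makes is checked
against that ground truth.

## The processing pipeline

One trial is a single running stance phase (heel strike to toe off,
detected where the vertical ground-reaction force crosses 15 N, with a
50 ms minimum-duration guard against noise spikes).  Nine joint-angle
channels (hip/knee/ankle x flexion-extension, ab-adduction, axial
rotation, from a Z-X-Y cardan decomposition of marker-cluster rotations
relative to a standing trial) and three GRF channels are:

1. lowpass filtered — zero-phase Butterworth (order 5, forward-backward,
   design cutoff pre-warped so the two-pass response is −3 dB at 15 Hz for
   angles, 50 Hz for forces);
2. time-normalized to 100 samples by shape-preserving piecewise cubic
   (PCHIP) interpolation;
3. standardized per participant: subtract the participant's average
   trajectory, divide by the participant's per-sample across-trial SD
   (ddof = 1, floored at 1e-8); statistics are computed within each day
   split;
4. rescaled per channel to [−1, 1] by the maximum absolute value over the
   split;
5. concatenated into a 1×1200 stride pattern (12 channels × 100 samples,
   fixed order; `channels.feature_index` is the public index map).

**What per-participant standardization does to identity.** Step 3 forces,
for every participant, channel and sample, the across-trial mean to 0 and
SD to 1.  All first-order identity information — everything that
distinguishes subjects by their *mean* curves, including body-size offsets
and gains — is removed exactly.  What survives is the *shape* of the
trial-to-trial fluctuations: their correlation structure across samples
and channels.  Any classifier downstream is therefore solving a
second-order problem.  Note also that normalizing test-day data by
test-day per-participant statistics presupposes that trial identity is
known at normalization time; the package reproduces this faithfully
rather than second-guessing it, and the permutation-null test shows the
pipeline itself does not leak labels into a trainable signal.

## The synthetic world

Templates are fixed smooth curves per channel (documented constants:
double-hump vertical force with a 60 N in-stance floor, braking/propulsion
anterior-posterior force, low-amplitude multiphasic frontal/transverse
curves, stylized sagittal angles).  Identity is planted only in
`planted_channels` × `planted_window` (defaults: hip ab-adduction, hip
axial rotation, knee ab-adduction, ankle in-eversion, medio-lateral GRF;
first 30% of stance), in two forms scaled by one `effect_size` knob:

* **Template offsets** — per subject and planted channel, a random
  raised-cosine bump pattern supported entirely inside the window, with
  window RMS `effect_size × noise_sigma`.  These drive the per-variable
  discriminability oracle and any between-subject analysis, but are
  *removed* by the pipeline's standardization.
* **Fluctuation signatures** — per subject, a "strategy contrast" curve
  spanning the planted channels, added to each trial with a ±1 coefficient
  (plus 0.15 Gaussian jitter).  This emulates discrete trial-to-trial
  coordination variation (e.g. strike-style alternation) and is the
  component that survives standardization: each subject's standardized
  trials form two antipodal clusters along a private direction.  The
  coefficient must be bimodal: with a zero-mean Gaussian coefficient the
  class-conditional distributions all overlap through the origin and no
  classifier can reach high per-trial accuracy.

Signature curves are built from an orthonormalized harmonic basis
(raised-cosine envelope × cosine harmonics, Gram-matrix-whitened) confined
to the window.  The harmonic count per channel matches what its lowpass
stage keeps — 2 for 15 Hz angle channels, 6 for 50 Hz force channels —
because a ~30% window of a ~0.22 s stance spans only ~70 ms and narrower
features would be filtered away.  Subject signature directions are drawn
orthonormal in the joint (channel × harmonic) coefficient space while the
subject count allows (≤ 14 for the default channels), random unit
directions beyond that.

Trial noise shared by all subjects has two components with exact
per-sample SD `noise_sigma`: 85% of the variance in a very smooth drift
(Gaussian-kernel correlation 0.15 s — slow neuromotor variability, about
one degree of freedom per stance) and 15% in a fast component (5 ms —
measurement noise).  The correlation lengths matter more than the
amplitudes: mid-range correlation (~10–40 ms) produces noise that lives in
the same smooth-function subspace as any plantable signature and was
empirically the difference between a recoverable and an unrecoverable
world.  Day 2 adds a small smooth per-subject template perturbation
(`day2_drift`, RMS 0.25 × noise SD) anywhere in stance.

Default `effect_size` is 3.0.  Reliability studies of running kinematics
report between-subject variance of frontal/transverse-plane angles several
times the within-subject trial variance (day-to-day ICCs above 0.9), so a
between/within ratio of ~3 is the realistic middle of the range; ratios
down to ~2 still support ≥ 90% identification here, ~1 does not survive
the filtering-plus-standardization pipeline at 10 subjects × 30 trials.

Raw mode (`render_raw`) turns angle channels into marker-cluster
trajectories by rotating standing-pose clusters through the chained
Z-X-Y joint rotations (pelvis fixed), and embeds the GRF channels in a
longer force record with sub-threshold padding.  The 15 N contact contract
is guaranteed by construction (stance vertical force clipped to ≥ 16 N,
padding to ≤ 14 N): the generator states the world rather than simulating
threshold-crossing physics.  The kinematics module recovers the generating
angles to ≤ 1e-6 degrees in noise-free mode, away from the gimbal-lock
zone (|middle rotation| near 90°, rejected with a diagnostic).

## Classifier

A 1200–H–C network (H = 2400 at study scale, 600 in the desk-scale world;
C = number of subjects), tanh hidden activation, linear outputs under
softmax cross-entropy, trained on all day-1 patterns with seeded
mini-batch gradient descent (batch 25, epoch limit 3000, loss-plateau
early stopping).  Accuracy is reported per participant,
`Accuracy(p) = n_p/N_p × 100`, and summarized as the *unweighted* mean
across participants.

Because the input patterns carry no class-mean signal (see above), the
loss surface at a generic small initialization is a saddle for exactly
the structure that matters: gradient descent first interpolates the
training set through the wide random-feature hidden layer and then stops
moving, generalizing at chance.  Three defaults address this, all
declared, all switchable back to the plainest variant:

* **Spectral initialization** (`init="spectral"`): part of the hidden
  layer starts as antisymmetric pairs ±v_k of the training data's leading
  principal directions (gain 1.2/√λ_k, bias +0.6).  Each pair with a
  positive bias computes an even function of the projection x·v_k — the
  magnitude detector the task needs — and the principal directions of the
  standardized training data contain the subject signature directions,
  whose eigenvalues stand clear of the fast-noise bulk.  The
  initialization uses no labels; supervised training then selects and
  sharpens the useful pairs.  `init="uniform"` gives the plain symmetric
  fan-in-scaled start (and chance-level generalization on this problem —
  preserved deliberately, as the contrast is informative).
* **Momentum 0.9** with learning rate 0.02 (plain `"sgd"` available).
* **Weight decay 1e-2.**  Besides its usual regularizing role, decay is
  what keeps the *explanation* honest here: hidden units aligned with
  strong but identity-free covariance directions (the smooth common noise,
  and the duration-dependent distortion the fixed-Hz filter imprints at
  high-curvature template regions) retain arbitrary output weights if
  nothing prunes them, and LRP then faithfully reports systematic
  relevance on variables that carry no identity.  With decay strong enough
  to actually shrink unused weights over training (lr x decay x steps of
  order 1), the aggregated relevance concentrates on the planted
  variables; at 1e-4-scale decay the shrinkage over a training run is a
  few percent and spurious relevance persists.  Day-2 accuracy also
  improves slightly (~1-2 pp).

## Relevance

For each correctly classified day-2 pattern, the predicted class's
pre-softmax score is decomposed by the ε-rule (ε = 1e-6 by default;
α-β rule available), with tanh treated as relevance-transparent.  Because
numerator and denominator of the redistribution share the same sum, the
only conservation loss is the ε stabilizer; tests hold relative leakage to
1e-6 on small networks and 1e-4 at full size.  Aggregation: normalize each
map to its own maximum, average, take absolute values, smooth each
100-sample channel independently with the (0.25, 0.5, 0.25) kernel three
times (replicate-edge padding; never across concatenation seams — the
temporal-dependence argument for smoothing does not hold across channel
boundaries), min-max rescale to [0, 1].  Three passes of that kernel equal
the 7-tap binomial kernel (1, 6, 15, 20, 15, 6, 1)/64 in the interior.

A practical caveat for interpreting relevance on this generator: the
network keys on the *fluctuation* signatures, which share the planted
window and channels with the template offsets, so planted-variable
recovery is tested against the planted index set as a whole, not against
the template bumps specifically.

## Reduction

Variables are ranked by aggregated relevance (ties broken by index,
stable).  For each k in the grid (default 16, 25, 50, 100, 200, 300, 500,
800, 1200 — anchored at the commonly quoted landmarks), day-2 patterns are
masked to the top-k variables, excluded variables set to exactly 0 — the
participant-mean value in the standardized, rescaled representation — and
re-evaluated with the *unchanged* trained network.  Retained sets are
nested by construction; k = 1200 reproduces the full evaluation
bit-identically.  Whole-channel subsets (e.g. the five planted
trajectories, 500 variables) are evaluated the same way.

## Numerical choices and degenerate inputs

* SD floor 1e-8 in standardization (zero-variance samples come out 0, with
  a log warning); all-zero channels pass rescaling unchanged, logged.
* Stance detection errors on zero or multiple qualifying contacts (strict
  mode; the protocol guarantees a single step on the plate).
* Cardan decomposition errors when |R[2,1]| ≥ 1 − 1e-9; rigid fits error
  on collinear clusters; Procrustes reflection optimum is corrected to a
  proper rotation.
* Untrained-network argmax ties break to the lowest class index.
* Circularly convolved trial noise normalizes by the folded (mod-n) kernel
  power, so the stated per-sample SD is exact even when the correlation
  length exceeds the stance length.
* All randomness flows from integer seeds through `numpy` generators;
  every generation and training path is bit-reproducible given its seed.

## What a green test establishes — and what it does not

The generator emulates the *statistical shape* of a two-day running study
(subject counts, trial counts, rates, identity concentrated in
frontal/transverse channels and early stance), not its biomechanics: no
validated gait model, no soft-tissue artifact, no intervention effects,
and an identity signal whose mathematical form (bimodal private modes) is
one stylized hypothesis about what makes real gait individual.  Green
end-to-end tests therefore establish that the pipeline, network, LRP and
ablation machinery do what they claim on a world where the answer is
known — not that real running data carry their identity signal in this
particular form.  Known limitations: at study scale (50 subjects) the
signature directions can no longer be mutually orthogonal and
identification accuracy on synthetic data degrades relative to the
10-subject desk world; and the `init="uniform"` network does not learn
this task at desk-scale sample sizes, which is a statement about the
synthetic task's difficulty, not about the study's data.
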