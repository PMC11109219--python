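# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `seqmeg`. It is the companion to the
API documentation: everything here is either implemented in the package or
asserted by its test suite; no empirical claim is made that the tests or
`scripts/acceptance.py` do not themselves compute.

## The experimental design being emulated

The package targets an old/new auditory recognition paradigm: subjects
memorise three five-tone melodies and are then presented with 135 five-tone
excerpts (five 350-ms tones, 1750 ms per sequence) while MEG is recorded.
Five conditions with 27 trials each: memorised sequences (`M`) and four
novel categories (`NT1`–`NT4`) in which every tone after the first k tones
is changed, so the first varied tone of `NTk` is tone k+1. Novel sequences
are built from the memorised ones by four symbolic variation strategies
applied per base melody and category — inverted melodic contour (×2),
scrambled tones (×3), same tone with octave shifts (×3), scrambled
intervals (×1) — operating on integer pitches; harmonic-preservation
nuances of real stimulus construction are not modelled. Epochs are 4500 ms
at 250 Hz with a 100-ms pre-stimulus baseline.

## Synthetic-data generator (`seqmeg.simulate`)

ROI-level source signals for six regions (left/right Heschl's gyrus LHG/RHG,
left/right hippocampus LHP/RHP, anterior cingulate ACC, medial cingulate MC)
are sums of Gaussian-windowed evoked deflections plus band-limited induced
bursts:

| effect | where | latency | sign/amplitude (a.u.) |
|---|---|---|---|
| N100 | LHG, RHG, every tone | 100 ms post-tone | −1.0, width 30 ms |
| onset anchor | HP/ACC/MC, first tone | 100 ms | −0.5, width 40 ms |
| recognition peak (M only) | RHG, LHP, RHP, ACC (+), MC (−) | 350 ms post-tones 2–5 | ±0.5, width 40 ms |
| prediction error (N only) | LHP, RHP, ACC (−), MC (+) | 250 ms post each varied tone | ±0.5 × (1.0, 0.55, 0.45, 0.40) over sequential varied tones |
| late N100 (N only) | LHG, RHG | 150 ms post each varied tone | −0.6, constant across varied tones |
| induced low band (N only) | all ROIs, 1.0–3.0 s | — | 2–20 Hz bursts, amplitude 0.5 |
| induced high band (M only) | all ROIs, 1.0–3.0 s | — | 30–60 Hz bursts, amplitude 0.5 |

Signals are written in the *sign-aligned* convention (first-tone response
negative everywhere); the prediction-error decay over sequential varied
tones is what the ROI ANOVAs are meant to recover, and the flat late-N100
in auditory cortex provides the corresponding null. Induced bursts have
independent random phase per trial, so they cancel from the evoked average
and survive only in per-trial power — the evoked/induced distinction the
time-frequency analysis relies on.

Between-subject structure: a multiplicative amplitude factor
(1 + 0.2·z, floored at 0.2), a per-ROI latency jitter (SD 10 ms), and a
per-subject covariate ("musical training" analogue, standard normal) that
multiplies the prediction-error amplitudes with loading 0.4 — constructed
so the population correlation between peak amplitude and covariate equals
the loading.

The forward model is a seeded Gaussian-random-field leadfield: per channel
and orientation, gains over voxels follow a squared-exponential spatial
covariance (default length 16 mm), so nearby voxels present correlated
sensor patterns as any physical forward model does. The inverse solution is
leadfield-agnostic, so a full-rank random gain exercises it; no head
geometry is modelled. ROI signals drive their member voxels through a fixed
random dipole orientation per voxel.

Noise has four components, all needed for a realistic inverse problem:
white sensor noise (SD 0.2), 1/f sensor noise (SD 0.2; spectrally shaped
white noise, exponent 1), ongoing 1/f activity in each ROI source (SD 0.3,
independent per trial) and in every background voxel (SD 0.1). The last two
matter beyond realism: noiseless, perfectly (anti)correlated ROI sources
defeat any LCMV filter (correlated-source cancellation), so ongoing source
activity is what makes the generator's output *reconstructable* at all.
The SDs were fixed once so that a 27-trial evoked average shows clear
single-subject peaks, which matches routine MEG practice.

Behaviour: per subject and condition, correct counts are binomial around
condition probabilities (M 22.33/27, NT1 22.36/27, NT2 21.58/27,
NT3 21.66/27, NT4 17.04/27) with a subject-level ability shift (SD 0.15),
and mean reaction times are normal (M 2426 ± 226 ms … NT4 2578 ± 259 ms) —
an NT4 deficit in both accuracy and speed.

What the generator does **not** emulate: artifacts (eye blinks, cardiac),
head movement, sensor-type unit differences beyond labels, realistic
anatomy, inter-trial learning dynamics, or harmonic structure of stimuli.
Passing recovery tests therefore demonstrates the *analysis chain* is
correct and calibrated, not that it would behave identically on raw MEG.

## Beamformer (`seqmeg.beamformer`)

Sensor data follow B(t) = L·Q(t) + ε. The sensor covariance C is computed
on the trial-concatenated data of *all* conditions (one filter per subject,
applied to every condition) with 5% diagonal loading by default. The three
dipole orientations are reduced to one by the SVD of (lᵀC⁻¹l)⁻¹, i.e. the
orientation maximising the unit-gain-constrained output power — the
standard scalar-beamformer choice; a Moore–Penrose pseudo-inverse covers
gains spanning fewer than three directions. Weights are
W_q = (L_qᵀC⁻¹L_q)⁻¹L_qᵀC⁻¹ (unit gain W_q·L_q = 1 by construction), then
Euclidean-normalised per row to counter the depth bias of the unnormalised
activity index. Evoked series are computed per condition from trial
averages; induced series keep single trials. The beamformer sign ambiguity
is resolved per source by flipping so the mean over the first-tone N100
window (70–130 ms) is negative; the same flip applies to all conditions.
Magnetometer-only reconstruction is the default on mixed-sensor data, with
a switch to use all channels (the synthetic tests use homogeneous arrays).

## Decoding (`seqmeg.decoding`)

Pairwise condition decoding per time point with a linear SVM (C = 1 —
fixed because activation patterns are only defined for linear models and
C has little effect at these trial counts), 5-fold leave-one-group-out
cross-validation repeated 100 times with reshuffled stratified fold
assignments. Features are standardized per time point with training-fold
statistics only. Classifier weights w are converted to activation patterns
via the training-data covariance, pattern = Σ_X·w, which is the
physiologically interpretable quantity. Temporal generalization trains at
each time point and tests at all others, applying the train-time scaler to
the test data. Group significance against the 50% chance level uses a
one-sided Wilcoxon signed-rank across subjects per entry; the accuracy
time series is FDR-corrected, the generalization matrix 2D
cluster-corrected.

## Cluster statistics (`seqmeg.stats`)

`fdr_bh` is Benjamini–Hochberg step-up (statsmodels). Cluster machinery:
p-value maps are binarized at α = 0.05; maximal runs (1D) or 4-connected
components (2D; 8-connectivity available) form clusters, split by the sign
of the statistic; a cluster is significant if its size exceeds the
(1 − mcs_p) quantile (mcs_p = 0.001) of the permutation distribution of
maximum cluster sizes over 1000 permutations. Cluster *size* is the
default extent measure; mass is available.

Two null-generation modes exist and the difference matters:

* `permute_labels` (default of `mcs_correct`): the permuter regenerates the
  statistic map under subject-level condition flips (or trial-label
  shuffles). Exact under exchangeability — this is the mode whose
  family-wise error the acceptance suite verifies.
* `permute_map`: the binarized map's entries are themselves shuffled. This
  destroys autocorrelation and is anticonservative for smooth maps, but at
  small n it is the only workable choice at extreme mcs_p: with 20
  subjects, the 99.9th percentile of the sign-flip null is dominated by
  near-identity flips that mirror a strong true effect, so the threshold
  converges on the true cluster's own size and label permutation can never
  detect it. The pipeline's 1D ROI and 2D time-frequency contrasts
  therefore use `permute_map`, and its anticonservatism should be kept in
  mind when interpreting borderline clusters.

Group tests: Kruskal–Wallis with mid-rank tie correction, Tukey–Kramer
studentized-range post-hocs (valid for unequal n), and fixed-effects
one-way ANOVA with dof (k−1, N−k); the F test is inherently upper-tailed.
Degenerate zero-variance contrasts map to the smallest positive p-value
rather than 0/NaN.

## ROI analysis (`seqmeg.roi`)

Channel selection keeps channels whose decoding-pattern magnitude strictly
exceeds mean + 1 sample SD, computed per channel type; selected channels
are split by first-tone N100 polarity before averaging (the same neural
source projects with both magnetic polarities, so unsigned averaging
cancels). Parcel aggregation is the unweighted mean of member-voxel series.
Source-leakage correction is symmetric multivariate orthogonalization: the
closest (Frobenius) set of mutually orthogonal series, computed by
alternating a polar decomposition with optimal per-column scales; output
zero-lag correlations are exactly zero and already-orthogonal input is a
fixed point. Orthogonalization is applied after aggregation, never before.

Peaks are extracted per tone 2–5 (tone 1 is condition-invariant) as
argmax/argmin in a 400-ms post-onset window (ties → earliest sample), with
amplitudes averaged over ±20 ms. Source contrasts use window-averaged
|activity| with voxelwise paired t-tests and FDR; ROI time-series contrasts
use signed series. Prediction-error ANOVAs take windowed amplitudes at
150 ms (HG) or 250 ms (HP/ACC/MC) after each varied tone: 6 ROIs ×
{NT1 (4 peaks), NT2 (3), NT3 (2)} = 18 one-way ANOVAs, FDR-corrected, with
Tukey–Kramer post-hocs. Covariate correlations are Pearson r of |peak
amplitude| against the per-subject covariate, FDR-corrected per family.

## Time-frequency (`seqmeg.timefreq`)

Complex Morlet wavelets, 1–60 Hz in 1-Hz steps, n_cycles = max(f/2, 3),
L2-normalised, convolved with mirror padding; samples within half a wavelet
of the edge are flagged. Power is the squared modulus, computed per trial
(induced), baseline-corrected by subtracting the per-frequency mean
pre-stimulus power, then trial-averaged. Condition contrasts are paired
t-maps over time × frequency with 2D cluster MCS. Power units are
arbitrary; no fT² calibration is attempted.

## Network model comparison (`seqmeg.bms`)

Six directed architectures over the six ROIs are compared on 350-ms
per-tone windows of the sign-aligned evoked ROI series (memorised: tones
2–5; each novel condition: its first varied tone — 8 analyses). The
generative model is a linear state-space surrogate x' = A(θ)x + c·drive
with A's off-diagonal support restricted to each architecture's
feedforward/feedback edges, a negative self-decay diagonal, and stimulus
drive (Gaussian bump, peak 60 ms, SD 25 ms) entering LHG and RHG. This
surrogate deliberately replaces a neural-mass cortical-microcircuit
integrator: the scientifically testable object at this scale is the
*architecture comparison*, and the surrogate keeps every architecture
distinguishable while admitting an exact Gaussian treatment. No attempt is
made to match any external toolbox's absolute free energies — only model
rankings are meaningful.

Fitting regresses the Savitzky–Golay-smoothed temporal derivative (window
11 samples, order 3 — naive differencing amplifies noise by the sampling
rate; too-wide smoothing biases the drive transient, which is why the
drive bump is 25 ms wide) on the node states and the drive, under Gaussian
priors: edges N(0, 1), self-decay N(−5 s⁻¹, 1), input gain N(0, 30²).
Observation noise is estimated by evidence maximisation. Because the model
is linear in θ, the Laplace posterior is exact and the variational free
energy has closed form, F = accuracy − complexity with
complexity = KL(posterior ‖ prior) ≥ 0; the identity holds to 1e-8 on
every fit by construction and is asserted in tests.

Random-effects model selection runs the variational Dirichlet scheme over
model frequencies (uniform Dirichlet(1) prior), yielding expected posterior
model probabilities; exceedance probabilities come from 10⁶ seeded
Dirichlet draws; the Bayesian omnibus risk (BOR) compares the free energy
of the random-effects model against the null in which all model
frequencies are exactly equal, BOR = 1/(1 + exp(F1 − F0)); protected
exceedance probabilities are PXP = EP·(1 − BOR) + BOR/K. All outputs are
invariant to adding a constant to every evidence entry.

The generator's dynamics defaults (forward 2 s⁻¹, backward 1 s⁻¹,
self-decay −6 s⁻¹, diagonal-dominant hence stable for every architecture
under 10% subject jitter) sit inside the prior-plausible regime; with
weights far outside the priors, every architecture shrinks to the prior
and the comparison degenerates — a real limitation of fixed priors that
applies equally to the full-scale method. Models 1 and 2 (reciprocal vs
feedforward-only) can confuse when the backward gain is very low relative
to observation noise; at the defaults the model-recovery suite selects the
generating architecture for all six generators.

## Problem sizes and error control

The recovery suites run at desk scale, chosen as the smallest problems
where the claims are statistically meaningful rather than as upper limits:
cohorts of 20 subjects, 60 sensors, a 100-voxel grid at 12-mm spacing
(5 replicate cohorts for the detection-power claim), 10-subject nulls for
chance calibration, 500 null datasets for FDR/FWER control, and 100 seeded
runs for dipole recovery. The MC (medial cingulate) effect is the
leakage-limited one: below ~60 channels its anticorrelated ACC neighbour
cancels it in reconstruction.

## Known limitations

* The leadfield is statistically, not physically, realistic; depth bias
  and sensor-type physics are only schematically present.
* `permute_map` cluster correction is anticonservative for smooth maps
  (see above); the exact sign-flip mode is the default for new analyses.
* The linear network surrogate cannot capture nonlinear neural-mass
  phenomena (resonance, gain modulation); architecture recovery results
  transfer to such models only qualitatively.
* Free energies are comparable across models within a window, not across
  windows or subjects with different noise estimates.
* The symbolic stimulus model ignores acoustics entirely; no audio or MIDI
  is produced.
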