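# Methods

This package analyses sensorimotor EEG around a cued motor protocol with
four conditions — real movement (RM), kinesthetic motor imagery (MI),
imagery with a median-nerve stimulation delivered 750 ms after the go cue
(MI+MNS), and stimulation at rest (MNS) — and asks whether the
stimulation-locked responses, altered by a concurrent intention to move,
support a better binary classification (MI+MNS vs MNS) than the classical
imagery-vs-rest contrast.  Because no public recordings accompany this
protocol, a synthetic cohort generator provides ground-truth data for every
stage; all quantitative claims the tests make are claims about that
generator.

## Synthetic cohort model

Each subject is simulated as two band-limited stochastic sources — a mu
rhythm (7–13 Hz) and a beta rhythm (15–30 Hz), obtained by zero-phase
band-pass filtering white Gaussian noise — placed over a C3-centred left
sensorimotor patch and mixed into a 16-channel motor-centred montage through
a Gaussian spatial gain map (σ = 0.35 in schematic head coordinates).  A
weaker mirror source centred on C4 carries only the stimulation-locked
responses, giving the bilateral topography expected for stimulation
rebounds.  Broadband white noise (3 µV rms per channel) and one EMG lead
(quiet except during real movements or injected contamination) complete the
model.

Condition effects are power envelopes g(t) (1 = baseline) applied to the
sources as amplitude × √g(t), so a band-power statistic recovers the
configured percentages in expectation:

* **MI** — sustained ERD of depth −15% from 0.3 to 3.2 s (both bands).
* **RM** — beta ERD interrupted by a mid-task ERS (+10%), a second ERD,
  then a post-movement beta rebound; the mu ERD is continuous.
* **MNS** — post-stimulation rebound (PSR, +50% power) for 250 ms after the
  pulse, a stimulation ERD (−15%) from 250 to 750 ms post-pulse, then a
  beta rebound (+30%, half that in mu) to 2.25 s post-pulse.
* **MI+MNS** — the product of the MI envelope and the stimulation envelope
  with the PSR scaled by (1 − psr_abolition), default abolition 0.9, and
  the beta rebound scaled by (1 − rebound_attenuation), default 0.5, times
  a post-task rebound peaking near 4.5 s (+33% in beta).

Multiplicative composition means the stimulation ERD briefly deepens the
ongoing imagery ERD where the two overlap (0.85 × 0.85 ≈ 0.72); the
alternative (clipping to the deeper of the two) was rejected as it breaks
the parameter-off identity that with zero abolition and attenuation the
MI+MNS envelope factorises exactly into MI × MNS.  Envelope transitions are
150 ms raised cosines (80 ms for the fast stimulation transients); the
protocol literature gives onset latencies, not shapes.

Effect sizes with a stated literature value (−15% ERD depth, +33% post-task
rebound, ~90% PSR abolition) use it; the remaining magnitudes (+50% PSR,
+30% rebound, 0.5 attenuation) and the source/noise amplitudes (6 µV rms
mu, 4 µV rms beta at the peak channel, 3 µV rms noise) were fixed once at
values typical of closed-eye sensorimotor EEG.  Trials are 8 ± 1 s
(uniform on [7, 9] s), 52 per condition, grouped into per-condition runs of
at most 26 trials in randomized order with a 15 s lead-in.  Generation runs
at 512 Hz by default so the resampling stage is still exercised; cohort
subjects get multiplicative log-normal jitter on effects (σ = 0.2) and
amplitudes (σ = 0.15) and additive jitter on the abolition/attenuation
fractions (σ = 0.05), with per-subject seeds derived from a master seed.

**What the generator does not emulate:** volume conduction from a
biophysical head model, somatosensory evoked potentials (only an optional
1-sample stimulation spike), eye/movement artifacts beyond the EMG bursts,
non-stationary background rhythms, or inter-subject montage differences.
Passing tests therefore demonstrate that the pipeline recovers effects of
the modelled kind at realistic SNR — not that real recordings would yield
the same accuracies.

## Preprocessing

Common average reference over the EEG leads (the EMG lead never enters the
average), polyphase anti-aliased resampling to 128 Hz, and 9 s epochs from
2 s before to 7 s after the go cue (half-open windows; sample 0 at the
window start, t = 0 at the cue).  Band-pass filters are Butterworth applied
forward–backward: zero phase preserves ERD/ERS latencies at the cost of a
doubled effective order, which is accepted and documented.  Classification
epochs use a wider [−3, 7] s window because the rest window of the
imagery-vs-rest paradigm starts 3 s before the cue.

Trial rejection applies two rules.  EMG: an imagery-family trial (MI,
MI+MNS) is dropped when its task-window EMG rms exceeds 3× its rest-window
rms — real movements are expected to produce EMG and are exempt.  Outlier:
a trial is dropped when its 250 ms-smoothed 8–30 Hz power trajectory
(averaged over EEG channels) stays outside the same-condition mean ± 2.5 SD
envelope for more than 1.0 s.  The sustained-excursion duration is the free
constant of this rule; 1.0 s keeps the false-alarm rate on clean synthetic
runs below 0.1% while still catching whole-trial amplitude outliers.
Survivors' samples are never modified, and only survivors reach any
downstream average.

## ERD/ERS quantification

The band-power method: square the band-passed samples, average across
trials, smooth with a 250 ms window sliding in 100 ms steps (centred
windows, truncated at the epoch edges), and normalize by the mean power of
the 1.5 s baseline starting 2 s before the cue:
ERD/ERS% = (P(t) − P_bl)/P_bl × 100.  Squaring before averaging (rather
than normalizing each trial first) is the default; a per-trial
"percentage" estimator is available behind a switch for comparison.  Band
presets are mu 7–13 Hz, beta 15–30 Hz, mu+beta 8–30 Hz; an alternative
8–12 Hz mu convention appears in parts of the literature and is selectable
but not the default.  Grand averages across subjects are pointwise means of
baseline-normalized curves.

A practical caveat for narrow bands: the mean band power in a 250 ms window
has roughly 2·B·T·n_trials degrees of freedom, so a 52-trial mu curve has
~11% pointwise relative noise.  Point estimates of ERD depth should
therefore be window means (or cohort grand averages), not single-trial or
single-point values; the recovery tests use the plateau mean and the
grand-average trough accordingly.

## Time–frequency analysis

ERSP maps use a 256-sample Hann window, 4× zero padding (0.125 Hz bin
spacing at 128 Hz), a quarter-window hop, and the 8–35 Hz range; values are
10·log10 of trial-averaged power over the mean baseline spectrum (divisive
dB baseline).  Significance uses a surrogate permutation test — labels
exchanged between the two conditions' trial pools (a paired sign-flip
variant is available for within-subject contrasts), two-tailed, with
p = (r+1)/(n_perm+1) so the smallest attainable p is 1/(n_perm+1) — and
Benjamini–Hochberg FDR across channels within each time frame for the
band topographies.

## Classification

Windows: imagery/movement task [0.5, 3.0) s after the cue vs the same
trials' rest segment [−3.0, −0.5) s (2.5 s each); stimulation pair
[−0.5, 2.5) s around the pulse for both MI+MNS and MNS trials (3 s).
Signals are band-passed 8–30 Hz with a 5th-order zero-phase Butterworth
filter; the EMG lead is excluded.  Four methods are compared: CSP+LDA
(log-variance features of the first and last 4 common-spatial-pattern
filters from the generalized eigenproblem C₁w = λ(C₁+C₂)w), MDM (minimum
affine-invariant distance to per-class Riemannian means), CSP+MDM (MDM on
CSP-filtered signals), and TS+LR (tangent-space projection at the
Riemannian barycenter of the training covariances followed by an
L2-regularized logistic head — the literature's "linear regression
classifier" is ambiguous, so an ordinary least-squares head thresholded at
0.5 is provided as an option).  Trial covariances are shrunk 1% toward a
scaled identity by default; shrinkage breaks exact affine invariance, so
the invariance tests set it to zero.

Evaluation is stratified 4-fold cross-validation with seeded fold
assignment; CSP filters, class means and the tangent reference are fitted
inside training folds only.  The Fréchet mean uses the standard fixed-point
iteration from the arithmetic mean with tolerance 1e-8; convergence is
linear and can be slow for high-dispersion sets, so the iteration cap is
200 with a hard error beyond it.  MDM ties (within numerical noise) go to
the lowest class index; CSP eigenvector signs are fixed by making the
largest-magnitude coefficient positive; band selection ties go to the
widest band.  The cross-subject comparison of paradigms uses a two-sided
paired t-test on per-subject accuracies and is undefined (an error) for
zero-variance differences.

## Problem sizes

The default pipeline runs 16 subjects × 52 trials × 4 conditions at 512 Hz
generation / 128 Hz analysis, which completes in a couple of minutes on one
core; the test suite uses the same sizes for the cohort-level checks and
smaller constructed inputs elsewhere.  Permutation counts default to 2,000
for analyses and are reduced (with coarser maps) in the calibration tests,
which assess rates against their own empirical standard errors.

## Known limitations

The generator's rank-two spatial structure (one patch per hemisphere per
band) makes spatial filtering easier than on real 128-channel EEG; absolute
accuracies are therefore not comparable to published values, only orderings
and calibration properties are meaningful.  EDF files can be imported (via
mne) but not written — the internal compressed trial store is the exchange
format.  No Laplacian/mastoid re-referencing, ICA, bad-channel
interpolation, cluster-based correction, or source localization is
provided.
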