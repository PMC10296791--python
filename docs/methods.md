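# Methods

`cardioresp` detects sleep respiratory events from cardiopulmonary signals
in three stages: (1) a three-class segment classifier separates normal
breathing, hypopnea and apnea on 10-s windows using airflow morphology,
heart-rate-variability (HRV), entropy and cardiopulmonary-coupling (CPC)
features; (2) apnea windows are subtyped into obstructive vs. central by a
recurrent sequence classifier reading a one-dimensional fusion of the
ribcage and abdomen effort leads; (3) per-segment predictions are merged
into events and summarized as an apnea–hypopnea index (AHI) with a clinical
severity grade. A synthetic polysomnography (PSG) generator provides
annotated recordings with the statistical structure each stage relies on,
so the whole pipeline is testable without clinical data.

## Signal model and preprocessing

Inputs are an ECG channel (128 Hz nominal) and oronasal airflow, ribcage
and abdomen effort channels (8 Hz nominal). Airflow is cleaned with a
zero-phase low-pass Butterworth filter, cutoff 0.3 Hz, order 4 (the order
is a config knob; zero-phase application is chosen so event morphology is
not phase-distorted, at the cost of squaring the magnitude response). ECG
baseline wander is removed by subtracting a baseline estimated with a
cascade of median filters (200 ms, then 600 ms): the short window erases
QRS complexes, the long one T waves, leaving the wander. Records are cut
into non-overlapping 10-s windows; a window inherits the label of an
annotated event covering more than half of it (annotations are half-open
intervals and non-overlapping, so the majority label is unique). A dense
schedule — 10-s windows with 90 % overlap — is used only when harvesting
obstructive/central training windows, where labelled data are scarce.

One consequence of the 0.3-Hz cleanup worth knowing: at a typical 15
breaths/min (0.25 Hz) the filter removes the harmonics that carry the
inspiration/expiration asymmetry, so the inspiratory duty cycle measured
on *filtered* flow trends toward 0.5 regardless of the true asymmetry.
Duty-cycle recovery is therefore verified on unfiltered band-limited flow;
in the classifier the feature still discriminates because apneic and
hypopneic windows alter it through amplitude, not shape.

## Features

**Airflow morphology.** Breaths are segmented by zero crossings of the
mean-removed flow; half-waves shorter than 0.5 s or with peaks below 5 %
of a record-level amplitude reference are treated as noise. The reference
is record-level deliberately: inside an apnea the window's own maximum is
noise, and a window-relative threshold would hallucinate breaths there.
Per breath: respiratory frequency RF = 1/cycle, inspiratory duty cycle
IDC = t_insp/cycle, slope = inspiratory volume / inspiratory time, plus
inspiratory/expiratory "volumes" (integrals of |flow|, arbitrary units —
no volumetric calibration) and signed areas. A window averages the
features of its breaths; a breathless window gets the all-zero apnea
signature.

**HRV.** R peaks come from the Pan–Tompkins cascade (5–15 Hz band-pass,
derivative, squaring, 150-ms moving-window integration, adaptive dual
thresholds with search-back, 200-ms refractory period), refined to the
band-passed R wave. Time-domain features: NN50 (successive differences
> 50 ms), pNN50 with the **total RR-interval count** as denominator (a
deliberate convention of this pipeline; the common convention divides by
the number of differences), RMSD, mean absolute deviation, coefficient of
variation, triangular index with 1/128-s bins (the tick of a 128-Hz ECG
clock), and serial correlation coefficients at lags 1–3. Frequency-domain
features: the RR tachogram is cubic-spline resampled to 4 Hz, mean-removed
and Welch-estimated; band powers are bin sums over VLF 0.0033–0.04, LF
0.04–0.15, HF 0.15–0.4 and TP 0–0.4 Hz, so VLF + LF + HF = TP exactly and
LF_norm + HF_norm = 1 with the VLF-free denominator. Poincaré SD1/SD2 use
the rotation closed forms sd1 = √(var(Δ)/2), sd2 = √(var(Σ)/2). A 10-s
window holds only a dozen beats, far too few for spectral estimates, so
all beat-based features are computed on a context window (window ± 25 s by
default, configurable down to 0) labelled by the centre window.

**Entropies** (natural log; nats). Shannon, Rényi (α = 2) and Tsallis
(q = 2) entropies on a 10-bin equal-width histogram of the RR series;
transfer entropy TE(EDR → RR) — respiration-to-heart direction — with
3-symbol quantile coding and lag 1 (series already taking ≤ 3 discrete
values keep their own alphabet, which makes the plug-in estimator exact on
symbolic inputs); Shannon entropy of the horizontal-visibility-graph
degree distribution (strict-inequality visibility, so ties block edges and
a constant series yields a path graph); and an alphabet entropy over
words (length 3) of sign-of-difference symbols {−, 0, +} with a dead band
of 0.1 × SD of the differences. All bin counts, orders and lengths are
package defaults exposed in `EntropyConfig`, not facts about any external
reference definition.

**Cardiopulmonary coupling.** The ECG-derived respiration (EDR) is the
per-beat QRS slope range: max − min of the ECG first derivative in a
±50 ms window around each R wave (beats clipped by a record edge are
dropped and counted). Both the RR and EDR beat series are cubic-spline
resampled to 4 Hz and their coupling spectrum computed as
CPC(ω) = C_xy(ω)·|S_xy(ω)|², with C_xy the coherence *coefficient* (square
root of the magnitude-squared coherence) and S_xy the Welch cross
spectrum (128-sample Hann windows, 50 % overlap). The composition is
implemented exactly as written; the classical C²·|S| variant is available
behind `variant="coh2_cross"`. Band features integrate CPC over
0.01–0.1 Hz (LF) and 0.1–0.4 Hz (HF); the band edges follow common CPC
practice and are config knobs.

## Two-lead fusion and apnea subtyping

The simultaneously sampled effort leads form a planar trajectory
p_i = (ribcage_i, abdomen_i). For each i, the fusion sample is
d_i = min_{|j−i| > w} ‖p_i − p_j‖ — the Euclidean distance to the closest
other state point, computed by exact brute force (an optional
Theiler-style exclusion window w, default 0, widens the self-exclusion).
The search runs within each 10-s window, the training unit.

During obstructive apnea the belts keep moving (the generator also gives
them paradoxical rib/abdomen phase opposition); during central apnea both
leads collapse to sensor noise. Unnormalized, this makes the mean fusion
amplitude of obstructive windows reliably exceed central ones. Per-window
z-scoring (the default, because effort-belt gains are arbitrary) erases
that amplitude information, and the contrast *reverses*: the z-scored
obstructive trajectory is a smooth curve whose nearest neighbours are
close, while z-scored central noise scatters into a cloud with larger
nearest-neighbour distances. Either way the two classes separate sharply;
the directional "obstructive > central" reading holds for unnormalized
fusion only, and the tests check it there.

The subtype classifier is a compact LSTM implemented directly in NumPy
(one layer, 32 hidden units by default, sigmoid read-out, full
backpropagation through time, Adam at 1e-2, early stopping on validation
loss with patience 30). At this scale — 80-sample sequences, a few hundred
training windows — it trains in seconds on one CPU, and its gradients are
verified against finite differences in the test suite. The operating
cutoff is chosen on the validation ROC by Youden's J.

## Classifiers, selection, attribution

The three-class stage offers decision trees, random forests and
gradient-boosted trees (XGBoost; 200 trees, depth 4, learning rate 0.1 by
default), trained with inverse-frequency sample weights because apneic
windows are rare in realistic recordings. Feature screening is a
Kruskal–Wallis test per feature across the three classes with
Benjamini–Hochberg control at α = 0.05; constant features get p = 1. The
statistic ordering is retained for top-k experiments. Attribution for the
boosted trees uses the booster's built-in TreeSHAP contributions, which
are exact for trees and satisfy the efficiency property (attributions plus
bias sum to the margin); non-tree models fall back to permutation
importance with a warning. Splits are stratified-random by default;
subject-wise splitting is available and recommended when cohorts are large
enough, and is asserted never to leak a subject.

## AHI reporting

Maximal runs of abnormal window labels merge into one event of the
majority type (ties go to apnea); runs shorter than the clinical 10-s
minimum are discarded; overlapping-window predictions are first reduced to
per-second majority labels. AHI = events/hour over *total recording time*
(no sleep staging is in scope, so the denominator is biased high and the
AHI correspondingly low relative to a staged montage). Severity uses the
half-open clinical bands: none < 5 ≤ mild < 15 ≤ moderate < 30 ≤ severe.
Cohort screening dichotomizes predicted and true AHI at 5, 15 or 30
events/h and reports precision/sensitivity/F1/accuracy.

## Synthetic generator

The generator emulates exactly the structure the pipeline exploits, with
every magnitude a parameter rather than a physiological claim:

* ECG from a five-Gaussian P-QRS-T template at R times driven by an RR
  process: baseline 60/HR with respiratory sinus arrhythmia (gain 0.04 at
  the breath rate), 10-ms white beat-to-beat jitter, RR lengthening by
  10 % during apnea with a 10 % rebound shortening for 15 s after (half
  those gains for hypopnea), and respiratory amplitude modulation of the
  QRS (gain 0.15) so an EDR is recoverable.
* Airflow as an asymmetric breath (inspiration 40 % of the 4-s cycle, at
  15 breaths/min) whose envelope drops to 1.5 % of baseline during apnea
  and 50 % during hypopnea. Envelope ramps live in the 0.5 s *outside*
  each annotated window so in-window amplitude contracts hold exactly.
* Effort leads that persist at 70 % with rib/abdomen phase opposition
  during obstructive apnea and collapse to 5 % during central apnea.
* White Gaussian channel noise (SD 0.01 on ECG, 0.02 on the 8-Hz
  channels). No powerline, motion artifacts, arousals or SpO2.

The apnea airflow floor (1.5 %) is set comfortably below the 5 %
breath-detection threshold; clinically an apnea only requires a ≥ 90 %
amplitude reduction, and the generator realizes a deep one so that the
"no breaths detected" signature is unambiguous. Cohorts derive per-subject
seeds deterministically from a master seed and place round(target × hours)
events with ≥ 20 s of quiet breathing between them, so the annotated rate
lands within ±0.5 events/h of each subject's target.

What passing on this generator does **not** show: robustness to ectopic
beats, electrode artifacts, sensor drift, positional changes, mixed
apneas, or the inter-subject variability of real PSG. The synthetic
cohort's class differences are cleaner than clinical ones, so held-out
scores here are upper bounds on, not estimates of, real-data performance.

## Numerical choices and degenerate inputs

Features that are undefined on a window (too few beats, zero variance,
empty HF band) are NaN-flagged, not raised; the boosted trees consume NaN
natively and other estimators impute the training median. Flat signals
yield an empty RR series (with a warning), zero transfer entropy, an
all-zero CPC spectrum, and the normalization-free fusion fallback. EDF
and WFDB round trips are exact to one 16-bit quantization step; the EDF
writer digitizes against the physical range as printed in its own 8-char
header field so the round trip cannot drift. Fusion nearest-neighbour
distances are brute-force exact (any accelerated search must match them
bit-for-bit). Problem sizes in the tests and acceptance script — an
8-subject, 20-minute-per-record cohort, 80-sample fused windows, an LSTM
of 16 units — were chosen so the full pipeline re-runs from scratch in
well under a minute on one CPU while leaving every stage's contract
observable.

## Known limitations

* AHI uses recording hours, not sleep hours.
* Mixed apnea is annotated in the I/O vocabulary but never classified.
* The dense-overlap subtype harvest assumes effort leads share one
  sampling rate.
* Per-window frequency features at the default ±25 s context have no
  meaningful VLF resolution; the VLF band is reported for completeness.
* The alphabet-entropy and visibility-graph constructions are this
  package's documented definitions; other packages' estimators with the
  same names may differ.
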