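# Methods

## Signal chain

Referential EEG (10–20 electrodes Fp1, Fp2, F3, F4, C3, C4, T3, T4, O1, O2;
256 Hz; microvolts) is band-passed 0.3–70 Hz with a zero-phase FIR filter
(Hamming-window design, centred FFT convolution of the symmetric kernel, so
no group delay distorts spindle timing; recordings at other rates are
resampled to 256 Hz first). The analysis montage is ten bipolar
derivations in five homologous pairs:

| region | left | right |
|---|---|---|
| fronto-central (FC) | Fp1-C3 | Fp2-C4 |
| fronto-temporal (FT) | Fp1-T3 | Fp2-T4 |
| centro-temporal (CT) | C3-T3 | C4-T4 |
| centro-occipital (CO) | C3-O1 | C4-O2 |
| temporo-occipital (TO) | T3-O1 | T4-O2 |

The centro-temporal derivations are synthesized from the referential
channels (equivalently (C3-O1) − (T3-O1)); the region → derivation map is
configurable because the centro-temporal source is a montage choice, not a
recording property. N2 sleep is taken from annotations (EDF+ or sidecar
CSV); segments are merged, sliced sample-wise, and a per-sample map back to
original recording time is kept so event onsets are reported in recording
time. Subjects with under 300 s of N2 are excluded (eligibility rule), and
detected runs that span a concatenation discontinuity are discarded.

## Spindle detector

Per derivation, over the subject's whole N2 data:

* sigma filter 11–15 Hz (zero-phase FIR, 1.5 Hz transition);
* envelope = |analytic signal| smoothed by a 0.2 s moving average;
* threshold = max(mean + 2 SD of that derivation's envelope, 5 µV);
* supra-threshold runs separated by < 0.25 s merge; runs must last 0.5–3 s.

The threshold is computed **per derivation**, never pooled across
hemispheres: pooling would raise the effective threshold on the
low-amplitude (lesioned) side, selectively discard its weakest spindles,
and bias the asymmetry ratio toward symmetry.

Each event's oscillation frequency is the peak of a Hann-tapered spectrum
of the whole event, zero-padded to 0.25 Hz bin spacing and refined by
log-parabolic interpolation; exact ties resolve to the lower frequency, and
13.0 Hz sits in the fast band (slow = [11, 13), fast = [13, 15]). Mean
event power is the mean squared sigma-filtered signal over the event
(A²/2 for a pure sinusoid of amplitude A). Band-wise regional power is the
mean of event powers over that derivation's events in the band — i.e.
powers are averaged per event and then across events, not pooled over
concatenated samples (the alternative weights long events more; both are
defensible, per-event averaging is the default).

**Source assignment.** Bipolar derivations share electrodes, so one focal
spindle necessarily leaves attenuated copies on electrode-sharing
derivations of the same hemisphere — with five derivations on four
electrodes per hemisphere the montage graph contains cycles, and no scalp
source can excite exactly one derivation. A detected event whose peak
envelope is below 0.7× that of a temporally overlapping event on another
same-hemisphere derivation is therefore treated as a volume-conducted copy
and discarded. The 0.7 ratio sits midway between the exact ½ amplitude a
pair-injected copy carries and 1.0 (two genuinely co-occurring spindles);
the step can be disabled (`source_assignment_ratio=None`).

## SPA indexes

SPA(region, band) = mean event power over the lesioned-hemisphere
derivation ÷ mean event power over the homologous non-lesioned derivation.
The lesion side comes from metadata; defining the ratio on the
lesioned/non-lesioned axis (not left/right) makes injury-associated
asymmetry < 1 regardless of side. Missing values (no events in a band, or
an excluded bad channel) carry a reason code and propagate as missing into
the statistics (pairwise deletion per index; listwise deletion inside the
logistic selection). Five regions × three bands = 15 indexes per subject.

## Statistics

* **Shapiro–Wilk** (valid 3 ≤ n ≤ 50) is computed per index as a logged
  justification for nonparametric tests; nothing branches on it.
* **Mann–Whitney U** uses mid-ranks for ties and reports U = min(U₁, U₂).
  The two-tailed p is exact — full enumeration of group-label assignments —
  whenever C(n, n₁) ≤ 20 000 (covers every case with n₁, n₂ ≤ 6), and
  otherwise the tie-corrected normal approximation without continuity
  correction, matching the asymptotic p of standard clinical software at
  the 13-vs-27 cohort size. The exact two-sided p is defined as
  P(|U − n₁n₂/2| ≥ |U_obs − n₁n₂/2|) under the permutation null.
* **No multiple-testing correction** is applied across the 15 indexes in
  the primary report (raw p-values are the decision inputs), but a
  clearly separated Holm-adjusted column is printed for transparency.
* **Forward stepwise logistic regression**: starting from the constant
  model, the candidate with the smallest Rao score-test p (1 df) enters if
  ≤ 0.05; after each entry every included predictor is re-tested with a
  likelihood-ratio test and removed if p ≥ 0.1, iterating to convergence
  with a visited-model guard. The conditional-estimates removal statistic
  of legacy stepwise implementations is an approximation to this LR
  statistic; the exact LR test is used here. Complete separation (frequent
  at n = 40 with a strong biomarker) is detected via non-convergence or
  runaway coefficients and handled by a lightly ridge-penalized fit
  (C = 10³), always flagged in the result.
* **Nagelkerke R²** = Cox–Snell R² rescaled by its maximum.
* **AUC** by pair counting with ties at ½, oriented so lower SPA predicts
  UCP; SE by the Hanley–McNeil formula, 95% CI normal and clipped to
  [0, 1].
* **Cut-off diagnostics** at SPA = 0.65 predict UCP iff SPA < 0.65
  (boundary → typical) and report the 2×2 table with sensitivity,
  specificity, PPV, NPV.
* **Grubbs test** (two-sided α = 0.05): G = max|x − x̄|/s against the
  t-based critical value; one outlier per call, iterative re-testing
  available.

## Synthetic cohorts

The generator emulates exactly what the pipeline consumes: 10 referential
channels of Gaussian 1/f^1.5 background (15 µV RMS; spectrum shaped in the
frequency domain, rescaled to the target RMS) with Tukey(0.5)-tapered
sinusoidal bursts. Defaults: 3 events/min per region, durations 1–2 s,
frequencies from an equal mixture of N(12.2, 0.4) and N(13.8, 0.4) Hz
clipped to 11.3–14.7 Hz, base amplitude 30 µV with 10% log-normal jitter,
~580 s of N2 in a 600 s recording. Default durations start at 1 s rather
than the 0.5 s physiological floor because an envelope threshold crosses
inside the taper: a 0.5 s burst would yield a supra-threshold run shorter
than the detector's own 0.5 s minimum and be discarded by construction. The taper's mean square is 0.6875, so a
burst of amplitude A has mean power 0.6875·A²/2.

Each event belongs to one region and is injected on that region's
derivation electrode pair as ±A/2 on the two electrodes, simultaneously
and homologously on both hemispheres, with the lesioned side scaled by the
region factor *a* — hence ground-truth SPA = *a*². Electrode-sharing
derivations see exact half-amplitude copies, which the detector's source
assignment removes; this is the intended, physically unavoidable coupling
discussed above. One global non-overlapping event schedule per subject
(exponential gaps at the summed rate, ≥ 0.6 s separation) keeps distinct
events clear of the merge gap.

**Cohort calibration.** Typical-outcome subjects draw per-region SPA
targets from a log-normal with median 1.0 and log-SD 0.236 (IQR ≈ 0.32
around symmetry). UCP subjects draw from ceiling·exp(−Exp(µ)) with
µ = ln(ceiling/median)/ln 2 — a left-skewed distribution with a hard
ceiling, reflecting that an outcome-defined UCP group is precisely the set
of infants whose asymmetry was substantial (a PPV of 100% at a cut-off is
only possible when no UCP case sits above it). Calibration constants
(per-region ceiling/median: FC 0.85/0.72, FT 0.95/0.62, CT 0.80/0.71,
CO 0.62/0.56, TO 1.05/0.84) live in `synthetic.UCP_SPA_CALIBRATION`. The
CO and CT interquartile ranges that result are narrower than a symmetric
log-normal matching the clinical IQRs would give; the skewed-ceiling form
was chosen because median, ceiling and group separation jointly matter for
the biomarker evaluation, and a symmetric distribution cannot satisfy all
three at once.

What the generator does **not** model: sleep architecture (cycles, REM,
arousals), artifacts, age-dependent spindle maturation, background
asymmetry, spatially spread sources, inter-event amplitude drift. Passing
tests therefore demonstrate that the pipeline recovers known asymmetry
from EEG-like signals under the detector's assumptions, not that it is
robust to every property of clinical recordings.

## Numerical choices and problem sizes

* Zero-phase filtering by centred FFT convolution of symmetric FIR
  kernels; transition widths 2·hp for the broadband filter, 1.5 Hz for the
  sigma filter.
* Hilbert transform on next-fast-length FFT sizes; envelope smoothing by
  moving average.
* EDF writing uses 16-bit quantization with per-channel symmetric physical
  ranges; round-trip error is below two quantization steps.
* Unit tests run subjects of 330–360 s (just above the 300 s eligibility
  floor); the end-to-end acceptance test runs 25 master seeds of the full
  default 40-subject, 600 s cohort, and the acceptance script runs one
  such cohort plus fidelity/recovery/null batches.
* Degenerate inputs (zero-variance samples, single-class outcomes, empty
  groups, missing electrodes, segments past the recording end) raise
  typed errors; single-class cohorts skip the group statistics with an
  explicit notice rather than failing.

## Known limitations

* Selective detection bias: in a region with strong asymmetry (a ≲ 0.5)
  the weakest lesioned-side spindles can fall below even the per-derivation
  threshold, so estimated SPA in that regime is biased toward 1 relative to
  a² (visible for the widest-spread FT calibration). This mirrors a real
  limitation of envelope-threshold detectors on attenuated signals.
* The stepwise selection inherits the usual caveats of stepwise methods
  (optimistic R², unstable predictor sets under correlated candidates);
  it is implemented because it is the evaluation procedure under study,
  not as a recommendation.
* The 0.65 cut-off and 0.05/0.1 stepwise thresholds are evaluation
  constants of the biomarker protocol, exposed in `RunConfig` but not
  tuned by this package.
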