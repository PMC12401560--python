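# Methods

This note documents the models, conventions and numerical choices
behind the package, in the order data flows through it.

## Stimulus design

A trial is a sequence of mini-sequences of `seq_len = 5` images: four
novel standards then one oddball drawn from a small encoded set. With
166 ms stimulus duration and 166 ms inter-stimulus interval the SOA is
0.332 s, giving an exact presentation rate of 1/0.332 ≈ 3.012 Hz and
an exact oddball rate of ≈ 0.602 Hz. The default design (416
standards, 8 oddballs × 13 repetitions) yields 520 images, 104 oddball
presentations and a 172.64 s trial.

Two rate conventions coexist: the *exact* rates above, and the
*nominal* rates (3 Hz, 0.6 Hz) at which the analysis tags the
spectrum. The schedule records both; the simulator generates at the
nominal rates so that analysis bins align exactly with the simulated
tones. This is a deliberate idealisation — with real hardware the
response follows the exact rate and the integer-cycle epoch is defined
against the oddball rate actually delivered.

Constraints on the ordering — each standard shown once, no oddball
image in consecutive oddball slots, fixation-target sequences (10% of
mini-sequences) never adjacent — are enforced by rejection sampling
with a greedy repair pass, and re-checked by an independent validator
after construction. Ordering is fully determined by the seed.

## Preprocessing

Fixed stage order: common-average re-reference → zero-phase lowpass →
polyphase resampling → integer-cycle epoching → polynomial detrending
→ artifact suppression.

* **Lowpass**: 2nd-order Butterworth at 40 Hz applied forward and
  backward (`sosfiltfilt`), i.e. 24 dB/octave total magnitude rolloff
  with zero phase; the cutoff sits at −6 dB (two −3 dB passes).
* **Resampling**: 500 → 120 Hz by polyphase rational resampling
  (×6/25). The lowpass is required *before* resampling (the order is
  enforced programmatically) so it serves as the anti-alias filter.
* **Epoch**: `round(n_cycles / f_oddball × fs)` samples from trial
  onset — 20800 samples (173.33 s) at 120 Hz for the default 104
  cycles. An integer cycle count is the binding constraint: it puts
  0.6 Hz and every multiple exactly on the FFT grid (bin spacing
  0.6/104 ≈ 0.00577 Hz, which prints as 0.0058). The trial itself
  lasts 172.64 s; generated recordings therefore include a short tail
  beyond the last stimulus so the epoch is complete. With real
  recordings the last ~0.7 s of the epoch extends past the final
  stimulus offset, which is immaterial for a steady-state analysis.
* **Detrend**: least-squares polynomial per channel, order 3 by
  default — removes DC and drift slower than roughly one oddball cycle
  while changing a 0.6 Hz sinusoid's amplitude by well under 0.5%.
  Fit uses a Vandermonde basis on x ∈ [−1, 1] for conditioning.
  Detrending runs *before* artifact zeroing so inserted zeros cannot
  bias the polynomial fit; the stage order is configurable in
  principle but the pipeline default is fixed.
* **Artifact suppression**: per channel, every maximal contiguous run
  of samples with |v| > 250 µV is replaced with zeros; flanking data
  is multiplied by a half-Hanning ramp descending to zero over 670
  samples each side, so the retained signal has no discontinuity.
  Ramps of runs closer than a taper length combine by pointwise
  minimum, keeping the envelope monotone into each run. The 670-point
  taper is interpreted at the 120 Hz analysis rate (≈ 5.6 s). The
  reported `fraction_zeroed` counts zeroed samples only; tapered
  samples are attenuated, not removed.

## Spectral metrics

Amplitude spectra use the single-sided normalisation 2|X_k|/N, so a
unit-amplitude bin-aligned sinusoid reads 1.0 in its bin. SNR divides
each bin by the mean amplitude of neighbours within ±0.10 Hz,
excluding the first bin on each side (which may carry leaked signal).
At the default resolution that is 17 bins per side minus the excluded
one — 32 baseline bins. Bins without a complete neighbourhood are
marked unavailable (NaN) rather than computed from a truncated
baseline.

**Harmonic selection.** Candidates are multiples of 0.6 Hz up to
20 Hz that are not multiples of 3 Hz. For each candidate,
Z = (amp − mean)/SD of the ±0.10 Hz neighbourhood is computed on the
grand average of the subjects' all-electrode mean amplitude spectra
(one shared selection for all subjects; per-subject selection would
make f+ incomparable across subjects). Scoring the SNR spectrum
instead of the amplitude spectrum is available behind a flag
(`use_snr=True`); the two agree on bin-aligned responses.

Two stopping rules are implemented. The default (`stop="first_gap"`)
includes candidates from the lowest frequency upward while Z > 1.96
and stops at the first non-significant one — the usual FPVS
harmonic-summation practice. The alternative (`stop="highest"`)
includes everything up to the highest significant candidate regardless
of gaps. The default was chosen because with ~18 pure-noise candidates
between 6.6 and 20 Hz, a single chance exceedance of Z = 1.96 (about a
3% event per candidate) would drag a block of noise frequencies into
f+ under the "highest" rule; the first-gap rule confines that risk to
the one candidate adjacent to the true family. With no significant
candidate at all, f+ falls back to the nominal nine-member family
(0.6, 1.2, 1.8, 2.4, 3.6, 4.2, 4.8, 5.4, 6.6 Hz) with a warning.

**Metrics.** Per electrode, F = SNR at 3 Hz and f+ = mean SNR over the
included harmonics; the scalp average is the mean over electrodes and
the maximal electrode is the argmax of f+ (ties resolved by channel
order). Nominal frequencies snap to the nearest bin and must lie
within half a bin; with compliant epochs the snap distance is zero.

## Synthetic data

The generator emulates the *statistical structure* the analysis
assumes, not the physiology:

* deterministic sinusoids at the base harmonics (3, 6 Hz) and the
  oddball family, with per-channel random phases;
* fixed topography conventions — base response largest at O1/O2,
  oddball response largest at Cz/P8;
* 1/f ("pink") noise synthesised by frequency-domain shaping
  (amplitude ∝ 1/√f, random phases, normalised to unit RMS then
  scaled) plus white noise — giving exact spectral control for the
  SNR noise-floor checks;
* square-pulse artifacts exceeding ±250 µV at Poisson times, recorded
  in the ground-truth manifest;
* per-subject oddball amplitude factors drawn per group from normal
  distributions (clipped at zero), with group means encoding
  configurable standardized differences; two-session data draw the
  second session from a bivariate model with correlation `retest_r`
  (the population consistency ICC for equal variances) and an additive
  session shift.

The amplitude scale is a documented convention, not an estimate of any
real dataset: oddball fundamental 0.7 µV with geometric harmonic decay
0.85, base 2.0/1.0 µV, pink 5 µV RMS, white 3 µV RMS. These values
give single-subject scalp-average f+ around 2–3 and make every family
member detectable in a 30-subject grand average. The decay matters
more than the scale: because subjects are combined by averaging
*magnitude* spectra, a tone buried below the per-bin noise floor
raises the average only quadratically in its amplitude, so a family
with a steep decay has upper harmonics that no cohort size can rescue.
Real EEG differs in ways the simulator does not model — non-sinusoidal
response waveshape, non-stationary noise, eye/muscle artifacts with
realistic morphology, volume conduction — so passing recovery tests
validates the analysis arithmetic and its statistical behaviour, not
claims about real patients.

Behavioural tables are generated per group: binomial 2AFC accuracy
(standards at chance 0.5), log-normal response times, a PVT mixture of
log-normal base responses with a lapse tail (> 500 ms) and occasional
false starts (< 100 ms), binomial DMS-48 subsets, and normal ACE-III
subscale scores (healthy-control memory mean 25, SD 2 — placing the
2-SD impairment cutoff at 21).

## Group statistics

* **ANCOVA**: `f_plus ~ group * electrode + F_snr` on stacked
  per-electrode rows, OLS with sum-to-zero contrasts and Type-III sums
  of squares; no subject random effect — a faithful reproduction of
  the stacked-row design convention, not an endorsement (with 8 rows
  per subject the error term ignores within-subject correlation). The
  second model regresses each subject's maximal-electrode f+ on group
  plus covariate. Pairwise Cohen's d (pooled SD) accompanies the
  F-tests.
* **Nonparametrics**: Kruskal–Wallis (tie-corrected) with two-sided
  Mann–Whitney post hocs using the tie-corrected normal approximation
  for Z, Bonferroni-multiplied p (capped at 1).
* **Bootstrap regression**: case resampling with replacement, OLS per
  resample, percentile 95% CIs, bootstrap p = 2·min(P(β* ≤ 0),
  P(β* ≥ 0)) with a +1 correction; standardized coefficients rescale
  by predictor and outcome SDs per resample. Percentile (rather than
  BCa) intervals are the package's choice where the convention was
  open; their mild undercoverage at n ≈ 50 is visible in the coverage
  study (~0.92–0.95 against the nominal 0.95).
* **ICC**: two-way mean squares (rows = subjects, columns = sessions)
  give ICC(C,1) = (MSR−MSE)/(MSR+(k−1)MSE), ICC(C,k) = (MSR−MSE)/MSR,
  ICC(A,1) = (MSR−MSE)/(MSR+(k−1)MSE+k(MSC−MSE)/n) and
  ICC(A,k) = (MSR−MSE)/(MSR+(MSC−MSE)/n), with the standard F-based
  CIs (Satterthwaite df for the agreement forms — the choice of CI
  method was open; F-based is the common default) and a session-bias
  F test MSC/MSE. Subjects with missing sessions are dropped and
  counted. Interpretation bands: ≤ 0.40 poor, 0.41–0.59 moderate,
  0.60–0.74 good, ≥ 0.75 excellent (compared at two decimals).

## Problem sizes used in the checks

The automated checks run at desk scale, chosen to keep Monte-Carlo
error well inside each assertion band: harmonic selection on
30-subject cohorts; effect-size recovery as the mean sample Cohen's d
over five replicate 200-per-group cohorts (ten for the null
configuration); ICC recovery as the mean over five replicate
300-subject two-session cohorts; bootstrap coverage over 500 simulated
n = 50 regressions at B = 1000. Replication across cohorts — rather
than a single draw — reflects that the recovery claims concern the
generator's convergence, while single draws at these sizes still
fluctuate beyond the stated bands a few percent of the time.

## Known limitations

* The stacked-row ANCOVA ignores within-subject correlation across
  electrodes (see above); a mixed-effects alternative is out of scope.
* Harmonic selection at a fixed Z > 1.96 carries an irreducible
  per-candidate false-positive rate; on a small fraction of simulated
  cohorts the selection includes one extra noise harmonic adjacent to
  the true family.
* EDF files are read (via mne) but not written; the native on-disk
  format is a float32 matrix with a JSON sidecar.
* The simulator's oddball response is strictly sinusoidal and
  stationary; fraction-of-data-removed statistics under artifact
  injection are qualitative only.
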