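# Methods

This note documents the models, numerical choices and limitations
behind `eyepatch`. The package implements the analysis chain of a
short-term monocular-deprivation experiment: EEG spectral features,
contrast-threshold psychometrics, binocular ocular-dominance indices,
and the repeated-measures inferential layer, together with synthetic
generators that emulate the statistical structure of such a study.

## Spectral pipeline

**Filtering.** The band-pass is a 5th-order Butterworth applied
forward–backward (`sosfiltfilt`), i.e. zero-phase with the squared
magnitude response. Second-order sections are used because a 1–30 Hz
band at a 1000 Hz rate is a narrow relative band for which the
transfer-function form of the same filter is numerically unstable. The
order was chosen so that the stop band reaches 40 dB of attenuation at
50 Hz line frequency (a 4th-order forward–backward design reaches only
≈36 dB there); passband ripple of a Butterworth design is negligible
by construction.

**Epoching.** Resting recordings drop their first 10 s (settling and
movement artifacts) and are cut into consecutive non-overlapping 7 s
epochs, discarding any remainder. SSVEP sessions consist of 10 s
trials; each is trimmed by 2 s at the head (stimulus-onset transient)
and 1 s at the tail, leaving one 7 s epoch per trial. The 7 s epoch
makes the spectral grid spacing 1/7 Hz, which places 15 Hz exactly on
bin 105 — the SSVEP response to 7.5 Hz counterphase flicker (cortex
responds at the second harmonic of counterphase flicker) is therefore
read without scalloping loss.

**Spectra.** Per epoch and channel the single-sided amplitude is
`2|X(f)|/N` on a rectangular window (DC and Nyquist unscaled), then
arithmetically averaged across epochs and channels. The rectangular
window is deliberate: all frequencies of interest are on-grid for 7 s
epochs, so tapering would only trade exact recovery for unneeded
leakage suppression. For phase-locked SSVEP analysis an optional
coherent mode averages epochs and channels in the time domain before
the FFT, which suppresses non-phase-locked background by √(n·m); the
two modes agree exactly for deterministic signals and the incoherent
mode is the default contract.

**Alpha peak.** The averaged spectrum is smoothed with a
Savitzky–Golay filter (default window 11 bins ≈ 1.6 Hz, cubic) and the
maximum over the inclusive 8–13 Hz band is taken; ties break to the
lowest frequency. The S-G window is wide enough to suppress
single-bin noise excursions but narrower than a physiological alpha
peak (≈1–2 Hz), so a real peak's height survives smoothing. Both
window and order are configurable.

**Normalization.** Before group comparison, each subject's feature
values are divided by that subject's mean across conditions and
rescaled by the grand mean. This removes between-subject amplitude
differences (skull thickness, electrode impedance) while preserving
each subject's condition ratios and the grand mean; it requires a
complete, positive subject × condition table. Normalization is applied
after channel averaging, and separately per feature family (SSVEP
amplitudes, alpha amplitudes).

**Montage.** When recordings carry 10-20 labels, a posterior-channel
filter (P/PO/O/CB prefixes, accepting digit or `z` suffixes) restricts
analysis to occipito-parietal electrodes; recordings with generic
labels are used whole.

## Psychometrics

The psychometric function is the natural-exponential Weibull
("Quick") form `P(c) = γ + (1−γ−λ)(1 − e^{−(c/α)^β})`. This base is
used — rather than the classical base-2 Quick form — because only the
natural base puts the threshold parameter α at 81.6% correct with a
2AFC guess rate of 0.5, which is the threshold convention the rest of
the pipeline (and the field's common usage) assumes; the base-2 form
would put 75% there. The lapse rate λ is fixed at 0 by default and
configurable; it is not estimated.

Fitting maximizes the product-binomial likelihood over (log α, log β)
with L-BFGS-B from a 4 × 4 multi-start grid, α bounded to
[min level/10, max level×10] and β to [0.5, 10]. Datasets whose
observed proportions never exceed the guessing floor, or sit at
ceiling everywhere, are non-identifiable and rejected. The bootstrap
is parametric: `n_boot` (default 500) datasets are simulated from the
fitted curve at the observed levels and trial counts and refit; the SE
is the SD of the bootstrap thresholds and the CI their 2.5/97.5
percentiles. The tests verify this SE against the Monte-Carlo spread
over independent datasets (agreement within 30% at the 6 × 75 design)
and verify the optimizer against an exhaustive lattice search.

The adjustment-method threshold averages the settled contrast over
correct trials only, as a geometric mean (thresholds are positive and
approximately log-normal; the arithmetic mean is available as an
option).

## Binocular indices

**Phase combination.** Gratings at ±22.5° phase are shown
dichoptically; in configuration 1 the unpatched eye carries +22.5°,
in configuration 2 the signs swap, so any constant positional bias
cancels. The index is *half* the difference of the configuration
means. The halving is a deliberate, documented choice: it makes the
index equal the true combined phase, so a balanced observer reads 0°
and the monocular limit reads ±22.5° (not ±45°), matching how the
stimulus geometry is described. A strengthening patched eye drives
the index negative.

**Rivalry.** The dominance ratio is total unpatched-eye dominant time
over total patched-eye dominant time. Durations are pooled (summed)
across the two 90 s sub-block configurations before dividing rather
than averaging per-block ratios — ratios of sums are less volatile
than means of ratios for short blocks. Mixed percepts are excluded
from both totals.

**Change metrics.** Every timeline carries a pre-deprivation baseline;
changes are per-timepoint subtractions from it, and the cumulative
change is the arithmetic mean of the changes at 0', 3', 6' and 9'.
Timelines accept any subset of post timepoints (the monocular
contrast-sensitivity experiment measures {0', 30'}, the binocular
experiments {0', 3', 6', 9', 30'}).

## Group statistics

Paired t, Pearson r and the ANOVA decompositions are delegated to
scipy/pingouin behind the package's validated surface; Holm–Bonferroni
uses the statsmodels step-down implementation, cross-checked in the
tests against a brute-force implementation of the definition. The
signed-rank test is computed directly (ranks of |differences| after
dropping zeros, mid-ranks for ties, normal approximation with tie
correction) because the package reports a *signed* Z — negative when
the first sample tends below the second — while library
implementations return an unsigned statistic for two-sided tests.

Repeated-measures ANOVA reports partial η² = SS_effect/(SS_effect +
SS_error) per effect, each effect tested against its own
effect-by-subject error term. For the one-way analysis the
Greenhouse–Geisser correction is applied when Mauchly's test rejects
sphericity at 0.05 (only possible with ≥3 levels), yielding fractional
degrees of freedom; epsilon and the Mauchly p are always reported.
For the two-way analysis uncorrected dfs are primary and GG-corrected
p-values are carried in `extras`. Degenerate tables are handled
explicitly rather than propagating NaNs: a flat table returns F = 0,
p = 1 (flagged), and a nonzero effect over a zero error term returns a
flagged infinite F.

## Synthetic generators

The generators define the study conditions under which the pipeline is
validated; all randomness flows from one explicit seed per call and a
fixed seed gives bit-identical output.

**EEG.** Each channel is the sum of (i) Gaussian noise synthesized in
the frequency domain with power ∝ 1/f^k (flat below 1 Hz to keep
variance finite), rescaled to a broadband RMS of `noise_scale`;
(ii) a band-limited alpha process with a Gaussian spectral envelope
(centre `alpha_freq`, FWHM `alpha_bandwidth`), scaled to the RMS of a
sinusoid of amplitude `alpha_amp` (zero bandwidth degenerates to a
pure sinusoid); and (iii) for SSVEP sessions, a deterministic
sinusoid at `ssvep_freq`, phase-locked across channels as a
stimulus-driven response is. Defaults — 10 µV alpha with 1 Hz
linewidth over 15 µV of 1/f noise at exponent 1, 1000 Hz sampling —
give an alpha peak clearly above the background (amplitude SNR ≈ 4 at
the peak bin), as in real occipital recordings. Two biases of the
real pipeline are faithfully reproduced rather than hidden: the
measured peak adds noise power in quadrature (so an amplitude ratio r
between conditions is compressed to ≈ √(r²x² + 1)/√(x² + 1) at
peak-to-background SNR x — about one percentage point at these
defaults for r = 1.233), and finite linewidth spreads peak energy
across bins. The generator produces no eye blinks, line noise, volume
conduction or non-stationarity, so passing recovery tests demonstrates
correctness of the spectral arithmetic, not robustness to real-world
artifacts.

**Behavior.** 2AFC responses are binomial draws from the Quick
probability. Adjustment trials settle log-normally around the true
threshold (`jitter_sd` log-units) with a small fixed probability of an
incorrect orientation report. The phase-combination observer is a
gain-weighted linear combiner — percept phase = arctan of the
gain-weighted tangent, the simplest model whose balanced case gives
0° and whose monocular limits give ±22.5° — with Gaussian report
noise. Rivalry is an alternating renewal process with
gamma-distributed dominance durations (shape 3 by default, the
standard empirical description of dominance-duration histograms);
mixed intervals, when requested, follow each dominance interval with
exponential durations sized to occupy the requested time fraction, and
the final interval is truncated so intervals tile the block exactly.

**Cohorts.** Per subject and metric, values follow `baseline +
between-subject offset + effect_at_0 · e^{−t/τ} + within-cell noise`,
with no effect at baseline by construction. The single-exponential
recovery (τ = 10 min by default, so the effect is ≈5% at 30') encodes
the monotone return to baseline such experiments show; the default
effects at 0' (perceived phase −14.0°/−6.14°, dominance ratio
−0.487/−0.414 for the open/closed conditions, contrast sensitivity
−33/−23 about a baseline of 100) are calibrated to the group means of
the study being emulated, with between-subject SD 4° (phase) and
measurement noise of a few units per metric. With `include_raw=True`
the cohort also emits per-cell raw trial tables (phase sessions,
rivalry sub-block pairs, constant-stimuli counts) parameterized to the
same latent values, so the entire chain from trial data to group
statistics can be exercised; latent phases are clipped to ±97% of the
stimulus phase where the gain model saturates.

## Problem sizes and tolerances

The validation suite uses the study's own designs where they are
stated: 7 s epochs at 1000 Hz, 5-minute resting recordings (41
epochs), 12 × 10 s SSVEP trials, six contrast levels × 75 trials,
16-trial phase sessions, 90 s rivalry sub-blocks, cohorts of 14
subjects × 2 conditions × 6 timepoints. Monte-Carlo checks use 20–200
replicates depending on the variance of the quantity under test:
alpha-ratio recovery averages 20 independent recording pairs
(tolerance ±2 percentage points on the enhancement, ±5% on the ratio),
threshold recovery uses 100 observers (median relative error < 5%),
bootstrap calibration compares against 200 independent datasets
(within 30%), and type-I calibration uses 2000 null simulations
(5% ± 2%). Long-run rivalry checks use 10⁴ s of process time
(ratio within ±0.05 of 1).

## Known limitations

- No artifact rejection beyond the stated trimming; no source
  localization, time-frequency analysis or coherence measures.
- The lapse rate is not estimated; severely lapsing observers will
  bias threshold estimates upward.
- The two-way RM-ANOVA reports GG-corrected p-values but not a
  per-effect Mauchly test (pingouin does not expose one for two
  within factors); the one-way path is Mauchly-gated.
- EDF files can be read (via mne) but not written; the native on-disk
  format is CSV + JSON sidecar.
- The generators assume complete, clean, balanced data; missing-cell
  handling is limited to explicit errors.
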