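# eyepatch

Analysis pipeline for short-term monocular-deprivation experiments in
visual neuroscience. When one eye of an adult observer is patched for a
couple of hours, ocular dominance transiently shifts toward the
deprived eye; the size of that shift can be modulated by the internal
neural state (for example whether the eye behind the patch is kept open
or closed, which changes occipital alpha power). Quantifying this
requires a chain of heterogeneous analyses, all of which this package
implements as a tested, reusable library:

- **EEG spectral features** (`eyepatch.spectral`): zero-phase 1–30 Hz
  band-pass, condition-specific epoching (resting state: discard 10 s,
  7 s epochs; SSVEP: 10 s trials trimmed 2 s head / 1 s tail),
  single-sided FFT amplitude spectra (`2|X(f)|/N`) averaged over epochs
  and channels, Savitzky–Golay-smoothed alpha-peak extraction over
  8–13 Hz, the SSVEP amplitude at the second harmonic of the flicker
  frequency (15 Hz for 7.5 Hz counterphase flicker), and subject-wise
  cross-condition normalization
  `v'(s,c) = v(s,c) / mean_c v(s,·) × grand_mean(v)`.
- **Psychometrics** (`eyepatch.psychometrics`): the Quick (Weibull)
  psychometric function
  `P(c) = γ + (1−γ−λ)(1 − e^{−(c/α)^β})`, maximum-likelihood fitting of
  (α, β) to constant-stimuli 2AFC data, parametric bootstrap SE/CI for
  the threshold α (the 81.6%-correct point for γ = 0.5, λ = 0), the
  adjustment-method threshold (geometric mean over correct trials),
  and the change metrics `dB = 20·log₁₀(CS_post/CS_base)`,
  `CS ratio = CS_UPE / CS_PE`, and `(closed − open)/open`.
- **Binocular dominance indices** (`eyepatch.binocular`): the
  phase-combination index (half the difference of the two
  configuration means, so a balanced observer reads 0° and monocular
  limits read ±22.5°) and the rivalry dominance ratio (UPE dominant
  time / PE dominant time, mixed percepts excluded, pooled across
  sub-blocks), plus per-timepoint and cumulative change metrics.
- **Group statistics** (`eyepatch.stats`): paired t, Holm–Bonferroni
  step-down correction, signed-rank Z with tie correction, Pearson r,
  and one-/two-way repeated-measures ANOVA with partial η² and
  Mauchly-gated Greenhouse–Geisser correction.
- **Synthetic data** (`eyepatch.synthetic`): seeded generators for all
  of the above — 1/f EEG with band-limited alpha and SSVEP components,
  Quick-function 2AFC observers, gain-weighted phase-combination
  observers, gamma-renewal rivalry timelines, and whole cohorts with
  exponentially recovering deprivation effects — so every stage is
  testable end-to-end without recorded data.

EEG moves on disk as raw-array CSV plus JSON sidecar (`eyepatch.io`);
EDF files can be read via `mne` (`pip install eyepatch[edf]`).

## Worked example

Fit a contrast threshold for a simulated observer at the standard
six-level × 75-trial design (`examples/contrast_threshold.py`):

```python
import numpy as np
import eyepatch as ep
from eyepatch.synthetic import gen_constant_stimuli

levels = np.array([0.015, 0.025, 0.04, 0.06, 0.09, 0.13])
observer = ep.PsychoObserverParams(true_alpha=0.05, true_beta=3.0, seed=11)
data = gen_constant_stimuli(observer, levels, n_per_level=75)
fit = ep.bootstrap_quick(ep.fit_quick(data), data, n_boot=500, seed=11)
```

prints

```
threshold alpha : 0.0500 +- 0.0032 (true 0.0500; 81.6% correct point)
slope beta      : 2.55 (true 3.00)
95% CI          : [0.0440, 0.0561]
contrast sensitivity = 1/alpha = 20.0
```

The threshold (the contrast at which this observer answers 81.6% of
orientation judgments correctly) is recovered exactly at its true
value here, with a bootstrap standard error of about 6% of the
threshold — typical for this trial budget. Contrast sensitivity is the
reciprocal threshold; a sensitivity drop from 103.086 to 70.017, as a
deprived eye might show immediately after patch removal, corresponds
to `-3.36 dB` or a `32.1%` decrease.

The other example scripts each exercise one capability end to end:

- `examples/eeg_spectral_features.py` — synthesize resting and SSVEP
  EEG, extract alpha peak (10.00 Hz here) and 15 Hz SSVEP amplitude
  (4.02 µV recovered from a generated 4 µV response), and normalize a
  subject × condition table.
- `examples/binocular_indices.py` — perceived phase and dominance
  ratio for a balanced vs a patched-eye-strengthened observer.
- `examples/cohort_statistics.py` — full inferential layer on a
  simulated 14-subject cohort (RM-ANOVAs, Wilcoxon, Holm-corrected
  paired t-tests).

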