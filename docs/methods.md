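# Methods

## Scoring model

The package quantifies cortico-muscular coupling as similarity between a
subject's paired LFP/EMG traces and a healthy-reference pair, using
unconstrained dynamic time warping with squared-difference cost
D(i, j) = (xᵢ − yⱼ)². No warping window (Sakoe–Chiba or Itakura) and no
step weights are applied: the classic three-way recursion runs over the
full n × m grid. Epoch lengths here (8000 samples for 4 s at 2 kHz) give
~6.4·10⁷ cells per comparison, which a compiled two-row dynamic program
handles in ~0.2 s on one CPU, so no approximate DTW variant is needed.
When the optimal path is requested, backtracking follows the argmin
predecessor with ties broken diagonal-first, then up, then left; the
tie-break affects only the reported path, never the distance. Path indices
are 0-based; the equivalent textbook presentation numbers the same path
from (1, 1).

The raw distance grows with sequence length, so it is normalized by 2n for
equal-length sequences. For unequal lengths the package divides by n + m,
which degenerates to 2n when n = m; equal lengths are the only case the
pipeline itself produces.

A normalized distance d maps to the percentage score 100·(1 − A·d),
clamped to [0, 100]. The raw affine map goes negative for very dissimilar
pairs; a percentage-scale score must stay in range, hence the clamp.

### The coefficient A

A is deliberately a free scaling parameter: it fixes which distance
corresponds to a score of zero. The package's default policy calibrates A
per run and per domain against the pre-stimulation cohort with a floor
score of 0 — i.e. A = 1/max(d) over the pooled pre-stimulation LFP and EMG
normalized distances. This makes every run self-contained and exactly
reproducible from its inputs. One A is shared by both modalities within a
domain, but the time and frequency domains are calibrated separately
because their distances differ by orders of magnitude (squared microvolts
summed over samples vs squared DFT magnitudes summed over bins). A pinned
`coefficient_A` in the config bypasses calibration and is then used for
both domains. Note that floor-calibration anchors the scale to the single
worst pre-stimulation sample, so absolute score values shift between
cohorts; paired pre/post comparisons are unaffected because both phases
are scored with the same A.

### Composite and inference

LFP and EMG scores combine as w·LFP + (1−w)·EMG with w = 0.5 by default
(exposed in the config). Group inference is a paired two-tailed t-test on
composite scores of the same subjects pre vs post stimulation, df = n − 1,
run independently in the two domains with no multiple-testing correction —
two raw p-values are reported. Zero-variance differences leave t
undefined; the package then reports p = 1 (all differences zero) or p = 0
(constant shift) with a warning. An unpaired test is intentionally not the
default: the two "groups" are repeated measurements of the same animals.

## Preprocessing

Fixed order: notch → baseline removal → bandpass, then epoching and trial
averaging.

- **Notch.** Second-order IIR notch at 50 Hz, Q = 30, applied
  forward-backward (zero-phase). The topology is a design choice; Q = 30
  (≈1.7 Hz bandwidth) removes mains interference while passing 40 Hz
  within 1 dB.
- **Baseline drift.** Moving-average subtraction over a 1 s window
  (configurable). This is the simplest drift remover that adapts to the
  local baseline and has an analytically checkable transfer function: a
  0.1 Hz drift is attenuated >90% while a 40 Hz tone (integer cycles per
  window) passes untouched. Window edges reflect, which preserves
  constants exactly.
- **Bandpass.** Zero-phase 4th-order Butterworth, 0.5–200 Hz for LFP and
  10–200 Hz for EMG. Butterworth's flat passband avoids coloring the 40 Hz
  band the analysis emphasizes; forward-backward application squares the
  magnitude response (≥20 dB at 300 Hz for the LFP band) and cancels phase.
- **Edge padding.** Forward-backward IIR filtering needs padding covering
  the filter's settling time. A 0.5 Hz band edge settles over seconds, far
  beyond scipy's default padding, so padding is sized as three periods of
  the slowest relevant pole (clamped to signal length). Within a 4 s epoch
  a residual sub-Hz transient at the ~1% level is unavoidable; it is
  common mode between sample and reference and does not affect score
  ordering.
- **Epochs.** Half-open windows around stimulation onsets: post-stimulus
  epochs start at the onset (the 300 ms stimulation burst is inside the
  window, consistent with a 4 s inter-trial interval tiling the recording);
  pre-stimulus epochs end at the onset. Onsets too close to the recording
  edge are skipped with a logged warning. The pre-stimulus placement
  convention (window ending exactly at onset) is a package convention, not
  an empirical fact about any particular acquisition.
- **Averaging and reference.** Trials average pointwise ("superposition").
  The healthy reference is the grand mean over the normal cohort of each
  subject's trial average; with a single subject it degenerates to that
  subject's average.

## Frequency-domain pathway

Spectra are single full-epoch one-sided DFT magnitudes — no Welch
segmenting, no taper — so bins are exact (0.25 Hz for 4 s epochs) and a
40 Hz oscillation lands on its own bin. Stored magnitudes are raw
|rfft(x)|; with that convention Parseval's identity is
2Σ|Xₖ|² − |X₀|² − |X_Nyq|² = N Σxₙ². Scoring compares magnitudes by
default ("amplitude" spectra); power and dB scales are config options, as
is averaging adjacent bins before DTW (off by default) to bound the
spectral DTW cost. Spectral analysis bands default to each modality's
time-domain filter band.

## Synthetic cohorts

Real recordings for this preparation are not publicly deposited, so the
generator produces cohorts with the statistical structure the analysis
assumes. Per trial, the LFP is a mixture of a 40 Hz oscillation and
band-limited 1/f noise, weighted so a regime-specific fraction of power
falls near 40 Hz, then peak-normalized to the regime amplitude with
per-trial jitter. The EMG is 10–200 Hz noise amplitude-modulated by the
cortical oscillation plus a small phase-locked 40 Hz component standing in
for (weak) cortico-muscular coherence.

The oscillation is stimulation-locked: base phase 0 for every trial and
subject, with per-trial Gaussian phase jitter. Phase locking is what makes
"averaging by superposition" meaningful — with fully random per-trial
phases the trial average and the grand-mean reference would converge to a
noise floor rather than an oscillatory waveform.

Regime defaults (all overridable per `CohortSpec`):

| regime | LFP:EMG peak ratio | 40 Hz power fraction | LFP peak (µV) | amp jitter | phase jitter (rad) |
|---|---|---|---|---|---|
| normal | 1.2 | 0.7 | 100 | 0.9–1.1 | 0.25 |
| bcao_pre | 3 | 0.2 | 400 | 0.7–1.5 | 0.5 |
| bcao_post | 100 | 0.7 | 110 | 0.95–1.05 | 0.3 |

The pre-stimulation regime is broadband (energy not concentrated at
40 Hz), strongly amplitude-elevated, and the most variable trial to trial.
The post-stimulation regime restores 40 Hz concentration near the normal
amplitude, imposes a mild bimodal amplitude envelope across the epoch, and
realizes the ~100:1 peak ratio through EMG suppression rather than LFP
inflation — post-stimulation traces must be close to the healthy reference
for the score increase to emerge, and the suppressed EMG is what a
cortically-gated effector would produce. The EMG phase-locked fraction is
0.08 in the normal and post regimes (0.05 pre); weak locking is both
physiologically realistic and necessary for the reference EMG not to
overstate coherent muscle drive. Amplitude-ratio and concentration targets
of every generated subject can be audited with `spectral_check`.

Noise is synthesized in the frequency domain from complex-Gaussian bins
(Rayleigh amplitudes), i.e. genuine band-limited Gaussian noise.
`noise_sigma` adds optional wide-band sensor noise in µV on top of the
physiological mixture and defaults to 0, since in-band noise is already
governed by the concentration parameter. Determinism: a cohort is a pure
function of (spec, seed); subject streams derive from
`SeedSequence(seed, spawn_key=(regime_code, subject_index))`, so the three
regimes may share one base seed without stream collisions.

What the generator does *not* model: biophysical neural-mass or motor-unit
dynamics, electrode drift and motion artifacts, spike contamination,
inter-subject differences in oscillation frequency, or any behavioral
covariate. Passing pipeline tests on these cohorts therefore demonstrates
that the scoring machinery recovers a stimulation effect of the assumed
amplitude/spectral structure — not that real recordings carry that
structure.

## Problem sizes and numerical choices

- Full-scale runs (acceptance script) use the study geometry: 30 reference
  subjects, 9 subjects pre/post, 30 trials of 4 s at 2 kHz, DTW at the
  full 8000-sample resolution (~13 s on one CPU).
- The repeated-reseed separation check in the test suite runs 100 full
  studies; for tractability it FIR-decimates trials (zero-phase) from
  2 kHz to 500 Hz before preprocessing and averages spectral bins in pairs.
  Every analysis band lies below the reduced 250 Hz Nyquist, so in-band
  content is unchanged while the DTW grid shrinks 16-fold.
- DTW inner loops are numba-compiled; the distance-only path uses a
  two-row rolling buffer (O(m) memory), while path recovery materializes
  the full cumulative matrix.
- An exhaustive path-enumeration oracle (`brute_force_dtw`, guarded at
  n + m ≤ 20) provides an implementation-independent cross-check; the
  dynamic program and the enumeration accumulate costs in the same
  left-to-right order, so their agreement is exact, not approximate.
- Degenerate inputs: empty sequences, empty trial sets, all-zero
  calibration distances, bands at or beyond Nyquist, and windows shorter
  than 3 samples all raise `ValidationError` rather than propagating NaNs.

## Known limitations

- Scores depend on the calibration cohort through A; only within-run
  comparisons (same A) are meaningful. Cross-study score comparisons
  require pinning A explicitly.
- DTW with squared-difference cost is amplitude-sensitive by design;
  recordings must share units and gain with the reference cohort, as no
  rescaling is applied.
- The paired t-test assumes approximately normal score differences; with
  n = 9 subjects this is a model assumption, not a verified property.
- On short epochs, zero-phase filtering with a 0.5 Hz corner leaves ~1%
  sub-Hz edge residue (see above); analyses needing clean sub-Hz content
  should record longer epochs.
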