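"""Preprocessing chain for paired LFP/EMG epochs.

Order of operations is fixed: 50 Hz notch ("trap") filter, moving-average
baseline-drift removal, modality-specific bandpass (0.5–200 Hz for LFP,
10–200 Hz for EMG), epoch extraction around stimulation onsets, and trial
averaging by superposition.  All filters are applied forward-backward
(zero-phase) so epochs stay time-aligned with the stimulation onset.

The healthy baseline used by the scorer is the grand mean across a normal
cohort: each subject's trials are averaged pointwise, then the subject
averages are averaged again, per modality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .errors import ValidationError
from .signal_io import Alignment, Modality, RunConfig, SignalTrace, TrialSet, _as_alignment

__all__ = [
    "ReferencePair",
    "design_notch",
    "notch_filter",
    "remove_baseline",
    "design_bandpass",
    "bandpass_filter",
    "extract_epochs",
    "average_trials",
    "build_reference",
    "preprocess_trials",
    "preprocess_and_average",
]

log = logging.getLogger(__name__)


@dataclass
class ReferencePair:
    """Grand-mean LFP and EMG traces serving as the healthy baseline."""

    lfp_ref: SignalTrace
    emg_ref: SignalTrace
    n_source_trials: int

    def __post_init__(self):
        if self.lfp_ref.n != self.emg_ref.n or self.lfp_ref.rate != self.emg_ref.rate:
            raise ValidationError("reference LFP and EMG must share length and rate")
        if self.n_source_trials < 1:
            raise ValidationError("n_source_trials must be >= 1")


# ---------------------------------------------------------------------------
# Filters


def design_notch(rate: float, freq: float = 50.0, q: float = 30.0):
    """Second-order IIR notch (b, a) for mains-interference removal."""
    if not 0 < freq < rate / 2:
        raise ValidationError(f"notch frequency {freq} Hz not in (0, {rate / 2}) Hz")
    if not q > 0:
        raise ValidationError("notch Q must be > 0")
    return sps.iirnotch(freq, q, fs=rate)


def design_bandpass(rate: float, band: tuple[float, float], order: int = 4):
    """Zero-phase-ready Butterworth bandpass in second-order sections."""
    low, high = float(band[0]), float(band[1])
    if not 0 < low < high:
        raise ValidationError(f"bandpass band must satisfy 0 < low < high, got {band}")
    if not high < rate / 2:
        raise ValidationError(f"bandpass high edge {high} Hz >= Nyquist {rate / 2} Hz")
    return sps.butter(order, (low, high), btype="bandpass", output="sos", fs=rate)


def _settle_padlen(n: int, rate: float, slowest_hz: float) -> int:
    # Forward-backward IIR filtering needs edge padding covering the filter's
    # settling time, ~3 periods of its slowest pole (a 0.5 Hz band edge
    # settles over seconds); scipy's default padding is far too short for that.
    if n < 8:
        raise ValidationError(f"trace of {n} samples too short to filter")
    return min(n - 1, max(int(3 * rate / slowest_hz), 24))


def _filtfilt_rows(b, a, arr: np.ndarray, rate: float, slowest_hz: float) -> np.ndarray:
    padlen = _settle_padlen(arr.shape[-1], rate, slowest_hz)
    return sps.filtfilt(b, a, arr, axis=-1, padlen=padlen)


def _sosfiltfilt_rows(sos, arr: np.ndarray, rate: float, slowest_hz: float) -> np.ndarray:
    padlen = _settle_padlen(arr.shape[-1], rate, slowest_hz)
    return sps.sosfiltfilt(sos, arr, axis=-1, padlen=padlen)


def notch_filter(x: SignalTrace, freq: float = 50.0, q: float = 30.0) -> SignalTrace:
    """Remove a narrow interference line (default 50 Hz mains), zero-phase."""
    b, a = design_notch(x.rate, freq, q)
    log.info("notch filter: %.6g Hz, Q=%.6g, rate=%.6g", freq, q, x.rate)
    return x.with_samples(_filtfilt_rows(b, a, x.samples, x.rate, freq / q))


def remove_baseline(x: SignalTrace, window_seconds: float = 1.0) -> SignalTrace:
    """Subtract a moving-average baseline estimated over ``window_seconds``.

    This is the drift remover behind the "adaptive high-pass" step: the
    local mean over the window tracks slow baseline wander and is removed,
    so the output mean over any full window is approximately zero.  Window
    edges are handled by reflection, which preserves a constant exactly.
    """
    if not 0 < window_seconds <= x.duration:
        raise ValidationError(
            f"baseline window {window_seconds}s not in (0, epoch duration {x.duration}s]"
        )
    k = int(round(window_seconds * x.rate))
    if k < 3:
        raise ValidationError(f"baseline window of {k} samples is shorter than 3 samples")
    baseline = uniform_filter1d(x.samples, size=k, mode="reflect")
    log.info("baseline removal: %.6g s window (%d samples)", window_seconds, k)
    return x.with_samples(x.samples - baseline)


def bandpass_filter(x: SignalTrace, band: tuple[float, float]) -> SignalTrace:
    """Zero-phase 4th-order Butterworth bandpass."""
    sos = design_bandpass(x.rate, band)
    log.info("bandpass filter: %.6g-%.6g Hz, rate=%.6g", band[0], band[1], x.rate)
    return x.with_samples(_sosfiltfilt_rows(sos, x.samples, x.rate, band[0]))


# ---------------------------------------------------------------------------
# Epoching and averaging


def extract_epochs(
    x: SignalTrace,
    onsets,
    epoch_seconds: float,
    alignment=Alignment.POST_STIMULUS,
) -> TrialSet:
    """Cut fixed-length epochs around stimulation onsets.

    Windows are half-open: ``post_stimulus`` takes ``[onset, onset + N)``
    (the 300 ms stimulation burst is inside the window), ``pre_stimulus``
    takes ``[onset - N, onset)``.  Onsets too close to the recording edge
    are skipped with a logged warning; zero usable onsets is an error.
    """
    alignment = _as_alignment(alignment)
    n_epoch = int(round(epoch_seconds * x.rate))
    if n_epoch < 2:
        raise ValidationError("epoch must span at least 2 samples")
    rows, skipped = [], 0
    for onset in onsets:
        onset = int(onset)
        start = onset if alignment is Alignment.POST_STIMULUS else onset - n_epoch
        stop = start + n_epoch
        if start < 0 or stop > x.n:
            skipped += 1
            log.warning(
                "skipping onset %d: %s window [%d, %d) exceeds trace of %d samples",
                onset, alignment.value, start, stop, x.n,
            )
            continue
        rows.append(x.samples[start:stop])
    if not rows:
        raise ValidationError("no onset admits a full epoch window")
    if skipped:
        log.warning("extract_epochs: %d of %d onsets skipped", skipped, skipped + len(rows))
    arr = np.stack(rows)
    labels = [f"{x.label}:{i}" for i in range(arr.shape[0])]
    return TrialSet.from_array(arr, rate=x.rate, modality=x.modality,
                               alignment=alignment, labels=labels)


def average_trials(t: TrialSet) -> SignalTrace:
    """Pointwise arithmetic mean across trials ("averaged by superposition")."""
    if not t.trials:
        raise ValidationError("cannot average an empty TrialSet")
    mean = t.as_array().mean(axis=0)
    return SignalTrace(mean, rate=t.rate, modality=t.modality,
                       label=f"mean({t.n_trials} trials)")


def build_reference(lfp_sets: list[TrialSet], emg_sets: list[TrialSet]) -> ReferencePair:
    """Grand-mean reference pair from a normal cohort.

    Each element of ``lfp_sets``/``emg_sets`` is one subject's preprocessed
    trials; subjects are first trial-averaged, then averaged across the
    cohort.  A single subject therefore yields that subject's own average.
    """
    if not lfp_sets or not emg_sets:
        raise ValidationError("need at least one subject per modality")
    refs = []
    for sets, want in ((lfp_sets, Modality.LFP), (emg_sets, Modality.EMG)):
        means = []
        for i, ts in enumerate(sets):
            if ts.modality != want:
                raise ValidationError(f"subject {i}: expected {want.value} trials")
            means.append(average_trials(ts).samples)
        lengths = {len(m) for m in means}
        if len(lengths) != 1:
            raise ValidationError(f"{want.value}: subject averages differ in length: {sorted(lengths)}")
        rates = {ts.rate for ts in sets}
        if len(rates) != 1:
            raise ValidationError(f"{want.value}: subjects differ in rate: {sorted(rates)}")
        grand = np.mean(means, axis=0)
        refs.append(SignalTrace(grand, rate=sets[0].rate, modality=want,
                                label=f"reference({len(sets)} subjects)"))
    return ReferencePair(lfp_ref=refs[0], emg_ref=refs[1],
                         n_source_trials=len(lfp_sets))


# ---------------------------------------------------------------------------
# Chain helpers


def preprocess_trials(t: TrialSet, cfg: RunConfig) -> TrialSet:
    """Apply notch -> baseline removal -> bandpass to every trial."""
    if not t.trials:
        raise ValidationError("cannot preprocess an empty TrialSet")
    arr = t.as_array()
    rate = t.rate
    b, a = design_notch(rate, cfg.notch_hz, cfg.notch_q)
    arr = _filtfilt_rows(b, a, arr, rate, cfg.notch_hz / cfg.notch_q)
    k = int(round(cfg.baseline_window_seconds * rate))
    if k < 3:
        raise ValidationError("baseline window shorter than 3 samples")
    arr = arr - uniform_filter1d(arr, size=k, axis=-1, mode="reflect")
    band = cfg.band_for(t.modality)
    sos = design_bandpass(rate, band)
    arr = _sosfiltfilt_rows(sos, arr, rate, band[0])
    log.info(
        "preprocessed %d %s trials (notch %.6g Hz Q=%.6g, baseline %.6g s, band %s Hz)",
        t.n_trials, t.modality.value, cfg.notch_hz, cfg.notch_q,
        cfg.baseline_window_seconds, cfg.band_for(t.modality),
    )
    labels = [tr.label for tr in t.trials]
    return TrialSet.from_array(arr, rate=rate, modality=t.modality,
                               alignment=t.alignment, labels=labels)


def preprocess_and_average(t: TrialSet, cfg: RunConfig) -> SignalTrace:
    """Full per-subject chain: filters then trial averaging."""
    return average_trials(preprocess_trials(t, cfg))


def decimate_trials(t: TrialSet, factor: int) -> TrialSet:
    """Zero-phase FIR decimation of every trial by an integer factor.

    Lossless for content below the new Nyquist; with the 0.5–200 Hz analysis
    bands, decimating 2 kHz recordings down to 500 Hz removes nothing in
    band while shrinking the quadratic DTW cost 16-fold.
    """
    if int(factor) != factor or factor < 1:
        raise ValidationError("decimation factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return t
    arr = sps.decimate(t.as_array(), factor, ftype="fir", zero_phase=True, axis=-1)
    labels = [tr.label for tr in t.trials]
    return TrialSet.from_array(arr, rate=t.rate / factor, modality=t.modality,
                               alignment=t.alignment, labels=labels)
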