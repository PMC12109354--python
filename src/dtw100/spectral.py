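"""Frequency-domain (FRE DTW-100) pathway.

Spectra are single full-epoch one-sided DFT magnitudes — no Welch
segmenting, no taper — so bin frequencies are exact (0.25 Hz for a 4 s
epoch at 2 kHz) and a 40 Hz oscillation lands on the 40.0 Hz bin.  The
stored magnitudes are raw ``|rfft(x)|`` values; with that convention
Parseval's identity reads

    2 * sum|X_k|^2 - |X_0|^2 - |X_Nyquist|^2 == N * sum x_n^2

(the Nyquist term only exists for even N).  Scoring runs the identical
DTW -> normalize -> percentage chain as the time domain, on spectra
restricted to the configured analysis band; by default it compares raw
magnitudes ("amplitude" spectra), with power and dB scales available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dtw_core import dtw_distance
from .errors import ValidationError
from .preprocess import ReferencePair
from .scoring import ScoreCard, composite_score, dtw100_score
from .signal_io import Modality, RunConfig, SignalTrace

__all__ = [
    "SpectrumTrace",
    "magnitude_spectrum",
    "decimate_bins",
    "spectrum_values",
    "pair_norm_distances_spectral",
    "score_sample_spectral",
    "write_spectrum",
]


@dataclass
class SpectrumTrace:
    """One-sided magnitude spectrum restricted to an analysis band."""

    freqs: np.ndarray
    magnitudes: np.ndarray
    modality: Modality
    resolution_hz: float

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.magnitudes = np.asarray(self.magnitudes, dtype=np.float64)
        if self.freqs.size != self.magnitudes.size:
            raise ValidationError("freqs and magnitudes must have equal length")
        if self.freqs.size < 1:
            raise ValidationError("empty spectrum")
        if np.any(self.magnitudes < 0):
            raise ValidationError("magnitudes must be non-negative")
        df = np.diff(self.freqs)
        if self.freqs.size > 1 and (
            np.any(df <= 0) or not np.allclose(df, self.resolution_hz, rtol=1e-9)
        ):
            raise ValidationError("freqs must increase uniformly by resolution_hz")


def magnitude_spectrum(x: SignalTrace, band: tuple[float, float] | None = None) -> SpectrumTrace:
    """One-sided DFT magnitude spectrum of the full epoch.

    ``band=(low, high)`` keeps only bins with ``low <= f <= high``; ``None``
    keeps the full one-sided spectrum (DC through Nyquist).
    """
    n = x.n
    freqs = np.fft.rfftfreq(n, d=1.0 / x.rate)
    mags = np.abs(np.fft.rfft(x.samples))
    if band is not None:
        low, high = float(band[0]), float(band[1])
        if not 0 <= low < high:
            raise ValidationError(f"band must satisfy 0 <= low < high, got {band}")
        if high > x.rate / 2:
            raise ValidationError(f"band edge {high} Hz exceeds Nyquist {x.rate / 2} Hz")
        mask = (freqs >= low) & (freqs <= high)
        if not mask.any():
            raise ValidationError(f"band {band} contains no spectral bins")
        freqs, mags = freqs[mask], mags[mask]
    return SpectrumTrace(freqs, mags, modality=x.modality, resolution_hz=x.rate / n)


def decimate_bins(s: SpectrumTrace, factor: int) -> SpectrumTrace:
    """Average adjacent bins by ``factor`` (bounds the spectral DTW cost)."""
    if int(factor) != factor or factor < 1:
        raise ValidationError("bin decimation factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return s
    keep = (s.freqs.size // factor) * factor
    if keep == 0:
        raise ValidationError(f"spectrum of {s.freqs.size} bins too short to decimate by {factor}")
    f = s.freqs[:keep].reshape(-1, factor).mean(axis=1)
    m = s.magnitudes[:keep].reshape(-1, factor).mean(axis=1)
    return SpectrumTrace(f, m, modality=s.modality, resolution_hz=s.resolution_hz * factor)


def spectrum_values(s: SpectrumTrace, scale: str = "magnitude") -> np.ndarray:
    """Spectrum on the requested comparison scale: magnitude, power or dB."""
    if scale == "magnitude":
        return s.magnitudes.copy()
    if scale == "power":
        return s.magnitudes**2
    if scale == "db":
        top = float(s.magnitudes.max())
        if top == 0.0:
            return np.zeros_like(s.magnitudes)
        floor = top * 1e-8  # -160 dB floor keeps log finite on empty bins
        return 20.0 * np.log10(np.maximum(s.magnitudes, floor))
    raise ValidationError(f"unknown spectrum scale {scale!r}")


def _spectral_values(trace: SignalTrace, cfg: RunConfig) -> np.ndarray:
    band = cfg.spectral_band_for(trace.modality)
    spec = magnitude_spectrum(trace, band)
    spec = decimate_bins(spec, cfg.spectral_decimate)
    return spectrum_values(spec, cfg.spectrum_scale)


def pair_norm_distances_spectral(
    lfp: SignalTrace, emg: SignalTrace, ref: ReferencePair, cfg: RunConfig
) -> tuple[float, float]:
    """Frequency-domain normalized DTW distances (LFP, EMG) vs the reference."""
    for trace, rtrace, want in (
        (lfp, ref.lfp_ref, Modality.LFP),
        (emg, ref.emg_ref, Modality.EMG),
    ):
        if trace.modality != want:
            raise ValidationError(f"expected a {want.value} trace, got {trace.modality.value}")
        if trace.n != rtrace.n or trace.rate != rtrace.rate:
            raise ValidationError(
                f"{want.value}: sample and reference must share length and rate"
            )
    dl = dtw_distance(_spectral_values(lfp, cfg), _spectral_values(ref.lfp_ref, cfg),
                      return_path=False).norm_distance
    de = dtw_distance(_spectral_values(emg, cfg), _spectral_values(ref.emg_ref, cfg),
                      return_path=False).norm_distance
    return dl, de


def score_sample_spectral(
    lfp: SignalTrace,
    emg: SignalTrace,
    ref: ReferencePair,
    cfg: RunConfig,
    *,
    phase: str = "pre",
    sample_id: str | None = None,
    coefficient_A: float | None = None,
) -> ScoreCard:
    """FRE DTW-100 scoring: the time-domain chain applied to magnitude spectra.

    The spectral domain has its own coefficient A (distances live on a very
    different scale from time-domain ones); supply it here or via config.
    """
    A = coefficient_A if coefficient_A is not None else cfg.coefficient_A
    if A is None:
        raise ValidationError(
            "coefficient A is not set; pass coefficient_A or calibrate it first"
        )
    dl, de = pair_norm_distances_spectral(lfp, emg, ref, cfg)
    ls = dtw100_score(dl, A)
    es = dtw100_score(de, A)
    return ScoreCard(
        sample_id=sample_id or lfp.label or "sample",
        lfp_score=ls,
        emg_score=es,
        composite=composite_score(ls, es, cfg.composite_weight),
        domain="frequency",
        phase=phase,
        coefficient_A=float(A),
    )


def write_spectrum(s: SpectrumTrace, path) -> None:
    """Two-column delimited text export: frequency (Hz), magnitude."""
    np.savetxt(path, np.column_stack([s.freqs, s.magnitudes]),
               fmt="%.17g", delimiter=",", header="freq_hz,magnitude", comments="")
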