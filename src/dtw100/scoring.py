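"""Percentage (DTW-100) scoring of a sample pair against the healthy reference.

A length-normalized DTW distance ``d`` maps to a percentage score

    score = 100 * (1 - A * d),   clamped to [0, 100]

where ``A`` is an adjustable positive coefficient.  The raw formula can go
negative for very dissimilar signals; a percentage scoring function must
stay within [0, 100], so scores are clamped.  The LFP and EMG scores are
combined into a weighted composite (default weights 0.5/0.5).

``A`` is a single shared coefficient per domain (same for LFP and EMG);
the time and frequency domains are calibrated separately because their
distances live on very different scales.  The default calibration policy
maps the worst pre-stimulation distance to a floor score of 0, which makes
a run self-contained and reproducible without an externally supplied A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .dtw_core import dtw_distance
from .errors import ValidationError
from .preprocess import ReferencePair
from .signal_io import Modality, RunConfig, SignalTrace

__all__ = [
    "ScoreCard",
    "dtw100_score",
    "calibrate_A",
    "composite_score",
    "score_sample",
    "pair_norm_distances",
    "write_score_table",
]


@dataclass
class ScoreCard:
    """Per-sample scores: LFP, EMG and the weighted composite, all in [0, 100]."""

    sample_id: str
    lfp_score: float
    emg_score: float
    composite: float
    domain: str  # "time" | "frequency"
    phase: str  # "pre" | "post"
    coefficient_A: float


def dtw100_score(norm_distance: float, coefficient_A: float) -> float:
    """Map a normalized DTW distance to a percentage score in [0, 100]."""
    if not coefficient_A > 0:
        raise ValidationError(f"coefficient A must be > 0, got {coefficient_A}")
    if norm_distance < 0:
        raise ValidationError(f"normalized distance must be >= 0, got {norm_distance}")
    return float(np.clip(100.0 * (1.0 - coefficient_A * norm_distance), 0.0, 100.0))


def calibrate_A(norm_distances, floor_score: float = 0.0) -> float:
    """Choose A so the largest calibration distance scores exactly ``floor_score``.

    Every calibration distance then lands in [floor_score, 100].  All-zero
    distances leave A undefined and raise.
    """
    if not 0 <= floor_score < 100:
        raise ValidationError(f"floor_score must be in [0, 100), got {floor_score}")
    d = np.asarray(list(norm_distances), dtype=np.float64)
    if d.size == 0:
        raise ValidationError("need at least one distance to calibrate A")
    if np.any(d < 0):
        raise ValidationError("normalized distances must be >= 0")
    dmax = float(d.max())
    if dmax == 0.0:
        raise ValidationError("all calibration distances are zero; A is undefined")
    return (1.0 - floor_score / 100.0) / dmax


def composite_score(lfp_score: float, emg_score: float, weight: float = 0.5) -> float:
    """Weighted combination ``weight * lfp + (1 - weight) * emg``."""
    for name, s in (("lfp_score", lfp_score), ("emg_score", emg_score)):
        if not 0 <= s <= 100:
            raise ValidationError(f"{name} {s} outside [0, 100]")
    if not 0 <= weight <= 1:
        raise ValidationError(f"weight {weight} outside [0, 1]")
    return weight * lfp_score + (1.0 - weight) * emg_score


def _decimated(samples: np.ndarray, q: int) -> np.ndarray:
    if q == 1:
        return samples
    # Zero-phase FIR decimation; after the 0.5-200 Hz preprocessing band any
    # factor keeping Nyquist above 200 Hz removes no in-band content.
    return sps.decimate(samples, q, ftype="fir", zero_phase=True)


def _check_against_reference(trace: SignalTrace, ref: SignalTrace, modality: Modality):
    if trace.modality != modality:
        raise ValidationError(f"expected a {modality.value} trace, got {trace.modality.value}")
    if trace.n != ref.n:
        raise ValidationError(
            f"{modality.value}: sample length {trace.n} != reference length {ref.n}"
        )
    if trace.rate != ref.rate:
        raise ValidationError(
            f"{modality.value}: sample rate {trace.rate} != reference rate {ref.rate}"
        )


def pair_norm_distances(
    lfp: SignalTrace, emg: SignalTrace, ref: ReferencePair, cfg: RunConfig
) -> tuple[float, float]:
    """Time-domain normalized DTW distances (LFP, EMG) of a sample vs the reference."""
    _check_against_reference(lfp, ref.lfp_ref, Modality.LFP)
    _check_against_reference(emg, ref.emg_ref, Modality.EMG)
    q = cfg.time_decimate
    dl = dtw_distance(_decimated(lfp.samples, q), _decimated(ref.lfp_ref.samples, q),
                      return_path=False).norm_distance
    de = dtw_distance(_decimated(emg.samples, q), _decimated(ref.emg_ref.samples, q),
                      return_path=False).norm_distance
    return dl, de


def score_sample(
    lfp: SignalTrace,
    emg: SignalTrace,
    ref: ReferencePair,
    cfg: RunConfig,
    *,
    phase: str = "pre",
    sample_id: str | None = None,
    coefficient_A: float | None = None,
) -> ScoreCard:
    """Time-domain DTW-100 scoring of one preprocessed, trial-averaged pair.

    ``coefficient_A`` overrides ``cfg.coefficient_A``; one of the two must
    be set (calibrate with :func:`calibrate_A` or let the pipeline do it).
    """
    A = coefficient_A if coefficient_A is not None else cfg.coefficient_A
    if A is None:
        raise ValidationError(
            "coefficient A is not set; pass coefficient_A or calibrate it first"
        )
    dl, de = pair_norm_distances(lfp, emg, ref, cfg)
    ls = dtw100_score(dl, A)
    es = dtw100_score(de, A)
    return ScoreCard(
        sample_id=sample_id or lfp.label or "sample",
        lfp_score=ls,
        emg_score=es,
        composite=composite_score(ls, es, cfg.composite_weight),
        domain="time",
        phase=phase,
        coefficient_A=float(A),
    )


def write_score_table(cards, path) -> None:
    """Serialize ScoreCards as a CSV score table (stable row order as given)."""
    lines = ["sample_id,phase,domain,lfp_score,emg_score,composite,coefficient_A"]
    for c in cards:
        lines.append(
            f"{c.sample_id},{c.phase},{c.domain},"
            f"{c.lfp_score:.10g},{c.emg_score:.10g},{c.composite:.10g},"
            f"{c.coefficient_A:.10g}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
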