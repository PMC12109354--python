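"""Synthetic paired LFP/EMG cohorts for the three study regimes.

No public recordings exist for this preparation, so the generator emulates
the descriptive statistics of the three cohorts the pipeline must separate:

* ``normal`` — LFP slightly stronger than EMG (peak ratio ~1.2), energy
  concentrated near 40 Hz (~70% of LFP power in the 35-45 Hz band).
* ``bcao_pre`` — global-ischemia model before stimulation: LFP peaks ~3x
  EMG, broadband (energy NOT concentrated at 40 Hz), markedly increased
  inter-trial variability and phase jitter.
* ``bcao_post`` — after low-intensity pulsed ultrasound: LFP 40 Hz-
  concentrated again with a bimodal amplitude envelope across the epoch,
  EMG strongly suppressed (time-domain LFP/EMG peak ratio ~100).

Signal model: each trial is a stimulation-locked 40 Hz oscillation mixed
with band-limited 1/f ("pink") noise, weighted by the regime's spectral
concentration, peak-normalized to the regime amplitude with per-trial
jitter.  EMG is 10-200 Hz noise amplitude-modulated by the cortical
oscillation (envelope coupling) plus a small phase-locked 40 Hz component
standing in for cortico-muscular coherence.  The oscillation's base phase
is locked to the stimulation onset (phase 0 for every subject) with
per-trial Gaussian jitter, so trial averaging and the cross-subject grand
mean retain the oscillatory waveform — without phase locking, averaging by
superposition would cancel it and no meaningful reference would exist.

Determinism: a cohort is a pure function of (spec, seed).  Subject streams
are derived as ``SeedSequence(seed, spawn_key=(regime_code, subject_index))``
so the three regimes can share one base seed without stream collisions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError
from .signal_io import Modality, TrialSet, write_trials

__all__ = [
    "REGIMES",
    "CohortSpec",
    "SyntheticCheckReport",
    "generate_subject",
    "generate_cohort",
    "spectral_check",
    "write_study",
]

GAMMA_HZ = 40.0  # stimulation-locked oscillation frequency
CONCENTRATION_BAND = (35.0, 45.0)  # band used to measure 40 Hz concentration

# Regime phenomenology targets.  Amplitudes are in µV; 'lfp_emg_peak_ratio'
# is the within-subject LFP:EMG peak amplitude ratio, 'spectral_concentration'
# the fraction of LFP power in the 35-45 Hz band.
REGIMES = {
    "normal": dict(
        lfp_emg_peak_ratio=1.2,
        spectral_concentration=0.7,
        lfp_peak_uv=100.0,
        amp_jitter=(0.9, 1.1),
        phase_jitter_rad=0.25,
        emg_locked_fraction=0.08,
        emg_coupling=0.5,
        bimodal_envelope=False,
    ),
    "bcao_pre": dict(
        lfp_emg_peak_ratio=3.0,
        spectral_concentration=0.2,
        lfp_peak_uv=400.0,
        amp_jitter=(0.7, 1.5),
        phase_jitter_rad=0.5,
        emg_locked_fraction=0.05,
        emg_coupling=0.15,
        bimodal_envelope=False,
    ),
    "bcao_post": dict(
        lfp_emg_peak_ratio=100.0,
        spectral_concentration=0.7,
        lfp_peak_uv=110.0,
        amp_jitter=(0.95, 1.05),
        phase_jitter_rad=0.3,
        emg_locked_fraction=0.08,
        emg_coupling=0.4,
        bimodal_envelope=True,
    ),
}
_REGIME_CODE = {"normal": 0, "bcao_pre": 1, "bcao_post": 2}

# Acceptance bands for the self-check: (concentration predicate, ratio band).
_CHECKS = {
    "normal": (("ge", 0.5), (1.05, 1.5)),
    "bcao_pre": (("le", 0.35), (2.5, 3.5)),
    "bcao_post": (("ge", 0.5), (80.0, 120.0)),
}


@dataclass
class CohortSpec:
    """Generator parameters for one cohort.

    Fields left ``None`` take the regime default from :data:`REGIMES`.
    ``noise_sigma`` is additive wide-band sensor noise (µV RMS) on top of
    the physiological mixture; it defaults to 0 because in-band noise is
    already governed by ``spectral_concentration``.
    """

    regime: str
    n_subjects: int = 9
    n_trials: int = 30
    rate: float = 2000.0
    epoch_seconds: float = 4.0
    lfp_emg_peak_ratio: float | None = None
    spectral_concentration: float | None = None
    noise_sigma: float = 0.0
    seed: int = 0
    lfp_peak_uv: float | None = None
    amp_jitter: tuple[float, float] | None = None
    phase_jitter_rad: float | None = None
    emg_locked_fraction: float | None = None
    emg_coupling: float | None = None
    bimodal_envelope: bool | None = None

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValidationError(
                f"unknown regime {self.regime!r}; expected one of {sorted(REGIMES)}"
            )
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ValidationError("n_subjects and n_trials must be >= 1")
        if self.rate <= 0 or self.epoch_seconds <= 0:
            raise ValidationError("rate and epoch_seconds must be > 0")
        defaults = REGIMES[self.regime]
        for key, value in defaults.items():
            if getattr(self, key) is None:
                setattr(self, key, value)
        if not 0 <= self.spectral_concentration <= 1:
            raise ValidationError("spectral_concentration must be in [0, 1]")
        if self.lfp_emg_peak_ratio <= 0:
            raise ValidationError("lfp_emg_peak_ratio must be > 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_seconds * self.rate))


def _band_noise(rng: np.random.Generator, trials: int, n: int, rate: float,
                band: tuple[float, float], pink: bool) -> np.ndarray:
    """(trials, n) unit-RMS band-limited Gaussian noise, 1/f-shaped when ``pink``.

    Synthesized in the frequency domain: complex-Gaussian bins (Rayleigh
    amplitudes, uniform phases) under the band envelope, inverse-transformed.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.zeros_like(freqs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    shape[mask] = freqs[mask] ** -0.5 if pink else 1.0
    z = rng.standard_normal((trials, freqs.size, 2))
    spectrum = shape * (z[..., 0] + 1j * z[..., 1])
    spectrum[:, 0] = 0.0
    x = np.fft.irfft(spectrum, n=n, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return np.divide(x, rms, out=x, where=rms > 0)


def _bimodal_envelope(t: np.ndarray) -> np.ndarray:
    """Mild two-hump amplitude envelope across the epoch (mean ~1)."""
    span = t[-1] if t[-1] > 0 else 1.0
    g1 = np.exp(-0.5 * ((t - 0.3 * span) / (0.12 * span)) ** 2)
    g2 = np.exp(-0.5 * ((t - 0.7 * span) / (0.12 * span)) ** 2)
    return 0.75 + 0.5 * (g1 + g2)


def _subject_rng(spec: CohortSpec, subject_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(spec.seed,
                                spawn_key=(_REGIME_CODE[spec.regime], subject_index))
    return np.random.default_rng(ss)


def generate_subject(spec: CohortSpec, subject_index: int) -> tuple[TrialSet, TrialSet]:
    """One subject's paired trials: (LFP TrialSet, EMG TrialSet)."""
    if subject_index < 0:
        raise ValidationError("subject_index must be >= 0")
    rng = _subject_rng(spec, subject_index)
    n = spec.n_samples
    t = np.arange(n) / spec.rate
    c = spec.spectral_concentration
    c_emg = spec.emg_locked_fraction
    emg_peak = spec.lfp_peak_uv / spec.lfp_emg_peak_ratio
    envelope = _bimodal_envelope(t) if spec.bimodal_envelope else np.ones_like(t)

    # Stimulation-locked oscillation: base phase 0, per-trial jitter.
    phis = rng.normal(0.0, spec.phase_jitter_rad, (spec.n_trials, 1))
    arg = 2.0 * np.pi * GAMMA_HZ * t + phis
    tones = np.sqrt(2.0) * np.sin(arg)  # unit RMS per trial

    pink = _band_noise(rng, spec.n_trials, n, spec.rate, (0.5, 200.0), pink=True)
    lfp_rows = (np.sqrt(c) * tones + np.sqrt(1.0 - c) * pink) * envelope
    peaks = np.max(np.abs(lfp_rows), axis=1)
    jit = rng.uniform(*spec.amp_jitter, spec.n_trials)
    lfp_rows *= (spec.lfp_peak_uv * jit / peaks)[:, None]

    carrier = _band_noise(rng, spec.n_trials, n, spec.rate, (10.0, 200.0), pink=False)
    coupling = 1.0 + spec.emg_coupling * np.sin(arg)
    emg_rows = np.sqrt(c_emg) * tones + np.sqrt(1.0 - c_emg) * carrier * coupling
    peaks = np.max(np.abs(emg_rows), axis=1)
    jit = rng.uniform(*spec.amp_jitter, spec.n_trials)
    emg_rows *= (emg_peak * jit / peaks)[:, None]

    if spec.noise_sigma > 0:
        lfp_rows = lfp_rows + rng.normal(0.0, spec.noise_sigma, lfp_rows.shape)
        emg_rows = emg_rows + rng.normal(0.0, spec.noise_sigma, emg_rows.shape)

    sid = f"{spec.regime}:{subject_index}"
    labels = [f"{sid}:t{i}" for i in range(spec.n_trials)]
    lfp_ts = TrialSet.from_array(lfp_rows, rate=spec.rate, modality=Modality.LFP, labels=labels)
    emg_ts = TrialSet.from_array(emg_rows, rate=spec.rate, modality=Modality.EMG, labels=labels)
    return lfp_ts, emg_ts


def generate_cohort(spec: CohortSpec) -> list[tuple[TrialSet, TrialSet]]:
    """All subjects of a cohort, deterministically seeded per subject."""
    return [generate_subject(spec, i) for i in range(spec.n_subjects)]


@dataclass
class SyntheticCheckReport:
    """Measured phenomenology of one generated subject vs its regime targets."""

    regime: str
    concentration: float  # LFP power fraction in the 35-45 Hz band
    peak_ratio: float  # max|LFP| / max|EMG| across all trials
    concentration_ok: bool
    ratio_ok: bool

    @property
    def passed(self) -> bool:
        return self.concentration_ok and self.ratio_ok


def spectral_check(pair: tuple[TrialSet, TrialSet], spec: CohortSpec) -> SyntheticCheckReport:
    """Verify a generated pair reproduces the regime's amplitude/spectral targets."""
    lfp_ts, emg_ts = pair
    lfp = lfp_ts.as_array()
    emg = emg_ts.as_array()
    freqs = np.fft.rfftfreq(lfp.shape[1], d=1.0 / lfp_ts.rate)
    power = np.abs(np.fft.rfft(lfp, axis=1)) ** 2
    lo, hi = CONCENTRATION_BAND
    in_band = (freqs >= lo) & (freqs <= hi)
    analysis = (freqs >= 0.5) & (freqs <= 200.0)
    total = power[:, analysis].sum(axis=1)
    frac = np.where(total > 0, power[:, in_band].sum(axis=1) / total, 0.0)
    concentration = float(frac.mean())
    peak_ratio = float(np.max(np.abs(lfp)) / np.max(np.abs(emg)))

    (op, conc_limit), (rlo, rhi) = _CHECKS[spec.regime]
    conc_ok = concentration >= conc_limit if op == "ge" else concentration <= conc_limit
    return SyntheticCheckReport(
        regime=spec.regime,
        concentration=concentration,
        peak_ratio=peak_ratio,
        concentration_ok=bool(conc_ok),
        ratio_ok=bool(rlo <= peak_ratio <= rhi),
    )


def write_study(
    out_dir,
    seed: int = 0,
    *,
    n_reference: int = 30,
    n_subjects: int = 9,
    n_trials: int = 30,
    rate: float = 2000.0,
    epoch_seconds: float = 4.0,
) -> Path:
    """Write a full synthetic study to disk and return the manifest path.

    Layout: one CSV per subject per modality plus ``manifest.yaml`` listing
    the reference cohort and the pre/post subject cohorts (same subject ids
    pre and post, mirroring repeated measurements on the same animals).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    common = dict(n_trials=n_trials, rate=rate, epoch_seconds=epoch_seconds, seed=seed)
    specs = {
        "normal": CohortSpec("normal", n_subjects=n_reference, **common),
        "bcao_pre": CohortSpec("bcao_pre", n_subjects=n_subjects, **common),
        "bcao_post": CohortSpec("bcao_post", n_subjects=n_subjects, **common),
    }

    def _dump(prefix: str, idx: int, pair) -> dict:
        entry = {}
        for mod, ts in zip(("lfp", "emg"), pair):
            fname = f"{prefix}{idx:02d}_{mod}.csv"
            write_trials(ts, out_dir / fname)
            entry[mod] = fname
        return entry

    reference = []
    for i, pair in enumerate(generate_cohort(specs["normal"])):
        reference.append({"id": f"n{i:02d}", **_dump("n", i, pair)})
    subjects = []
    for phase, regime, prefix in (("pre", "bcao_pre", "pre"), ("post", "bcao_post", "post")):
        for i, pair in enumerate(generate_cohort(specs[regime])):
            subjects.append({"id": f"s{i}", "phase": phase, **_dump(prefix, i, pair)})

    manifest = {
        "rate": rate,
        "epoch_seconds": epoch_seconds,
        "seed": seed,
        "reference": reference,
        "subjects": subjects,
    }
    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path
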