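"""Core signal containers and delimited-text / config I/O.

Trial data live in plain delimited text (comma or tab, auto-detected): one
column per trial, one row per sample, optional single header row.  Amplitudes
are treated as microvolts throughout but never rescaled — scoring is
unit-consistent as long as sample and reference share units.

The run configuration is a flat YAML mapping; missing keys fall back to the
study defaults (50 Hz notch, 0.5–200 Hz LFP band, 10–200 Hz EMG band, 4 s
epochs, 0.5/0.5 composite weight, 2 kHz sampling).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import DataFormatError, ValidationError

__all__ = [
    "Modality",
    "Alignment",
    "SignalTrace",
    "TrialSet",
    "RunConfig",
    "read_trials",
    "write_trials",
    "load_config",
    "dump_config",
]


class Modality(str, enum.Enum):
    """Recording channel type: cortical field potential or muscle activity."""

    LFP = "LFP"
    EMG = "EMG"


class Alignment(str, enum.Enum):
    """Epoch placement relative to the stimulation onset."""

    PRE_STIMULUS = "pre_stimulus"
    POST_STIMULUS = "post_stimulus"


def _as_modality(value) -> Modality:
    if isinstance(value, Modality):
        return value
    try:
        return Modality(str(value).upper())
    except ValueError:
        raise ValidationError(f"unknown modality: {value!r} (expected LFP or EMG)") from None


def _as_alignment(value) -> Alignment:
    if isinstance(value, Alignment):
        return value
    try:
        return Alignment(str(value).lower())
    except ValueError:
        raise ValidationError(
            f"unknown alignment: {value!r} (expected pre_stimulus or post_stimulus)"
        ) from None


@dataclass
class SignalTrace:
    """One channel's uniformly sampled values.

    Parameters
    ----------
    samples
        Ordered real amplitudes (µV).  At least two samples.
    rate
        Sampling frequency in Hz, strictly positive.  All downstream band
        edges must lie below ``rate / 2``.
    modality
        ``Modality.LFP`` or ``Modality.EMG``.
    label
        Free-text subject/sample identifier.
    """

    samples: np.ndarray
    rate: float
    modality: Modality
    label: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValidationError("SignalTrace samples must be one-dimensional")
        if self.samples.size < 2:
            raise ValidationError("SignalTrace needs at least 2 samples")
        self.rate = float(self.rate)
        if not self.rate > 0:
            raise ValidationError(f"sampling rate must be > 0, got {self.rate}")
        self.modality = _as_modality(self.modality)
        self.label = str(self.label)

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Epoch duration in seconds."""
        return self.n / self.rate

    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n) / self.rate

    def with_samples(self, samples: np.ndarray) -> "SignalTrace":
        """Copy of this trace with new sample values (same rate/modality/label)."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


@dataclass
class TrialSet:
    """Stack of equal-length epochs from repeated stimulation trials.

    All trials must share length, rate and modality, and the length in
    samples must equal ``round(epoch_seconds * rate)``.  An empty trial list
    is representable (operations that need data raise on it).
    """

    trials: list[SignalTrace]
    epoch_seconds: float
    alignment: Alignment = Alignment.POST_STIMULUS

    def __post_init__(self):
        self.trials = list(self.trials)
        self.epoch_seconds = float(self.epoch_seconds)
        self.alignment = _as_alignment(self.alignment)
        if self.epoch_seconds <= 0:
            raise ValidationError("epoch_seconds must be > 0")
        if self.trials:
            first = self.trials[0]
            for i, t in enumerate(self.trials):
                if t.n != first.n:
                    raise ValidationError(
                        f"trial {i} has {t.n} samples, expected {first.n}"
                    )
                if t.rate != first.rate:
                    raise ValidationError(f"trial {i} rate {t.rate} != {first.rate}")
                if t.modality != first.modality:
                    raise ValidationError(
                        f"trial {i} modality {t.modality} != {first.modality}"
                    )
            expected = round(self.epoch_seconds * first.rate)
            if first.n != expected:
                raise ValidationError(
                    f"trial length {first.n} != round(epoch_seconds*rate) = {expected}"
                )

    @classmethod
    def from_array(
        cls,
        arr: np.ndarray,
        rate: float,
        modality,
        alignment=Alignment.POST_STIMULUS,
        labels: list[str] | None = None,
    ) -> "TrialSet":
        """Build a TrialSet from a (n_trials, n_samples) array."""
        arr = np.asarray(arr, dtype=np.float64)
        if arr.ndim != 2:
            raise ValidationError("expected a 2-D (n_trials, n_samples) array")
        if labels is None:
            labels = [f"trial{i:02d}" for i in range(arr.shape[0])]
        trials = [
            SignalTrace(row, rate=rate, modality=modality, label=lab)
            for row, lab in zip(arr, labels)
        ]
        return cls(trials, epoch_seconds=arr.shape[1] / rate, alignment=alignment)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_samples(self) -> int:
        if not self.trials:
            raise ValidationError("empty TrialSet has no sample length")
        return self.trials[0].n

    @property
    def rate(self) -> float:
        if not self.trials:
            raise ValidationError("empty TrialSet has no rate")
        return self.trials[0].rate

    @property
    def modality(self) -> Modality:
        if not self.trials:
            raise ValidationError("empty TrialSet has no modality")
        return self.trials[0].modality

    def as_array(self) -> np.ndarray:
        """Trials stacked as a (n_trials, n_samples) float array."""
        if not self.trials:
            raise ValidationError("empty TrialSet")
        return np.stack([t.samples for t in self.trials])


_SPECTRUM_SCALES = ("magnitude", "power", "db")


@dataclass(frozen=True)
class RunConfig:
    """Run-wide analysis parameters with study defaults.

    ``coefficient_A`` is the adjustable scaling of the percentage score; when
    left ``None`` it is calibrated per domain against the pre-stimulation
    cohort (worst pre-stimulation sample scores ``0``).  ``spectral_band``
    of ``None`` mirrors each modality's time-domain filter band.
    """

    rate: float = 2000.0
    notch_hz: float = 50.0
    notch_q: float = 30.0
    lfp_band: tuple[float, float] = (0.5, 200.0)
    emg_band: tuple[float, float] = (10.0, 200.0)
    epoch_seconds: float = 4.0
    baseline_window_seconds: float = 1.0
    coefficient_A: float | None = None
    composite_weight: float = 0.5
    spectral_band: tuple[float, float] | None = None
    spectrum_scale: str = "magnitude"
    time_decimate: int = 1
    spectral_decimate: int = 1
    seed: int = 0

    def __post_init__(self):
        if not self.rate > 0:
            raise ValidationError("rate: must be > 0")
        nyquist = self.rate / 2.0
        if not 0 < self.notch_hz < nyquist:
            raise ValidationError(f"notch_hz: {self.notch_hz} not in (0, rate/2)")
        if not self.notch_q > 0:
            raise ValidationError("notch_q: must be > 0")
        for key in ("lfp_band", "emg_band", "spectral_band"):
            band = getattr(self, key)
            if band is None:
                continue
            band = (float(band[0]), float(band[1]))
            object.__setattr__(self, key, band)
            low, high = band
            if not 0 < low < high:
                raise ValidationError(f"{key}: need 0 < low < high, got {band}")
            if not high < nyquist:
                raise ValidationError(
                    f"{key}: high edge {high} Hz >= Nyquist {nyquist} Hz"
                )
        if not self.epoch_seconds > 0:
            raise ValidationError("epoch_seconds: must be > 0")
        if not 0 < self.baseline_window_seconds <= self.epoch_seconds:
            raise ValidationError(
                "baseline_window_seconds: must be in (0, epoch_seconds]"
            )
        if self.coefficient_A is not None and not self.coefficient_A > 0:
            raise ValidationError("coefficient_A: must be > 0 when set")
        if not 0.0 <= self.composite_weight <= 1.0:
            raise ValidationError(
                f"composite_weight: {self.composite_weight} not in [0, 1]"
            )
        if self.spectrum_scale not in _SPECTRUM_SCALES:
            raise ValidationError(
                f"spectrum_scale: {self.spectrum_scale!r} not in {_SPECTRUM_SCALES}"
            )
        for key in ("time_decimate", "spectral_decimate"):
            v = getattr(self, key)
            if int(v) != v or v < 1:
                raise ValidationError(f"{key}: must be a positive integer")
            object.__setattr__(self, key, int(v))

    def band_for(self, modality) -> tuple[float, float]:
        """Time-domain filter band for a modality."""
        return self.lfp_band if _as_modality(modality) is Modality.LFP else self.emg_band

    def spectral_band_for(self, modality) -> tuple[float, float]:
        """Analysis band for spectra; mirrors the filter band unless pinned."""
        if self.spectral_band is not None:
            return self.spectral_band
        return self.band_for(modality)


# ---------------------------------------------------------------------------
# Trial-matrix I/O


def _detect_delimiter(line: str) -> str | None:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # whitespace


def _is_numeric_row(cells: list[str]) -> bool:
    try:
        for c in cells:
            float(c)
    except ValueError:
        return False
    return bool(cells)


def _split(line: str, delim: str | None) -> list[str]:
    line = line.strip()
    return line.split(delim) if delim else line.split()


def _diagnose(path: Path, delim: str | None, skiprows: int) -> None:
    """Slow second pass locating the defect np.loadtxt choked on."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= skiprows or not line.strip():
                continue
            rows.append((lineno, _split(line, delim)))
    if not rows:
        raise DataFormatError(f"{path}: no data rows")
    width = len(rows[0][1])
    for lineno, cells in rows:
        if len(cells) != width:
            raise DataFormatError(
                f"{path}: ragged columns — row {lineno} has {len(cells)} fields but "
                f"{width} trial columns were established by the first data row"
            )
    for lineno, cells in rows:
        for col, cell in enumerate(cells, start=1):
            try:
                float(cell)
            except ValueError:
                raise DataFormatError(
                    f"{path}: non-numeric value {cell!r} at row {lineno}, column {col}"
                ) from None


def read_trials(
    path,
    rate: float,
    modality,
    *,
    orientation: str = "columns",
    alignment=Alignment.POST_STIMULUS,
) -> TrialSet:
    """Read a delimited-text trial matrix.

    ``orientation="columns"`` (the default, and the on-disk convention of
    :func:`write_trials`) means one column per trial and one row per sample;
    ``"rows"`` transposes.  The orientation is an explicit flag, never
    guessed from the data.  A single non-numeric header row is tolerated.
    """
    path = Path(path)
    if orientation not in ("columns", "rows"):
        raise ValidationError(f"orientation must be 'columns' or 'rows', got {orientation!r}")
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
    if not first:
        raise DataFormatError(f"{path}: file is empty")
    delim = _detect_delimiter(first)
    skiprows = 0 if _is_numeric_row(_split(first, delim)) else 1
    try:
        arr = np.loadtxt(path, delimiter=delim, skiprows=skiprows, ndmin=2)
    except ValueError:
        _diagnose(path, delim, skiprows)
        raise  # diagnosis found nothing; re-raise the original error
    if arr.size == 0:
        raise DataFormatError(f"{path}: no data rows")
    if orientation == "columns":
        arr = arr.T  # -> (n_trials, n_samples)
    if arr.shape[1] < 2:
        raise DataFormatError(f"{path}: trials need at least 2 samples, got {arr.shape[1]}")
    labels = [f"{path.stem}:{i}" for i in range(arr.shape[0])]
    return TrialSet.from_array(arr, rate=rate, modality=modality, alignment=alignment, labels=labels)


def write_trials(t: TrialSet, path) -> None:
    """Write a TrialSet as delimited text, one column per trial.

    Values are written with ``%.17g`` so a read/write round trip reproduces
    float64 samples exactly.  Delimiter is a tab for ``.tsv`` paths, comma
    otherwise.
    """
    if not t.trials:
        raise ValidationError("refusing to write an empty TrialSet")
    path = Path(path)
    delim = "\t" if path.suffix.lower() == ".tsv" else ","
    arr = t.as_array().T  # (n_samples, n_trials): one column per trial
    np.savetxt(path, arr, fmt="%.17g", delimiter=delim)


# ---------------------------------------------------------------------------
# Config I/O

_CONFIG_KEYS = {f.name for f in fields(RunConfig)}
_BAND_KEYS = ("lfp_band", "emg_band", "spectral_band")


def load_config(path) -> RunConfig:
    """Load a flat YAML config; missing keys take the study defaults."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a flat key-value mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValidationError(f"{path}: unknown config key(s): {sorted(unknown)}")
    for key in _BAND_KEYS:
        if raw.get(key) is not None:
            band = raw[key]
            if not (isinstance(band, (list, tuple)) and len(band) == 2):
                raise ValidationError(f"{path}: {key} must be a [low, high] pair")
            raw[key] = (float(band[0]), float(band[1]))
    return RunConfig(**raw)


def dump_config(cfg: RunConfig, path) -> None:
    """Write a RunConfig as flat YAML (inverse of :func:`load_config`)."""
    out = {}
    for f in fields(RunConfig):
        v = getattr(cfg, f.name)
        if isinstance(v, tuple):
            v = list(v)
        out[f.name] = v
    Path(path).write_text(yaml.safe_dump(out, sort_keys=True))
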