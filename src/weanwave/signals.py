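"""Data model and I/O for spontaneous-breathing-trial (SBT) record bundles.

An :class:`SbtRecord` holds everything recorded for one patient during a
30-minute SBT: high-rate waveform channels (ECG, photoplethysmogram,
respiratory impedance, arterial blood pressure), per-second numeric vitals
(heart rate, respiratory rate, mean arterial pressure), a per-breath
ventilator series (tidal volume, inspiratory/expiratory time) and the
weaning outcome label.

Records round-trip losslessly through a plain-text bundle directory
(``metadata.json`` plus one CSV per channel), and two preprocessing steps
prepare them for feature extraction: anti-aliased down-sampling of
waveforms to a common rate (62.5 Hz by default) and cropping of every
channel to the middle analysis window of the trial.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import firwin, resample_poly

__all__ = [
    "WAVEFORM_NAMES",
    "NUMERIC_NAMES",
    "LABELS",
    "WaveformChannel",
    "NumericChannel",
    "BreathSeries",
    "SbtRecord",
    "read_record",
    "write_record",
    "downsample",
    "middle_window",
]

WAVEFORM_NAMES = ("ECG", "PPG", "RESP_IMP", "ABP")
NUMERIC_NAMES = ("HR", "RR", "MAP")
LABELS = ("success", "failure", "unknown")

#: Common waveform rate used by the analysis.
DEFAULT_WAVEFORM_RATE = 62.5

# Float format that round-trips IEEE doubles exactly through text.
_FLOAT_FMT = "%.17g"


class BundleError(ValueError):
    """Raised when a record bundle is malformed or inconsistent."""


def _as_float_array(values, *, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name}: samples must be one-dimensional")
    bad = np.flatnonzero(~np.isfinite(arr))
    if bad.size:
        raise ValueError(
            f"{name}: non-finite sample at index {int(bad[0])}"
        )
    return arr


@dataclass(frozen=True)
class WaveformChannel:
    """One continuously sampled waveform (ECG, PPG, RESP_IMP or ABP).

    Time is implicit: sample ``i`` is at ``start_offset + i / sampling_rate``
    seconds from the start of the SBT.
    """

    name: str
    sampling_rate: float
    samples: np.ndarray
    start_offset: float = 0.0

    def __post_init__(self):
        if self.name not in WAVEFORM_NAMES:
            raise ValueError(f"unknown waveform channel {self.name!r}")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(
            self, "samples", _as_float_array(self.samples, name=self.name)
        )

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    def __eq__(self, other) -> bool:
        if not isinstance(other, WaveformChannel):
            return NotImplemented
        return (
            self.name == other.name
            and self.sampling_rate == other.sampling_rate
            and self.start_offset == other.start_offset
            and np.array_equal(self.samples, other.samples)
        )


@dataclass(frozen=True)
class NumericChannel:
    """A low-rate numeric vital series (HR, RR or MAP), 1 Hz by default."""

    name: str
    samples: np.ndarray
    sampling_rate: float = 1.0
    start_offset: float = 0.0

    def __post_init__(self):
        if self.name not in NUMERIC_NAMES:
            raise ValueError(f"unknown numeric channel {self.name!r}")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        arr = _as_float_array(self.samples, name=self.name)
        if np.any(arr < 0):
            raise ValueError(f"{self.name}: values must be nonnegative")
        object.__setattr__(self, "samples", arr)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    def __eq__(self, other) -> bool:
        if not isinstance(other, NumericChannel):
            return NotImplemented
        return (
            self.name == other.name
            and self.sampling_rate == other.sampling_rate
            and self.start_offset == other.start_offset
            and np.array_equal(self.samples, other.samples)
        )


@dataclass(frozen=True)
class BreathSeries:
    """Per-breath ventilator parameters over the trial.

    ``onset_s`` are breath-onset times in seconds from SBT start (strictly
    increasing), ``tidal_volume_ml`` in millilitres, inspiratory and
    expiratory times in seconds.
    """

    onset_s: np.ndarray
    tidal_volume_ml: np.ndarray
    insp_time_s: np.ndarray
    exp_time_s: np.ndarray

    def __post_init__(self):
        onset = _as_float_array(self.onset_s, name="breaths.onset_s")
        tv = _as_float_array(self.tidal_volume_ml, name="breaths.tidal_volume_ml")
        ti = _as_float_array(self.insp_time_s, name="breaths.insp_time_s")
        te = _as_float_array(self.exp_time_s, name="breaths.exp_time_s")
        n = len(onset)
        if not (len(tv) == len(ti) == len(te) == n):
            raise ValueError("breath series columns must have equal length")
        if n and np.any(np.diff(onset) <= 0):
            raise ValueError("breath onsets must be strictly increasing")
        if np.any(ti <= 0) or np.any(te <= 0):
            raise ValueError("inspiratory and expiratory times must be positive")
        if np.any(tv < 0):
            raise ValueError("tidal volume must be nonnegative")
        for attr, arr in (
            ("onset_s", onset),
            ("tidal_volume_ml", tv),
            ("insp_time_s", ti),
            ("exp_time_s", te),
        ):
            object.__setattr__(self, attr, arr)

    @classmethod
    def empty(cls) -> "BreathSeries":
        z = np.empty(0)
        return cls(z, z, z, z)

    def __len__(self) -> int:
        return len(self.onset_s)

    @property
    def ie_ratio(self) -> np.ndarray:
        """Inspiratory-to-expiratory time ratio, one value per breath."""
        return self.insp_time_s / self.exp_time_s

    def restrict(self, t0: float, t1: float, *, shift: bool = True) -> "BreathSeries":
        """Breaths whose onset lies in ``[t0, t1)``, optionally re-timed to t0."""
        keep = (self.onset_s >= t0) & (self.onset_s < t1)
        onset = self.onset_s[keep]
        if shift:
            onset = onset - t0
        return BreathSeries(
            onset,
            self.tidal_volume_ml[keep],
            self.insp_time_s[keep],
            self.exp_time_s[keep],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, BreathSeries):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, a), getattr(other, a))
            for a in ("onset_s", "tidal_volume_ml", "insp_time_s", "exp_time_s")
        )


@dataclass
class SbtRecord:
    """One patient's SBT recording with outcome label and metadata."""

    patient_id: str
    label: str = "unknown"
    sbt_duration: float = 1800.0
    waveforms: dict = field(default_factory=dict)
    numerics: dict = field(default_factory=dict)
    breaths: BreathSeries = field(default_factory=BreathSeries.empty)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if not self.sbt_duration > 0:
            raise ValueError("sbt_duration must be positive")
        for name, ch in self.waveforms.items():
            if name != ch.name:
                raise ValueError(f"waveform key {name!r} != channel name {ch.name!r}")
        for name, ch in self.numerics.items():
            if name != ch.name:
                raise ValueError(f"numeric key {name!r} != channel name {ch.name!r}")

    def channel(self, name: str):
        """Look up a channel (waveform or numeric) by name."""
        if name in self.waveforms:
            return self.waveforms[name]
        if name in self.numerics:
            return self.numerics[name]
        raise KeyError(name)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SbtRecord):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.label == other.label
            and self.sbt_duration == other.sbt_duration
            and self.waveforms == other.waveforms
            and self.numerics == other.numerics
            and self.breaths == other.breaths
            and self.metadata == other.metadata
        )


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

def _write_value_csv(path: Path, values: np.ndarray) -> None:
    lines = ["value"]
    lines.extend(_FLOAT_FMT % v for v in values)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def _read_value_csv(path: Path, *, name: str) -> np.ndarray:
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.split("\n") if ln != ""]
    if not lines or lines[0] != "value":
        raise BundleError(f"{path.name}: expected a single 'value' column header")
    try:
        return _as_float_array([float(x) for x in lines[1:]], name=name)
    except ValueError as exc:
        raise BundleError(f"{path.name}: {exc}") from exc


_BREATH_COLUMNS = ("onset_s", "tidal_volume_ml", "insp_time_s", "exp_time_s")


def write_record(record: SbtRecord, path) -> Path:
    """Write ``record`` as a plain-text bundle directory.

    Layout: ``<patient_id>/metadata.json`` plus ``waveform_<NAME>.csv``,
    ``numeric_<NAME>.csv`` (single ``value`` column) and ``breaths.csv``.
    Floating-point payloads are written with enough digits to round-trip
    exactly; two writes of the same record are byte-identical.
    """
    root = Path(path) / record.patient_id
    root.mkdir(parents=True, exist_ok=True)

    meta = {
        "patient_id": record.patient_id,
        "label": record.label,
        "sbt_duration_s": record.sbt_duration,
        "waveforms": {
            name: {
                "sampling_rate_hz": ch.sampling_rate,
                "start_offset_s": ch.start_offset,
                "n_samples": len(ch.samples),
            }
            for name, ch in sorted(record.waveforms.items())
        },
        "numerics": {
            name: {
                "sampling_rate_hz": ch.sampling_rate,
                "start_offset_s": ch.start_offset,
                "n_samples": len(ch.samples),
            }
            for name, ch in sorted(record.numerics.items())
        },
        "n_breaths": len(record.breaths),
        "metadata": record.metadata,
    }
    (root / "metadata.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
        newline="\n",
    )

    for name, ch in record.waveforms.items():
        _write_value_csv(root / f"waveform_{name}.csv", ch.samples)
    for name, ch in record.numerics.items():
        _write_value_csv(root / f"numeric_{name}.csv", ch.samples)

    b = record.breaths
    lines = [",".join(_BREATH_COLUMNS)]
    for i in range(len(b)):
        lines.append(
            ",".join(
                _FLOAT_FMT % v
                for v in (b.onset_s[i], b.tidal_volume_ml[i], b.insp_time_s[i], b.exp_time_s[i])
            )
        )
    (root / "breaths.csv").write_text(
        "\n".join(lines) + "\n", encoding="utf-8", newline="\n"
    )
    return root


def read_record(path) -> SbtRecord:
    """Read and validate a bundle directory written by :func:`write_record`.

    Every channel declared in ``metadata.json`` must be present on disk;
    a missing file, a NaN sample or a sample-count mismatch is a hard
    error naming the offending channel.
    """
    root = Path(path)
    meta_path = root / "metadata.json"
    if not meta_path.is_file():
        raise BundleError(f"{root}: missing metadata.json")
    meta = json.loads(meta_path.read_text(encoding="utf-8"))

    waveforms = {}
    for name, info in meta.get("waveforms", {}).items():
        fp = root / f"waveform_{name}.csv"
        if not fp.is_file():
            raise BundleError(f"{root.name}: declared waveform {name} has no file")
        samples = _read_value_csv(fp, name=name)
        if len(samples) != info["n_samples"]:
            raise BundleError(
                f"{root.name}: waveform {name} has {len(samples)} samples, "
                f"metadata declares {info['n_samples']}"
            )
        waveforms[name] = WaveformChannel(
            name, info["sampling_rate_hz"], samples, info.get("start_offset_s", 0.0)
        )

    numerics = {}
    for name, info in meta.get("numerics", {}).items():
        fp = root / f"numeric_{name}.csv"
        if not fp.is_file():
            raise BundleError(f"{root.name}: declared numeric {name} has no file")
        samples = _read_value_csv(fp, name=name)
        if len(samples) != info["n_samples"]:
            raise BundleError(
                f"{root.name}: numeric {name} has {len(samples)} samples, "
                f"metadata declares {info['n_samples']}"
            )
        numerics[name] = NumericChannel(
            name, samples, info["sampling_rate_hz"], info.get("start_offset_s", 0.0)
        )

    bp = root / "breaths.csv"
    if not bp.is_file():
        raise BundleError(f"{root.name}: missing breaths.csv")
    lines = [ln for ln in bp.read_text(encoding="utf-8").split("\n") if ln != ""]
    if not lines or tuple(lines[0].split(",")) != _BREATH_COLUMNS:
        raise BundleError(f"{root.name}: breaths.csv has unexpected columns")
    rows = [[float(x) for x in ln.split(",")] for ln in lines[1:]]
    if rows:
        cols = np.asarray(rows, dtype=float).T
        breaths = BreathSeries(*cols)
    else:
        breaths = BreathSeries.empty()
    if len(breaths) != meta.get("n_breaths", len(breaths)):
        raise BundleError(f"{root.name}: breath count mismatch with metadata")

    return SbtRecord(
        patient_id=meta["patient_id"],
        label=meta.get("label", "unknown"),
        sbt_duration=meta["sbt_duration_s"],
        waveforms=waveforms,
        numerics=numerics,
        breaths=breaths,
        metadata=meta.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def downsample(channel: WaveformChannel, target_rate: float = DEFAULT_WAVEFORM_RATE) -> WaveformChannel:
    """Anti-aliased rational down-sampling of a waveform channel.

    A linear-phase FIR low-pass with cutoff at 0.8x the Nyquist frequency
    of the target rate is applied inside a polyphase resampler before
    decimation, so that aliased high-frequency content cannot leak into
    downstream entropy estimates.  Non-integer rate ratios (e.g. 250 Hz or
    500 Hz monitors down to 62.5 Hz) are handled by rational resampling.
    Upsampling is refused.
    """
    if target_rate > channel.sampling_rate:
        raise ValueError(
            f"cannot upsample {channel.name} from {channel.sampling_rate} Hz "
            f"to {target_rate} Hz"
        )
    if target_rate == channel.sampling_rate:
        return channel

    ratio = Fraction(target_rate / channel.sampling_rate).limit_denominator(1000)
    up, down = ratio.numerator, ratio.denominator
    # FIR designed at the upsampled rate; 0.8 * target Nyquist expressed as a
    # fraction of the upsampled Nyquist is 0.8 / down.
    # long kaiser FIR keeps the passband flat to ~0.7x the target Nyquist
    # while meeting the 0.8x cutoff
    numtaps = min(64 * down + 1, 8001)
    h = firwin(numtaps, 0.8 / down, window=("kaiser", 8.0))
    resampled = resample_poly(channel.samples, up, down, window=h * up)

    expected = math.ceil(len(channel.samples) * up / down)
    resampled = resampled[:expected]
    return WaveformChannel(channel.name, target_rate, resampled, channel.start_offset)


def middle_window(record: SbtRecord, window_s: float = 600.0) -> SbtRecord:
    """Crop every channel to the centred analysis window of the trial.

    The window is the half-open interval
    ``[(D - w)/2, (D + w)/2)`` of the trial of duration ``D``; with the
    defaults (30-min trial, 10-min window) a 62.5 Hz waveform keeps samples
    37,500..74,999 and a 1 Hz vital keeps 600 samples starting at t=600 s.
    Breath onsets are restricted to the window and re-timed to its start.
    """
    if window_s > record.sbt_duration:
        raise ValueError(
            f"window ({window_s} s) exceeds trial duration ({record.sbt_duration} s)"
        )
    if window_s == record.sbt_duration:
        return record
    t0 = (record.sbt_duration - window_s) / 2.0
    t1 = t0 + window_s

    def crop(ch, cls):
        i0 = int(round((t0 - ch.start_offset) * ch.sampling_rate))
        n = int(round(window_s * ch.sampling_rate))
        if i0 < 0 or i0 + n > len(ch.samples):
            raise ValueError(
                f"channel {ch.name} does not span the analysis window"
            )
        if cls is WaveformChannel:
            return WaveformChannel(ch.name, ch.sampling_rate, ch.samples[i0 : i0 + n], 0.0)
        return NumericChannel(ch.name, ch.samples[i0 : i0 + n], ch.sampling_rate, 0.0)

    return SbtRecord(
        patient_id=record.patient_id,
        label=record.label,
        sbt_duration=window_s,
        waveforms={k: crop(v, WaveformChannel) for k, v in record.waveforms.items()},
        numerics={k: crop(v, NumericChannel) for k, v in record.numerics.items()},
        breaths=record.breaths.restrict(t0, t1),
        metadata={**record.metadata, "window_of": record.sbt_duration, "window_t0_s": t0},
    )
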