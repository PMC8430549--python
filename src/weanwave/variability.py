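"""Variability and complexity feature extractors for SBT biosignals.

Three families of indices are computed from the middle analysis window of
a spontaneous breathing trial:

* **Poincaré geometry** of a lag-1 return map.  For a series
  :math:`x_1,\\dots,x_N` the short-term spread SD1 and long-term spread
  SD2 are the standard deviations of the lagged point cloud
  :math:`(x_n, x_{n+1})` perpendicular to and along the identity line,
  with the closed forms ``SD1^2 = Var(x_{n+1} - x_n) / 2`` and
  ``SD2^2 = Var(x_{n+1} + x_n) / 2`` (population variance).  Applied to
  per-second vitals (HR, RR, MAP) and per-breath ventilator series.

* **Sample entropy** (SampEn), ``-log(A/B)`` where ``B`` counts pairs of
  length-``m`` templates within Chebyshev tolerance ``r`` (self-matches
  excluded) and ``A`` the same for length ``m+1``.  Low values indicate a
  regular, predictable signal.  Applied to the 62.5 Hz waveforms.

* **Detrended fluctuation analysis** (DFA).  The mean-centred series is
  integrated, split into non-overlapping boxes of size ``n``, linearly
  detrended per box, and the RMS residual ``F(n)`` regressed on ``n`` in
  log-log space.  The slope is the scaling exponent: 0.5 for
  uncorrelated noise, above 0.5 for fractal (long-range correlated)
  signals.  ``alpha1`` uses short scales, ``alpha2`` longer scales.

The rapid shallow breathing index (RSBI, breaths/min per litre of tidal
volume) is computed from the per-breath series over the same window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial import cKDTree

from .signals import SbtRecord

__all__ = [
    "PoincareResult",
    "ComplexityResult",
    "DFAResult",
    "FeatureConfig",
    "FeatureVector",
    "poincare",
    "sample_entropy",
    "dfa",
    "rsbi",
    "extract_features",
    "FEATURE_NAMES",
    "features_to_frame",
    "DEFAULT_SCALES1",
    "DEFAULT_SCALES2",
]


# ---------------------------------------------------------------------------
# Poincaré
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoincareResult:
    """SD1/SD2 ellipse axes of the lag-1 Poincaré plot."""

    sd1: float
    sd2: float
    ratio: float  # sd1/sd2; NaN when sd2 == 0

    @property
    def ratio_defined(self) -> bool:
        return not math.isnan(self.ratio)


def poincare(series) -> PoincareResult:
    """Poincaré SD1/SD2 from the lagged pairs ``(x_n, x_{n+1})``.

    Equivalent to rotating the point cloud by 45 degrees and taking the
    axis standard deviations (population convention).  A zero SD2
    (e.g. a perfectly alternating series) leaves the ratio flagged as
    undefined (NaN) rather than raising.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("poincare requires a 1-d series of length >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("poincare input must be finite")
    diff = x[1:] - x[:-1]
    summ = x[1:] + x[:-1]
    var1 = float(np.var(diff))
    var2 = float(np.var(summ))
    # variances that are pure cancellation noise (e.g. a constant series
    # with a large offset) are clamped to exactly zero
    floor = 1e-15 * max(float(np.mean(summ)) ** 2, 1.0)
    var1 = 0.0 if var1 <= floor else var1
    var2 = 0.0 if var2 <= floor else var2
    sd1 = math.sqrt(0.5 * var1)
    sd2 = math.sqrt(0.5 * var2)
    ratio = sd1 / sd2 if sd2 > 0 else math.nan
    return PoincareResult(sd1, sd2, ratio)


# ---------------------------------------------------------------------------
# Sample entropy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplexityResult:
    """Sample entropy and the parameters it was computed with."""

    sampen: float  # NaN when undefined (no template matches)
    m: int
    r: float
    n_used: int
    a_count: int = 0
    b_count: int = 0

    @property
    def defined(self) -> bool:
        return not math.isnan(self.sampen)


def _pair_count(templates: np.ndarray, r: float) -> int:
    """Unordered template pairs within Chebyshev distance ``r``.

    Dual-tree counting on a KD-tree; exact (counts the same pairs as a
    naive O(N^2) scan, with ``<= r`` inclusion).
    """
    tree = cKDTree(np.ascontiguousarray(templates))
    total = tree.count_neighbors(tree, r, p=np.inf)
    return int(total - len(templates)) // 2


def sample_entropy(series, m: int = 2, r: float | None = None, *,
                   r_frac: float = 0.2, stride: int = 1) -> ComplexityResult:
    """Sample entropy ``-log(A/B)`` with Chebyshev tolerance ``r``.

    Parameters follow the field convention: ``m = 2`` and, when ``r`` is
    not given explicitly, ``r = r_frac * SD`` of the analysed series
    (population SD, after any striding), which makes the estimate
    invariant under affine rescaling of the input.  ``stride`` keeps
    every ``stride``-th sample before analysis — a desk-scale control for
    long waveforms; ``stride=1`` analyses every sample.

    ``A == 0`` or ``B == 0`` (no matching templates) yields an undefined
    result (NaN) rather than an infinite or fake value.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("sample_entropy requires a 1-d series")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    x = x[::stride]
    n = len(x)
    if n < m + 2:
        raise ValueError(f"series too short for m={m}: need at least {m + 2} samples")
    if r is None:
        r = r_frac * float(np.std(x))
    if not r > 0:
        raise ValueError("tolerance r must be positive")

    nt = n - m  # both template lengths use the first n-m starting points
    xm = sliding_window_view(x, m)[:nt]
    xm1 = sliding_window_view(x, m + 1)
    b = _pair_count(xm, r)
    a = _pair_count(xm1, r)
    if a == 0 or b == 0:
        return ComplexityResult(math.nan, m, float(r), n, a, b)
    return ComplexityResult(-math.log(a / b), m, float(r), n, a, b)


# ---------------------------------------------------------------------------
# Detrended fluctuation analysis
# ---------------------------------------------------------------------------

def _log_spaced_scales(lo: int, hi: int, num: int) -> tuple[int, ...]:
    raw = np.geomspace(lo, hi, num)
    return tuple(sorted(set(int(round(v)) for v in raw)))


#: Short-scale band (samples) for alpha1 and longer band for alpha2.
#: The lower edge is kept at 10 samples: first-order DFA with smaller boxes
#: has a known upward bias (white noise reads ~0.59 over 4-16 samples) that
#: would corrupt the alpha = 0.5 reference for uncorrelated data.
DEFAULT_SCALES1 = _log_spaced_scales(10, 40, 7)
DEFAULT_SCALES2 = _log_spaced_scales(40, 160, 7)


@dataclass(frozen=True)
class DFAResult:
    """Short- and long-scale DFA exponents and the fluctuation function."""

    alpha1: float
    alpha2: float
    alpha_ratio: float  # alpha1/alpha2; NaN when alpha2 == 0
    scales1: tuple
    scales2: tuple
    fluctuations: dict = field(repr=False, default_factory=dict)

    @property
    def defined(self) -> bool:
        return not (math.isnan(self.alpha1) or math.isnan(self.alpha2))


def _fluctuation(profile: np.ndarray, n: int) -> float:
    """RMS residual of per-box linear detrending at box size ``n``."""
    k = len(profile) // n
    boxes = profile[: k * n].reshape(k, n)
    t = np.arange(n, dtype=float)
    # least-squares line per box via closed-form normal equations
    t_mean = t.mean()
    t_var = ((t - t_mean) ** 2).sum()
    y_mean = boxes.mean(axis=1, keepdims=True)
    slope = ((boxes - y_mean) * (t - t_mean)).sum(axis=1, keepdims=True) / t_var
    resid = boxes - (y_mean + slope * (t - t_mean))
    return float(np.sqrt(np.mean(resid**2)))


def dfa(series, scales1=DEFAULT_SCALES1, scales2=DEFAULT_SCALES2) -> DFAResult:
    """First-order DFA over two scale bands.

    The series is mean-centred and integrated; for each box size the
    integrated profile is partitioned into non-overlapping boxes, each
    box is linearly detrended, and ``F(n)`` is the RMS residual.  Each
    exponent is the least-squares slope of ``log F(n)`` against
    ``log n`` over its band.  A constant input produces ``F(n) == 0``
    and an undefined (NaN) result.
    """
    x = np.asarray(series, dtype=float)
    scales1 = tuple(int(s) for s in scales1)
    scales2 = tuple(int(s) for s in scales2)
    if len(scales1) < 3 or len(scales2) < 3:
        raise ValueError("each scale band needs at least 3 box sizes")
    if min(scales1 + scales2) < 4:
        raise ValueError("box sizes must be >= 4 for linear detrending")
    max_scale = max(scales1 + scales2)
    if len(x) < 4 * max_scale:
        raise ValueError(
            f"series of length {len(x)} too short for max box size {max_scale}"
        )

    profile = np.cumsum(x - x.mean())
    fluct = {n: _fluctuation(profile, n) for n in sorted(set(scales1 + scales2))}
    if any(f == 0.0 for f in fluct.values()):
        return DFAResult(math.nan, math.nan, math.nan, scales1, scales2, fluct)

    def band_slope(scales):
        logn = np.log([float(s) for s in scales])
        logf = np.log([fluct[s] for s in scales])
        return float(np.polyfit(logn, logf, 1)[0])

    a1 = band_slope(scales1)
    a2 = band_slope(scales2)
    ratio = a1 / a2 if a2 != 0 else math.nan
    return DFAResult(a1, a2, ratio, scales1, scales2, fluct)


# ---------------------------------------------------------------------------
# RSBI
# ---------------------------------------------------------------------------

def rsbi(breaths, window_s: float) -> float:
    """Rapid shallow breathing index: breaths/min divided by mean VT (L)."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    n = len(breaths)
    if n == 0:
        raise ValueError("RSBI requires at least one breath in the window")
    mean_vt_l = float(np.mean(breaths.tidal_volume_ml)) / 1000.0
    if mean_vt_l <= 0:
        raise ValueError("RSBI undefined for zero mean tidal volume")
    rate_per_min = n / (window_s / 60.0)
    return rate_per_min / mean_vt_l


# ---------------------------------------------------------------------------
# Feature vector assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureConfig:
    """Extraction settings (defaults follow the analysis conventions)."""

    sampen_m: int = 2
    sampen_r_frac: float = 0.2
    sampen_stride: int = 1
    dfa_scales1: tuple = DEFAULT_SCALES1
    dfa_scales2: tuple = DEFAULT_SCALES2
    window_s: float = 600.0


# (item, index) pairs in the canonical table order: 18 Poincaré rows on
# numeric / per-breath series, then 16 waveform complexity rows, then RSBI.
_POINCARE_ITEMS = (
    ("hr", "HR"),
    ("rr", "RR"),
    ("vt", None),  # per-breath tidal volume
    ("ie", None),  # per-breath I:E ratio
    ("ti", None),  # per-breath inspiratory time
    ("map", "MAP"),
)
_WAVE_ITEMS = (("ecg", "ECG"), ("resp", "RESP_IMP"), ("ppg", "PPG"), ("abp", "ABP"))

FEATURE_NAMES: tuple = tuple(
    f"{item}_{idx}" for item, _ in _POINCARE_ITEMS for idx in ("sd1", "sd2", "sd1_sd2")
) + tuple(
    f"{item}_{idx}"
    for item, _ in _WAVE_ITEMS
    for idx in ("sampen", "alpha1", "alpha2", "alpha_ratio")
)
assert len(FEATURE_NAMES) == 34


@dataclass
class FeatureVector:
    """The 34 variability indices plus RSBI for one patient.

    ``values`` maps feature name to float (NaN where masked);
    ``mask`` is True wherever a source channel was absent or a ratio /
    entropy was undefined.
    """

    patient_id: str
    label: str
    values: dict
    mask: dict
    rsbi: float = math.nan

    def __post_init__(self):
        missing = set(FEATURE_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"feature vector incomplete: missing {sorted(missing)}")

    def to_series(self) -> pd.Series:
        data = {"patient_id": self.patient_id, "label": self.label}
        for name in FEATURE_NAMES:
            data[name] = math.nan if self.mask.get(name, False) else self.values[name]
        data["rsbi"] = self.rsbi
        return pd.Series(data)


def _poincare_triplet(series, min_len: int = 3):
    try:
        res = poincare(series)
    except ValueError:
        return {"sd1": math.nan, "sd2": math.nan, "sd1_sd2": math.nan}, True
    vals = {"sd1": res.sd1, "sd2": res.sd2, "sd1_sd2": res.ratio}
    return vals, False


def extract_features(record: SbtRecord, config: FeatureConfig = FeatureConfig()) -> FeatureVector:
    """Assemble the per-patient feature vector from a windowed record.

    Poincaré indices come from the per-second HR, RR and MAP series and
    the per-breath tidal-volume, I:E-ratio and inspiratory-time
    sequences; SampEn and the two DFA exponents from each 62.5 Hz
    waveform.  Missing channels (or undefined ratios) never raise — the
    corresponding features are masked.  Extraction is deterministic.
    """
    values: dict = {}
    mask: dict = {}

    def put(name, value, masked):
        values[name] = value
        mask[name] = masked or (isinstance(value, float) and math.isnan(value))

    breath_sources = {
        "vt": record.breaths.tidal_volume_ml,
        "ie": record.breaths.ie_ratio,
        "ti": record.breaths.insp_time_s,
    }
    for item, channel_name in _POINCARE_ITEMS:
        if channel_name is None:
            series = breath_sources[item]
            present = len(series) >= 3
        else:
            present = channel_name in record.numerics
            series = record.numerics[channel_name].samples if present else None
        if not present:
            for idx in ("sd1", "sd2", "sd1_sd2"):
                put(f"{item}_{idx}", math.nan, True)
            continue
        vals, failed = _poincare_triplet(series)
        for idx, v in vals.items():
            put(f"{item}_{idx}", v, failed)

    for item, channel_name in _WAVE_ITEMS:
        names = [f"{item}_{i}" for i in ("sampen", "alpha1", "alpha2", "alpha_ratio")]
        if channel_name not in record.waveforms:
            for nm in names:
                put(nm, math.nan, True)
            continue
        samples = record.waveforms[channel_name].samples
        try:
            ent = sample_entropy(
                samples,
                m=config.sampen_m,
                r_frac=config.sampen_r_frac,
                stride=config.sampen_stride,
            )
            put(f"{item}_sampen", ent.sampen, not ent.defined)
        except ValueError:
            put(f"{item}_sampen", math.nan, True)
        try:
            d = dfa(samples, config.dfa_scales1, config.dfa_scales2)
            put(f"{item}_alpha1", d.alpha1, math.isnan(d.alpha1))
            put(f"{item}_alpha2", d.alpha2, math.isnan(d.alpha2))
            put(f"{item}_alpha_ratio", d.alpha_ratio, math.isnan(d.alpha_ratio))
        except ValueError:
            for nm in names[1:]:
                put(nm, math.nan, True)

    try:
        rsbi_value = rsbi(record.breaths, config.window_s)
    except ValueError:
        rsbi_value = math.nan

    return FeatureVector(
        patient_id=record.patient_id,
        label=record.label,
        values=values,
        mask=mask,
        rsbi=rsbi_value,
    )


def features_to_frame(vectors) -> pd.DataFrame:
    """Stack feature vectors into the one-row-per-patient feature table."""
    df = pd.DataFrame([v.to_series() for v in vectors])
    return df.reset_index(drop=True)
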