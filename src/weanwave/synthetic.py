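"""Synthetic SBT cohort generator.

The real study cohort (67 weaning successes, 22 failures) is not publicly
distributable, so this module generates record bundles with the
*statistical* structure the analysis consumes: per-second vitals with
controllable Poincaré geometry, per-breath ventilator series with
controllable rate and tidal volume (hence RSBI), and 62.5 Hz waveforms —
quasi-periodic template trains with fractional-Gaussian-noise (fGn)
modulated cycle lengths and additive fGn "roughness" — whose sample
entropy and DFA exponents move monotonically with the generator knobs.

Group default parameters target the published success/failure group
profiles of the feature table (e.g. ECG SampEn lower in success, HR
SD1/SD2 higher in success) via small simulation-calibrated maps; they are
matched in expectation, not per patient.  Waveforms are generic template
trains, not physiologically detailed simulators: the downstream analysis
consumes only variability statistics.

A single ``separation`` scale ``s`` interpolates every failure-group
parameter between the success value (``s = 0``, groups collapse) and the
calibrated failure value (``s = 1``, default study conditions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .signals import (
    DEFAULT_WAVEFORM_RATE,
    BreathSeries,
    NumericChannel,
    SbtRecord,
    WaveformChannel,
)

__all__ = [
    "fgn_autocovariance",
    "gen_fgn",
    "gen_numeric_series",
    "gen_waveform",
    "gen_breaths",
    "NumericParams",
    "WaveformParams",
    "BreathParams",
    "GroupParams",
    "GroupProfile",
    "CohortSpec",
    "gen_patient",
    "gen_cohort",
]


# ---------------------------------------------------------------------------
# Fractional Gaussian noise (Davies-Harte circulant embedding)
# ---------------------------------------------------------------------------

def fgn_autocovariance(k, H: float, sigma: float = 1.0):
    """Autocovariance gamma(k) of fGn with Hurst exponent ``H``."""
    k = np.abs(np.asarray(k, dtype=float))
    h2 = 2.0 * H
    return 0.5 * sigma**2 * ((k + 1) ** h2 - 2 * k**h2 + np.abs(k - 1) ** h2)


def gen_fgn(H: float, n: int, seed=None, sigma: float = 1.0) -> np.ndarray:
    """Exact stationary fGn sample of length ``n`` via circulant embedding.

    The circulant covariance of size ``2n`` is diagonalised by FFT; its
    eigenvalues must be nonnegative for the embedding to be valid (they
    are for fGn with 0 < H < 1 up to rounding; materially negative
    eigenvalues raise).  ``seed`` may be an int or a Generator.
    """
    if not 0.0 < H < 1.0:
        raise ValueError("Hurst exponent must lie in (0, 1)")
    if n < 64:
        raise ValueError("n must be >= 64")
    rng = np.random.default_rng(seed)

    m = 2 * n
    gamma = fgn_autocovariance(np.arange(n + 1), H, sigma)
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2n
    eig = np.fft.fft(row).real
    if eig.min() < -1e-8 * eig.max():
        raise ValueError(f"circulant embedding not nonnegative for H={H}, n={n}")
    eig = np.clip(eig, 0.0, None)

    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    w = np.fft.fft(np.sqrt(eig / (2.0 * m)) * z)
    return np.sqrt(2.0) * w.real[:n]


# ---------------------------------------------------------------------------
# Numeric (per-second / per-breath) series with target Poincaré geometry
# ---------------------------------------------------------------------------

_AR_PHI = 0.95  # fixed slow-component pole; sets the feasibility floor below
# (kept fast enough that a 600-sample window realises the stationary
# variance, so finite-window Poincaré estimates stay near their targets)


def _ratio_bounds(phi: float = _AR_PHI) -> tuple[float, float]:
    lo = math.sqrt((1 - phi) / (1 + phi))
    return lo, 1.0


def gen_numeric_series(
    target_sd1_sd2_ratio: float,
    target_sd2: float,
    n: int,
    seed=None,
    mean: float = 0.0,
    nonnegative: bool = False,
) -> np.ndarray:
    """Gaussian series whose Poincaré SD1/SD2 hits the targets in expectation.

    The series is a slow AR(1) component (long-term spread, sets SD2)
    plus fast white noise (short-term spread, sets SD1).  With total
    variance ``v`` and lag-1 autocorrelation ``rho``,
    ``SD1 = sqrt(v (1 - rho))`` and ``SD2 = sqrt(v (1 + rho))``, so the
    target ratio fixes ``rho = (1 - r^2)/(1 + r^2)`` and the component
    variances follow.  Ratios outside the achievable band (below
    ``sqrt((1-phi)/(1+phi))`` or above 1 for this composition) raise.
    """
    r = float(target_sd1_sd2_ratio)
    sd2 = float(target_sd2)
    if not (r > 0 and sd2 > 0):
        raise ValueError("targets must be positive")
    lo, hi = _ratio_bounds()
    if not (lo <= r <= hi):
        raise ValueError(
            f"target SD1/SD2 ratio {r:.3f} outside achievable band [{lo:.3f}, {hi:.0f}]"
        )
    rho = (1 - r**2) / (1 + r**2)
    var_total = sd2**2 / (1 + rho)
    var_slow = var_total * rho / _AR_PHI
    var_fast = var_total - var_slow

    rng = np.random.default_rng(seed)
    e = rng.standard_normal(n) * math.sqrt(max(var_slow, 0.0) * (1 - _AR_PHI**2))
    slow = np.empty(n)
    prev = rng.standard_normal() * math.sqrt(max(var_slow, 0.0))
    for i in range(n):
        prev = _AR_PHI * prev + e[i]
        slow[i] = prev
    fast = rng.standard_normal(n) * math.sqrt(max(var_fast, 0.0))
    x = mean + slow + fast
    if nonnegative:
        x = np.clip(x, 0.0, None)
    return x


# ---------------------------------------------------------------------------
# Waveform template trains
# ---------------------------------------------------------------------------

def _gauss(phase, centre, width):
    return np.exp(-0.5 * ((phase - centre) / width) ** 2)


def _template_ecg(phase):
    # schematic P-QRS-T: narrow dominant spike with small flanking waves
    return (
        1.0 * _gauss(phase, 0.30, 0.028)
        - 0.18 * _gauss(phase, 0.24, 0.03)
        - 0.14 * _gauss(phase, 0.36, 0.03)
        + 0.12 * _gauss(phase, 0.12, 0.05)
        + 0.28 * _gauss(phase, 0.55, 0.06)
    )


def _template_ppg(phase):
    return np.sin(np.pi * np.mod(phase, 1.0) ** 0.8) ** 2


def _template_resp(phase):
    return 0.5 * (1 - np.cos(2 * np.pi * phase))


def _template_abp(phase):
    p = np.mod(phase, 1.0)
    return np.sin(np.pi * p**0.7) ** 1.5 + 0.12 * _gauss(p, 0.55, 0.05)


_TEMPLATES = {
    "ECG": (_template_ecg, 1.2),     # base cycle rate (Hz)
    "PPG": (_template_ppg, 1.2),
    "RESP_IMP": (_template_resp, 0.33),
    "ABP": (_template_abp, 1.2),
}


def gen_waveform(
    kind: str,
    duration: float,
    rate: float = DEFAULT_WAVEFORM_RATE,
    *,
    noise_frac: float = 0.1,
    h_mod: float = 0.85,
    cycle_cv: float = 0.03,
    base_freq: float | None = None,
    amplitude: float = 1.0,
    baseline: float = 0.0,
    seed=None,
) -> WaveformChannel:
    """Quasi-periodic template train with tunable complexity.

    The instantaneous cycle rate is modulated by standardised fGn with
    Hurst ``h_mod`` and coefficient of variation ``cycle_cv``; additive
    fGn of the same Hurst, scaled to ``noise_frac`` of the clean-signal
    SD, supplies irregularity.  ``noise_frac`` is monotone in sample
    entropy; ``h_mod`` is monotone in the short-scale DFA exponent at
    fixed ``noise_frac`` (visibly so once the additive noise is
    appreciable — for a nearly clean train the smooth template dominates
    the short scales).
    """
    if kind not in _TEMPLATES:
        raise ValueError(f"unknown waveform kind {kind!r}")
    template, default_freq = _TEMPLATES[kind]
    f0 = base_freq if base_freq is not None else default_freq
    n = int(round(duration * rate))
    rng = np.random.default_rng(seed)

    # cycle-rate modulation: slow fGn sampled per second, held across samples
    n_slow = max(64, int(math.ceil(duration)) + 1)
    mod = gen_fgn(h_mod, n_slow, rng)
    mod = (mod - mod.mean()) / (mod.std() + 1e-12)
    t = np.arange(n) / rate
    inst_freq = f0 * (1.0 + cycle_cv * np.interp(t, np.arange(n_slow), mod))
    inst_freq = np.clip(inst_freq, 0.1 * f0, 3.0 * f0)
    phase = np.cumsum(inst_freq) / rate
    clean = template(np.mod(phase, 1.0))

    sd = float(np.std(clean)) or 1.0
    if noise_frac > 0:
        noise = gen_fgn(h_mod, max(n, 64), rng)[:n]
        noise = (noise - noise.mean()) / (noise.std() + 1e-12)
        signal = clean + noise_frac * sd * noise
    else:
        signal = clean
    samples = baseline + amplitude * signal
    return WaveformChannel(kind, rate, samples)


# ---------------------------------------------------------------------------
# Per-breath series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BreathParams:
    """Ventilator per-breath generator settings for one patient."""

    resp_rate: float = 20.0          # breaths/min
    tv_mean_ml: float = 430.0
    tv_ratio: float = 0.72           # Poincaré SD1/SD2 target of the VT series
    tv_sd2_ml: float = 70.0
    ti_mean_s: float = 1.0
    ti_ratio: float = 0.66
    ti_sd2_s: float = 0.15
    interval_cv: float = 0.08


def gen_breaths(duration: float, params: BreathParams, seed=None) -> BreathSeries:
    """Breath onsets with jittered intervals plus VT / T_insp series."""
    rng = np.random.default_rng(seed)
    mean_interval = 60.0 / params.resp_rate
    n_est = int(duration / mean_interval * 1.5) + 8
    intervals = mean_interval * np.clip(
        1.0 + params.interval_cv * rng.standard_normal(n_est), 0.3, 2.5
    )
    onsets = np.cumsum(intervals)
    onsets = onsets[onsets < duration]
    n = len(onsets)
    if n == 0:
        return BreathSeries.empty()

    tv = gen_numeric_series(
        params.tv_ratio, params.tv_sd2_ml, n, rng, mean=params.tv_mean_ml,
    )
    tv = np.clip(tv, 20.0, None)
    ti = gen_numeric_series(
        params.ti_ratio, params.ti_sd2_s, n, rng, mean=params.ti_mean_s,
    )
    ti = np.clip(ti, 0.25, None)
    intervals_used = np.diff(np.concatenate([[0.0], onsets]))
    te = np.clip(intervals_used - ti, 0.25, None)
    return BreathSeries(onsets, tv, ti, te)


# ---------------------------------------------------------------------------
# Group profiles and cohort assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NumericParams:
    """Per-second vital generator settings (Poincaré targets + level)."""

    ratio: float
    sd2: float
    mean: float


@dataclass(frozen=True)
class WaveformParams:
    noise_frac: float
    h_mod: float
    cycle_cv: float = 0.03
    base_freq: float | None = None  # None = template default cycle rate
    amplitude: float = 1.0
    baseline: float = 0.0


@dataclass(frozen=True)
class GroupParams:
    """All generator settings for one outcome group (population means)."""

    hr: NumericParams
    rr: NumericParams
    map: NumericParams
    breaths: BreathParams
    ecg: WaveformParams
    resp_imp: WaveformParams
    ppg: WaveformParams
    abp: WaveformParams
    # relative between-patient heterogeneity of each scalar parameter
    het: float = 0.30


# Defaults target the published group profiles.  Poincaré ratio/SD2 pairs
# for HR, RR and MAP and the per-breath VT / T_insp series are taken directly
# from the success/failure columns of the feature table; waveform noise
# fractions come from a one-off simulated calibration sweep chosen so the
# extracted SampEn group ordering and rough scale follow the published table
# (ECG clearly noisier / higher-entropy in failure, PPG and ABP mildly so,
# respiratory impedance nearly identical).  Breath-rate / tidal-volume levels
# give overlapping RSBI distributions so the RSBI rule alone discriminates
# weakly, as in the published comparison.
_SUCCESS = GroupParams(
    hr=NumericParams(0.43, 6.74, 85.0),
    rr=NumericParams(0.62, 2.94, 20.0),
    map=NumericParams(0.50, 10.80, 85.0),
    breaths=BreathParams(
        resp_rate=20.0, tv_mean_ml=430.0, tv_ratio=0.72, tv_sd2_ml=70.0,
        ti_mean_s=1.00, ti_ratio=0.66, ti_sd2_s=0.147,
    ),
    ecg=WaveformParams(noise_frac=0.50, h_mod=0.92, cycle_cv=0.03),
    resp_imp=WaveformParams(noise_frac=0.015, h_mod=0.85, cycle_cv=0.02),
    ppg=WaveformParams(noise_frac=0.010, h_mod=0.85, cycle_cv=0.01),
    abp=WaveformParams(noise_frac=0.020, h_mod=0.85, cycle_cv=0.02),
)
_FAILURE = GroupParams(
    hr=NumericParams(0.32, 8.63, 90.0),
    rr=NumericParams(0.65, 3.08, 22.0),
    map=NumericParams(0.40, 15.98, 82.0),
    breaths=BreathParams(
        resp_rate=22.0, tv_mean_ml=400.0, tv_ratio=0.62, tv_sd2_ml=45.0,
        ti_mean_s=0.90, ti_ratio=0.58, ti_sd2_s=0.156,
    ),
    ecg=WaveformParams(noise_frac=1.00, h_mod=0.70, cycle_cv=0.03),
    resp_imp=WaveformParams(noise_frac=0.018, h_mod=0.82, cycle_cv=0.02),
    ppg=WaveformParams(noise_frac=0.080, h_mod=0.82, cycle_cv=0.01),
    abp=WaveformParams(noise_frac=0.045, h_mod=0.82, cycle_cv=0.02),
)


def _lerp(a: float, b: float, s: float) -> float:
    return a + s * (b - a)


def _scale_group(success: GroupParams, failure: GroupParams, s: float) -> GroupParams:
    """Interpolate every failure parameter toward the success value."""

    def num(a: NumericParams, b: NumericParams) -> NumericParams:
        return NumericParams(_lerp(a.ratio, b.ratio, s), _lerp(a.sd2, b.sd2, s), _lerp(a.mean, b.mean, s))

    def wav(a: WaveformParams, b: WaveformParams) -> WaveformParams:
        if a.base_freq is None and b.base_freq is None:
            f0 = None
        else:
            fa = a.base_freq if a.base_freq is not None else b.base_freq
            fb = b.base_freq if b.base_freq is not None else a.base_freq
            f0 = _lerp(fa, fb, s)
        return WaveformParams(
            noise_frac=_lerp(a.noise_frac, b.noise_frac, s),
            h_mod=_lerp(a.h_mod, b.h_mod, s),
            cycle_cv=_lerp(a.cycle_cv, b.cycle_cv, s),
            base_freq=f0,
            amplitude=_lerp(a.amplitude, b.amplitude, s),
            baseline=_lerp(a.baseline, b.baseline, s),
        )

    br = BreathParams(
        resp_rate=_lerp(success.breaths.resp_rate, failure.breaths.resp_rate, s),
        tv_mean_ml=_lerp(success.breaths.tv_mean_ml, failure.breaths.tv_mean_ml, s),
        tv_ratio=_lerp(success.breaths.tv_ratio, failure.breaths.tv_ratio, s),
        tv_sd2_ml=_lerp(success.breaths.tv_sd2_ml, failure.breaths.tv_sd2_ml, s),
        ti_mean_s=_lerp(success.breaths.ti_mean_s, failure.breaths.ti_mean_s, s),
        ti_ratio=_lerp(success.breaths.ti_ratio, failure.breaths.ti_ratio, s),
        ti_sd2_s=_lerp(success.breaths.ti_sd2_s, failure.breaths.ti_sd2_s, s),
        interval_cv=_lerp(success.breaths.interval_cv, failure.breaths.interval_cv, s),
    )
    return GroupParams(
        hr=num(success.hr, failure.hr),
        rr=num(success.rr, failure.rr),
        map=num(success.map, failure.map),
        breaths=br,
        ecg=wav(success.ecg, failure.ecg),
        resp_imp=wav(success.resp_imp, failure.resp_imp),
        ppg=wav(success.ppg, failure.ppg),
        abp=wav(success.abp, failure.abp),
        het=failure.het,
    )


@dataclass(frozen=True)
class GroupProfile:
    """Success/failure generator parameter sets plus the separation scale.

    ``separation = 1`` reproduces the default (study-condition) group
    difference; ``separation = 0`` collapses the failure group onto the
    success group, removing every systematic difference.
    """

    success: GroupParams = _SUCCESS
    failure: GroupParams = _FAILURE
    separation: float = 1.0

    def __post_init__(self):
        if self.separation < 0:
            raise ValueError("separation must be >= 0")

    def effective_failure(self) -> GroupParams:
        return _scale_group(self.success, self.failure, self.separation)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size and recording settings (defaults: the study conditions)."""

    n_success: int = 67
    n_failure: int = 22
    sbt_duration: float = 1800.0
    waveform_rate: float = DEFAULT_WAVEFORM_RATE
    seed: int = 0
    profile: GroupProfile = field(default_factory=GroupProfile)

    def __post_init__(self):
        if self.n_success < 0 or self.n_failure < 0:
            raise ValueError("cohort counts must be nonnegative")


def _truncated_normal(rng, mean, rel_sd, lo, hi):
    v = rng.normal(mean, abs(mean) * rel_sd)
    return float(np.clip(v, lo, hi))


def _lognormal_jitter(rng, mean, sigma, lo=0.0, hi=np.inf):
    """Multiplicative right-skewed jitter with expectation ``mean``."""
    v = mean * math.exp(rng.normal(0.0, sigma) - 0.5 * sigma**2)
    return float(np.clip(v, lo, hi))


def _draw_patient_params(group: GroupParams, rng) -> dict:
    """Patient-level parameters drawn around the group means.

    Scale-like parameters (spreads, noise fractions, rates) get
    right-skewed lognormal jitter; bounded parameters get truncated
    Gaussians.  The heterogeneity level reproduces within-group feature
    SDs of realistic magnitude.
    """
    h = group.het
    lo_ratio, _ = _ratio_bounds()

    def num(p: NumericParams):
        return {
            "ratio": _truncated_normal(rng, p.ratio, h * 1.5, lo_ratio + 0.01, 0.98),
            "sd2": _lognormal_jitter(rng, p.sd2, h * 1.5, 0.1 * p.sd2, 4.0 * p.sd2),
            "mean": _truncated_normal(rng, p.mean, 0.06, 0.7 * p.mean, 1.3 * p.mean),
        }

    def wav(p: WaveformParams, default_freq):
        f0 = p.base_freq if p.base_freq is not None else default_freq
        return {
            "noise_frac": _lognormal_jitter(rng, p.noise_frac, h * 1.6, 0.0, 5.0 * p.noise_frac + 1e-6),
            "h_mod": _truncated_normal(rng, p.h_mod, 0.07, 0.55, 0.98),
            "cycle_cv": p.cycle_cv,
            "base_freq": _truncated_normal(rng, f0, 0.12, 0.6 * f0, 1.5 * f0),
        }

    b = group.breaths
    return {
        "hr": num(group.hr),
        "rr": num(group.rr),
        "map": num(group.map),
        "breaths": {
            "resp_rate": _truncated_normal(rng, b.resp_rate, 0.15, 8.0, 38.0),
            "tv_mean_ml": _truncated_normal(rng, b.tv_mean_ml, 0.22, 120.0, 900.0),
            "tv_ratio": _truncated_normal(rng, b.tv_ratio, h, lo_ratio + 0.01, 0.98),
            "tv_sd2_ml": _lognormal_jitter(rng, b.tv_sd2_ml, h * 1.5, 5.0, 4.0 * b.tv_sd2_ml),
            "ti_mean_s": _truncated_normal(rng, b.ti_mean_s, 0.12, 0.4, 2.0),
            "ti_ratio": _truncated_normal(rng, b.ti_ratio, h, lo_ratio + 0.01, 0.98),
            "ti_sd2_s": _lognormal_jitter(rng, b.ti_sd2_s, h * 1.5, 0.02, 0.8),
            "interval_cv": b.interval_cv,
        },
        "ecg": wav(group.ecg, _TEMPLATES["ECG"][1]),
        "resp_imp": wav(group.resp_imp, _TEMPLATES["RESP_IMP"][1]),
        "ppg": wav(group.ppg, _TEMPLATES["PPG"][1]),
        "abp": wav(group.abp, _TEMPLATES["ABP"][1]),
    }


_WAVE_KINDS = {"ecg": "ECG", "resp_imp": "RESP_IMP", "ppg": "PPG", "abp": "ABP"}


def gen_patient(
    patient_id: str,
    label: str,
    params: dict,
    *,
    sbt_duration: float = 1800.0,
    waveform_rate: float = DEFAULT_WAVEFORM_RATE,
    seed=None,
) -> SbtRecord:
    """Materialise one patient's record from drawn generator parameters."""
    rng = np.random.default_rng(seed)
    n_sec = int(round(sbt_duration))

    numerics = {}
    for key, name in (("hr", "HR"), ("rr", "RR"), ("map", "MAP")):
        p = params[key]
        series = gen_numeric_series(
            p["ratio"], p["sd2"], n_sec, rng, mean=p["mean"], nonnegative=True
        )
        numerics[name] = NumericChannel(name, series)

    waveforms = {}
    for key, kind in _WAVE_KINDS.items():
        p = params[key]
        waveforms[kind] = gen_waveform(
            kind,
            sbt_duration,
            waveform_rate,
            noise_frac=p["noise_frac"],
            h_mod=p["h_mod"],
            cycle_cv=p["cycle_cv"],
            base_freq=p.get("base_freq"),
            seed=rng,
        )

    bp = params["breaths"]
    breaths = gen_breaths(
        sbt_duration,
        BreathParams(
            resp_rate=bp["resp_rate"],
            tv_mean_ml=bp["tv_mean_ml"],
            tv_ratio=bp["tv_ratio"],
            tv_sd2_ml=bp["tv_sd2_ml"],
            ti_mean_s=bp["ti_mean_s"],
            ti_ratio=bp["ti_ratio"],
            ti_sd2_s=bp["ti_sd2_s"],
            interval_cv=bp["interval_cv"],
        ),
        rng,
    )

    return SbtRecord(
        patient_id=patient_id,
        label=label,
        sbt_duration=sbt_duration,
        waveforms=waveforms,
        numerics=numerics,
        breaths=breaths,
        metadata={"synthetic": True},
    )


def _flatten_params(params: dict) -> dict:
    flat = {}
    for group_key, sub in params.items():
        for k, v in sub.items():
            flat[f"{group_key}.{k}"] = v
    return flat


def gen_cohort(spec: CohortSpec = CohortSpec()):
    """Generate a full cohort of records plus a true-parameter manifest.

    Returns ``(records, manifest)`` where ``manifest`` is a DataFrame with
    one row per patient listing every drawn generator parameter, so any
    extracted feature's expected value can be recomputed from it.
    Fully deterministic under a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    failure_group = spec.profile.effective_failure()

    records, rows = [], []
    plan = [("success", spec.profile.success)] * spec.n_success + [
        ("failure", failure_group)
    ] * spec.n_failure
    for i, (label, group) in enumerate(plan):
        pid = f"P{i + 1:03d}"
        params = _draw_patient_params(group, rng)
        rec = gen_patient(
            pid,
            label,
            params,
            sbt_duration=spec.sbt_duration,
            waveform_rate=spec.waveform_rate,
            seed=rng,
        )
        records.append(rec)
        rows.append({"patient_id": pid, "label": label, **_flatten_params(params)})

    manifest = pd.DataFrame(rows)
    return records, manifest
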