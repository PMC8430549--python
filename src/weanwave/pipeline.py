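"""End-to-end orchestration: bundles -> features -> comparison -> evaluation.

``run_all`` ties the stages together exactly as the analysis prescribes:
read (or accept in memory) a cohort of SBT records, down-sample
waveforms to the common rate, crop to the middle analysis window,
extract the 34 variability features plus RSBI, compare groups under the
rank-indexed thresholds, select the significant and near-significant
features plus RSBI for modelling, and evaluate the RSBI-only, forest and
logistic comparators by bootstrap.  Given a seed, the whole run is a
pure function of its configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .groupstats import DEFAULT_ALPHA, DEFAULT_NEAR_P, ComparisonTable, compare_groups
from .predict import EvalReport, ForestSpec, bootstrap_eval, feature_importance, fit_forest
from .signals import DEFAULT_WAVEFORM_RATE, downsample, middle_window, read_record
from .variability import FeatureConfig, extract_features, features_to_frame

__all__ = ["RunConfig", "RunResult", "run_all", "load_config"]

log = logging.getLogger("weanwave")


@dataclass(frozen=True)
class RunConfig:
    """All run settings; defaults are the analysis' stated conditions."""

    input_dir: str | None = None
    out_dir: str | None = None
    seed: int = 0
    waveform_rate: float = DEFAULT_WAVEFORM_RATE
    window_s: float = 600.0
    sampen_m: int = 2
    sampen_r_frac: float = 0.2
    sampen_stride: int = 1
    dfa_scales1: tuple | None = None
    dfa_scales2: tuple | None = None
    alpha: float = DEFAULT_ALPHA
    near_p: float = DEFAULT_NEAR_P
    forest: ForestSpec = field(default_factory=ForestSpec)
    n_bootstrap: int = 1000
    train_frac: float = 0.7
    comparators: tuple = ("rsbi", "forest", "logistic")
    skip_bad: bool = False

    def feature_config(self) -> FeatureConfig:
        kwargs = dict(
            sampen_m=self.sampen_m,
            sampen_r_frac=self.sampen_r_frac,
            sampen_stride=self.sampen_stride,
            window_s=self.window_s,
        )
        if self.dfa_scales1 is not None:
            kwargs["dfa_scales1"] = tuple(self.dfa_scales1)
        if self.dfa_scales2 is not None:
            kwargs["dfa_scales2"] = tuple(self.dfa_scales2)
        return FeatureConfig(**kwargs)


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML (JSON is a subset of YAML and also works)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    forest = ForestSpec(**data.pop("forest", {}))
    for key in ("comparators", "dfa_scales1", "dfa_scales2"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return RunConfig(forest=forest, **data)


@dataclass
class RunResult:
    features: pd.DataFrame
    comparison: ComparisonTable
    selected_features: list
    evaluation: EvalReport
    importance: pd.Series


def _load_records(config: RunConfig):
    root = Path(config.input_dir)
    bundles = sorted(p for p in root.iterdir() if (p / "metadata.json").is_file())
    if not bundles:
        raise ValueError(f"no record bundles found under {root}")
    records = []
    for p in bundles:
        try:
            records.append(read_record(p))
        except Exception as exc:
            if config.skip_bad:
                log.warning("skipping bad bundle %s: %s", p.name, exc)
                continue
            raise ValueError(f"unreadable bundle {p.name}: {exc}") from exc
    return records


def run_all(config: RunConfig, records=None) -> RunResult:
    """Run the full analysis; see the module docstring for the stages.

    ``records`` may be supplied in memory (e.g. from the synthetic
    cohort generator); otherwise bundles are read from
    ``config.input_dir``.  When ``config.out_dir`` is set, the feature
    table, comparison table, evaluation JSON, importance CSV and the
    resolved configuration are written there.
    """
    log.info("run config: %s", dataclasses.asdict(config))
    if records is None:
        if config.input_dir is None:
            raise ValueError("either records or config.input_dir is required")
        records = _load_records(config)
    if not records:
        raise ValueError("empty cohort")

    fc = config.feature_config()
    vectors = []
    for rec in records:
        prepared = {}
        for name, ch in rec.waveforms.items():
            prepared[name] = (
                downsample(ch, config.waveform_rate)
                if ch.sampling_rate > config.waveform_rate
                else ch
            )
        rec = dataclasses.replace(rec, waveforms=prepared)
        windowed = middle_window(rec, config.window_s)
        vectors.append(extract_features(windowed, fc))
    features = features_to_frame(vectors)

    comparison = compare_groups(
        features, config.alpha, near_p=config.near_p
    )
    selected = comparison.selected_features(include_rsbi=True)
    log.info("selected features for modelling: %s", selected)

    evaluation = bootstrap_eval(
        features,
        selected,
        comparators=config.comparators,
        n_iter=config.n_bootstrap,
        train_frac=config.train_frac,
        seed=config.seed,
        forest_spec=dataclasses.replace(config.forest, seed=config.seed),
    )

    # full-cohort forest for the importance table (missing values imputed
    # by cohort medians)
    X = features[selected].astype(float)
    X = X.fillna(X.median().fillna(0.0))
    full_forest = fit_forest(
        X, features["label"].to_numpy(),
        dataclasses.replace(config.forest, seed=config.seed),
    )
    importance = feature_importance(full_forest).sort_values(ascending=False)

    result = RunResult(features, comparison, selected, evaluation, importance)
    if config.out_dir is not None:
        _write_artifacts(config, result)
    return result


def _write_artifacts(config: RunConfig, result: RunResult) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(out / "features.csv", index=False)
    result.comparison.to_csv(out / "comparison.csv")
    result.evaluation.to_json(out / "evaluation.json")
    result.importance.rename_axis("feature").to_csv(out / "importance.csv")
    cfg = dataclasses.asdict(config)
    cfg["selected_features"] = result.selected_features
    (out / "run_config.json").write_text(
        json.dumps(cfg, indent=2, default=str) + "\n", encoding="utf-8"
    )
    log.info("artifacts written to %s", out)
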