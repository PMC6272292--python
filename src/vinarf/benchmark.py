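"""Benchmark orchestration: train/test presets over a featurized store.

A benchmark is a test set plus an ordered list of training sets, evaluated by
a subset of the four model families:

* ``vina``       — the composite score with published weights, no training;
* ``mlr_vina``   — least squares on the 6 Vina features;
* ``rf_vina``    — random forest on the 6 Vina features;
* ``rf_vinaelem``— random forest on all 42 features.

RF models contribute one results row per seed (10 by default); deterministic
models contribute a single row.  Medians over seeds are the headline numbers,
matching the convention of comparing scoring functions by the median of their
seed-replicate instances.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DEFAULT_SEEDS, VinaWeights
from .interactions import VINA6_NAMES, VINAELEM42_NAMES, vina_score_from_features
from .metrics import MetricsReport, PredictionSet, compute_metrics
from .models import RFConfig, fit_mlr, fit_rf, predict

logger = logging.getLogger(__name__)

__all__ = [
    "BenchmarkSpec",
    "FeatureStore",
    "run_benchmark",
    "summarize",
    "comparison_report",
    "results_to_csv",
]

MODEL_NAMES = ("vina", "mlr_vina", "rf_vina", "rf_vinaelem")
_METRIC_COLS = ("rmse", "sd", "rp", "rs", "n", "a", "b")


@dataclass
class FeatureStore:
    """Feature rows (42 or 6 columns, indexed by complex id) plus labels."""

    features: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        missing = self.labels.index.difference(self.features.index)
        if len(missing):
            raise ValueError(f"labels without feature rows: {list(missing[:5])}")

    def resolve(self, codes: list[str], allow_missing: bool = False) -> list[str]:
        known = [c for c in codes if c in self.features.index and c in self.labels.index]
        unknown = [c for c in codes if c not in known]
        if unknown and not allow_missing:
            raise KeyError(f"unresolvable codes (first few): {unknown[:5]}")
        if unknown:
            logger.warning("dropping %d unresolvable codes", len(unknown))
        return known

    def X(self, codes: list[str], columns: tuple[str, ...]) -> pd.DataFrame:
        return self.features.loc[codes, list(columns)]

    def y(self, codes: list[str]) -> np.ndarray:
        return self.labels.loc[codes].to_numpy(dtype=float)


@dataclass
class BenchmarkSpec:
    """One benchmark: a name, a test set, training sets, models and seeds."""

    name: str
    test_codes: list[str]
    training_sets: list[tuple[str, list[str]]]
    models: tuple[str, ...] = MODEL_NAMES
    seeds: tuple[int, ...] = DEFAULT_SEEDS
    rf_config: RFConfig | None = None
    vina_weights: VinaWeights = field(default_factory=VinaWeights)

    def __post_init__(self) -> None:
        if not self.training_sets:
            raise ValueError("at least one training set is required")
        bad = [m for m in self.models if m not in MODEL_NAMES]
        if bad:
            raise ValueError(f"unknown models: {bad}")
        test = set(self.test_codes)
        for label, codes in self.training_sets:
            overlap = test & set(codes)
            if overlap:
                raise ValueError(
                    f"training set {label!r} overlaps the test set: "
                    f"{sorted(overlap)[:5]}"
                )


def _report_row(
    spec_name: str, model: str, label: str, train_n: int, seed, report: MetricsReport
) -> dict:
    row = {
        "benchmark": spec_name,
        "model": model,
        "training_label": label,
        "train_n": train_n,
        "seed": seed if seed is not None else -1,
    }
    for m in _METRIC_COLS:
        v = getattr(report, m)
        row[m] = np.nan if v is None else v
    return row


def run_benchmark(
    spec: BenchmarkSpec,
    store: FeatureStore,
    allow_missing: bool = False,
    sd_ddof: int = 1,
) -> pd.DataFrame:
    """Run every (training set x model) cell of a benchmark.

    Train/test disjointness is asserted before any training; RF rows are one
    per seed.  Fully deterministic for fixed spec and store.
    """
    test_codes = store.resolve(spec.test_codes, allow_missing)
    y_test = store.y(test_codes)
    rows: list[dict] = []
    rf_config = spec.rf_config or RFConfig(seeds=spec.seeds)

    for label, codes in spec.training_sets:
        train_codes = store.resolve(codes, allow_missing)
        if set(train_codes) & set(test_codes):
            raise ValueError(f"training set {label!r} overlaps test set")
        n_train = len(train_codes)
        for model_name in spec.models:
            if model_name == "vina":
                X = store.X(test_codes, VINA6_NAMES)
                preds = np.asarray(
                    vina_score_from_features(X.to_numpy(), spec.vina_weights)
                )
                report = compute_metrics(PredictionSet(preds, y_test), sd_ddof=sd_ddof)
                rows.append(_report_row(spec.name, model_name, label, n_train, None, report))
            elif model_name == "mlr_vina":
                lm = fit_mlr(store.X(train_codes, VINA6_NAMES), store.y(train_codes))
                preds = predict(lm, store.X(test_codes, VINA6_NAMES))
                report = compute_metrics(PredictionSet(preds, y_test), sd_ddof=sd_ddof)
                rows.append(_report_row(spec.name, model_name, label, n_train, None, report))
            else:
                cols = VINA6_NAMES if model_name == "rf_vina" else VINAELEM42_NAMES
                X_train = store.X(train_codes, cols)
                X_test = store.X(test_codes, cols)
                y_train = store.y(train_codes)
                for seed in spec.seeds:
                    model = fit_rf(X_train, y_train, seed, rf_config)
                    preds = predict(model, X_test)
                    report = compute_metrics(PredictionSet(preds, y_test), sd_ddof=sd_ddof)
                    rows.append(
                        _report_row(spec.name, model_name, label, n_train, seed, report)
                    )
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Per-(training set, model) componentwise medians over seeds.

    Ordering is stable: by training label (input order preserved), then model.
    """
    if results.empty:
        raise ValueError("empty results table")
    label_order = list(dict.fromkeys(results["training_label"]))
    model_order = [m for m in MODEL_NAMES if m in set(results["model"])]
    rows = []
    for label in label_order:
        for model in model_order:
            cell = results[(results["training_label"] == label) & (results["model"] == model)]
            if cell.empty:
                continue
            row = {
                "benchmark": cell["benchmark"].iloc[0],
                "model": model,
                "training_label": label,
                "train_n": int(cell["train_n"].iloc[0]),
                "n_seeds": int(len(cell)),
            }
            for m in _METRIC_COLS:
                row[m] = float(np.median(cell[m].to_numpy()))
            rows.append(row)
    return pd.DataFrame(rows)


def comparison_report(
    own: pd.DataFrame,
    external: pd.DataFrame | None = None,
    test_size: int | None = None,
) -> pd.DataFrame:
    """Merge own summary rows with printed literature values, ranked by Rp.

    ``own`` needs columns name/N/Rp/SD (a summary row can be adapted by the
    caller); ``external`` is a user-supplied table of published values with
    the same columns.  Sorting: Rp descending, ties by SD ascending.  Rows
    scoring fewer than ``test_size`` complexes are flagged ``partial``.
    """
    frames = [own.copy()]
    if external is not None and not external.empty:
        frames.append(external.copy())
    merged = pd.concat(frames, ignore_index=True)
    required = {"name", "N", "Rp", "SD"}
    if not required.issubset(merged.columns):
        raise ValueError(f"comparison table needs columns {sorted(required)}")
    merged = merged.sort_values(
        ["Rp", "SD"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if test_size is not None:
        merged["partial"] = merged["N"] < test_size
    return merged


def results_to_csv(results: pd.DataFrame, path: str | None = None) -> str:
    """Canonical CSV serialisation with fixed float formatting.

    Formatting is pinned (repr-precision, fixed column order) so identical
    runs produce byte-identical files.
    """
    buf = io.StringIO()
    results.to_csv(buf, index=False, float_format="%.12g", lineterminator="\n")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w", newline="") as fh:
            fh.write(text)
    return text


def plot_boxplots(results: pd.DataFrame, metric: str, out_png: str) -> None:
    """Optional boxplot figure (one box per training set x model).

    Matplotlib is imported lazily; the CSV tables remain the canonical
    artifact.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    label_order = list(dict.fromkeys(results["training_label"]))
    model_order = [m for m in MODEL_NAMES if m in set(results["model"])]
    fig, ax = plt.subplots(figsize=(1.2 * len(label_order) * len(model_order) + 2, 4))
    data, ticks = [], []
    for label in label_order:
        for model in model_order:
            cell = results[
                (results["training_label"] == label) & (results["model"] == model)
            ][metric].dropna()
            if len(cell):
                data.append(cell.to_numpy())
                ticks.append(f"{label}\n{model}")
    ax.boxplot(data, tick_labels=ticks)
    ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
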