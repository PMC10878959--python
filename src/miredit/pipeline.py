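"""End-to-end orchestration: simulate -> build -> normalize -> select -> evaluate.

A :class:`RunConfig` (loadable from YAML, unknown keys rejected) fixes
every threshold and seed; :func:`run_e2e` executes the staged analysis
on a synthetic cohort and writes datasets, selections, evaluation
reports and a manifest recording every default into a run directory.
Re-running with the same configuration reproduces the outputs
byte-identically.

Test-split labels are shielded by :class:`~miredit.models.LabelGuard`
during the training stages; only the final evaluation stage may read
them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dfl import DFLConfig
from .editing import CallThresholds
from .features import FilterConfig, build_datasets
from .io import write_matrix_tsv, write_metadata_tsv
from .models import (
    LabelGuard,
    SplitSpec,
    evaluate_on_test,
    loocv,
    make_dfl_spec,
    make_knn_spec,
    stratified_split,
)
from .normalize import normalize_features
from .synthetic import CohortSimConfig, PlantedEffect, simulate_feature_cohort

logger = logging.getLogger(__name__)


class ConfigValidationError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one end-to-end run."""

    seed: int = 0
    cohort: CohortSimConfig = dataclasses.field(default_factory=CohortSimConfig)
    call: CallThresholds = dataclasses.field(default_factory=CallThresholds)
    filters: FilterConfig = dataclasses.field(default_factory=FilterConfig)
    dfl: DFLConfig = dataclasses.field(
        default_factory=lambda: DFLConfig(max_evals_per_cardinality=20000)
    )
    split: SplitSpec = dataclasses.field(default_factory=SplitSpec)
    batch_backend: str = "fallback"
    knn_k: int = 6
    run_loocv: bool = False

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(raw) - set(known)
        if unknown:
            raise ConfigValidationError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        nested = {
            "cohort": CohortSimConfig,
            "call": CallThresholds,
            "filters": FilterConfig,
            "dfl": DFLConfig,
            "split": SplitSpec,
        }
        for key, value in raw.items():
            if key in nested:
                sub_cls = nested[key]
                sub_known = {f.name for f in dataclasses.fields(sub_cls)}
                sub_unknown = set(value) - sub_known
                if sub_unknown:
                    raise ConfigValidationError(
                        f"unknown keys under {key!r}: {sorted(sub_unknown)}"
                    )
                if key == "cohort" and "planted_effects" in value:
                    value = dict(value)
                    value["planted_effects"] = tuple(
                        PlantedEffect(**e) for e in value["planted_effects"]
                    )
                try:
                    kwargs[key] = sub_cls(**value)
                except ValueError as exc:
                    raise ConfigValidationError(f"invalid {key!r} config: {exc}") from exc
            else:
                kwargs[key] = value
        cfg = cls(**kwargs)
        if cfg.batch_backend not in ("fallback", "combat-seq"):
            raise ConfigValidationError(f"unknown batch backend {cfg.batch_backend!r}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigValidationError("config must be a YAML mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _json_default(obj: Any):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"unserializable {type(obj)!r}")


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def run_e2e(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute every stage and write the run directory; returns the report."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    # stage 1: simulate the cohort (the run seed overrides the cohort seed)
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    aom, aem, el, meta, truth = simulate_feature_cohort(cohort_cfg)
    write_metadata_tsv(meta, out / "metadata.tsv")

    # stage 2: filter + assemble the three datasets
    datasets = build_datasets(aom, aem, el, meta, config.filters)

    # stage 3: batch correction + quantile normalization
    normalized = {
        name: normalize_features(fm, backend=config.batch_backend)
        for name, fm in datasets.items()
    }
    for name, fm in normalized.items():
        write_matrix_tsv(fm.values, out / f"dataset_{name}.tsv")

    # stage 4: stratified split
    split_spec = dataclasses.replace(config.split, seed=config.seed)
    train_ids, test_ids = stratified_split(meta, split_spec)
    guard = LabelGuard(meta["class"], train_ids)

    knn = make_knn_spec(k=config.knn_k)
    dfl_spec = make_dfl_spec(config.dfl)

    # stage 5: DFL feature selection + model fits on training data only
    report: dict[str, Any] = {"datasets": {}}
    trained: dict[str, list[tuple]] = {}
    for name, fm in normalized.items():
        x_train = fm.values.loc[train_ids]
        y_train = guard.training_labels(train_ids).to_numpy()

        dfl_model = dfl_spec.fit(x_train, y_train)
        selection = dfl_model.selection_
        selected = selection.features or list(fm.values.columns)
        knn_model = knn.fit(x_train[selected], y_train)

        entry: dict[str, Any] = {
            "n_features": int(fm.values.shape[1]),
            "selected_features": selection.features,
            "selection_converged": bool(selection.converged),
            "selection_mi_bits": selection.mi,
            "class_entropy_bits": selection.h_y,
        }
        if config.run_loocv:
            entry["loocv_accuracy_pct"] = 100.0 * loocv(
                knn, x_train[selected], y_train
            )
        report["datasets"][name] = entry
        trained[name] = [
            (knn, knn_model, selected),
            (dfl_spec, dfl_model, list(fm.values.columns)),
        ]

    # stage 6: independent-test evaluation (the guard opens only now)
    guard.release()
    y_test = guard.test_labels(test_ids).to_numpy()
    for name, fm in normalized.items():
        for spec, model, cols in trained[name]:
            ev = evaluate_on_test(model, spec, fm.values.loc[test_ids, cols], y_test)
            report["datasets"][name][spec.name] = {
                "test_accuracy_pct": ev.accuracy,
                "confusion": ev.confusion,
                "auc": ev.auc,
            }

    manifest = {
        "package": "miredit",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_train": len(train_ids),
        "n_test": len(test_ids),
        "defaults": {
            "dfl_epsilon": config.dfl.epsilon,
            "dfl_max_cardinality": config.dfl.max_cardinality,
            "dfl_n_bins": config.dfl.n_bins,
            "knn_k": config.knn_k,
            "knn_metric": "euclidean",
            "knn_tie_rule": "smaller mean distance, then smaller class label",
            "dfl_tie_rule": "largest table count, then lexicographically smallest key",
            "function_table_majority_tie": "smallest class label",
            "batch_backend": config.batch_backend,
            "normalization_order": "batch correction -> x100 EL merge -> quantile normalization",
        },
    }
    _write_json(manifest, out / "manifest.json")
    _write_json(report, out / "report.json")
    _write_json(
        {"train": train_ids, "test": test_ids}, out / "split.json"
    )
    logger.info("run complete: %s", out)
    return report
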