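"""Assembling the three feature datasets from counts and editing levels.

Three families of features describe each sample:

* AOM — abundances (raw counts) of original miRNAs,
* AEM — abundances (raw counts) of edited/mutated miRNA sequences,
* EL  — editing levels of M/E sites, stored as percent (level x 100).

Low-information features are dropped by group-mean filters computed per
class: a count feature is kept when its mean raw count in either class
is strictly greater than ``count_group_mean_min`` (default 10); an EL
feature is kept when its mean editing level in either class is strictly
greater than ``el_group_mean_min`` percent (default 10).  Missing
editing levels (sites uncovered in a sample) are imputed as 0 before
filtering, and the imputation is logged.

The three analysis datasets are AOM alone, "editing" (AEM + EL) and
"combined" (AOM + AEM + EL).  Filters are computed on the full cohort
before any train/test split, mirroring the upstream study design; the
resulting mild information leakage is documented in the README.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KIND_AOM = "AOM"
KIND_AEM = "AEM"
KIND_EL = "EL"


class FeatureError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class FilterConfig:
    el_group_mean_min: float = 10.0  # percent
    count_group_mean_min: float = 10.0  # raw counts

    def __post_init__(self) -> None:
        if self.el_group_mean_min < 0 or self.count_group_mean_min < 0:
            raise FeatureError("filter thresholds must be non-negative")


@dataclasses.dataclass
class FeatureMatrix:
    """A samples x features table with per-column kinds and sample metadata."""

    values: pd.DataFrame
    kinds: pd.Series  # feature id -> AOM | AEM | EL
    metadata: pd.DataFrame  # index sample; columns batch, class

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FeatureError(f"duplicate feature id {dup!r}")
        if not self.values.index.equals(self.metadata.index):
            raise FeatureError("sample index mismatch between values and metadata")
        if set(self.kinds.index) != set(self.values.columns):
            raise FeatureError("kind annotation does not cover the feature set")
        el_cols = self.kinds[self.kinds == KIND_EL].index
        if len(el_cols):
            el = self.values[el_cols].to_numpy(dtype=float)
            finite = el[np.isfinite(el)]
            if finite.size and (finite.min() < 0 or finite.max() > 100):
                raise FeatureError("EL columns must lie in [0, 100] percent")
        count_cols = self.kinds[self.kinds != KIND_EL].index
        if len(count_cols) and (self.values[count_cols].to_numpy() < 0).any():
            raise FeatureError("count columns must be non-negative")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, features: Sequence[str]) -> "FeatureMatrix":
        feats = list(features)
        return FeatureMatrix(
            values=self.values[feats].copy(),
            kinds=self.kinds[feats].copy(),
            metadata=self.metadata.copy(),
        )


def quantify_counts(
    assignments: pd.DataFrame, samples: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tally per-sample read assignments into AOM and AEM count matrices.

    ``assignments`` has one row per read with columns ``sample``,
    ``mirna`` and ``kind`` (AOM or AEM).  ``samples`` fixes the sample
    universe so that samples with no reads appear as all-zero rows.
    """
    required = {"sample", "mirna", "kind"}
    if not required <= set(assignments.columns):
        raise FeatureError(f"assignments need columns {sorted(required)}")
    if samples is None:
        samples = list(pd.unique(assignments["sample"]))
    else:
        unknown = set(assignments["sample"]) - set(samples)
        if unknown:
            raise FeatureError(f"unknown sample id {sorted(unknown)[0]!r}")

    out = []
    for kind in (KIND_AOM, KIND_AEM):
        sub = assignments[assignments["kind"] == kind]
        counts = (
            sub.groupby(["sample", "mirna"], sort=True)
            .size()
            .unstack(fill_value=0)
            .reindex(index=list(samples), fill_value=0)
        )
        counts.index.name = "sample"
        counts.columns.name = None
        out.append(counts.astype(int))
    return out[0], out[1]


def filter_by_group_mean(
    matrix: pd.DataFrame,
    classes: pd.Series,
    threshold: float,
    scale: float = 1.0,
) -> list[str]:
    """Keep features whose class mean (on ``scale`` x values) is strictly
    greater than ``threshold`` in at least one class."""
    labels = classes.reindex(matrix.index)
    if labels.isna().any():
        raise FeatureError("every sample needs a class label")
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise FeatureError(f"expected two classes, got {uniq}")
    keep = np.zeros(matrix.shape[1], dtype=bool)
    for cls in uniq:
        members = matrix.loc[labels == cls]
        if members.empty:
            raise FeatureError(f"class {cls!r} has no samples")
        keep |= (members.mean(axis=0).to_numpy() * scale) > threshold
    return [f for f, k in zip(matrix.columns, keep) if k]


def apply_filters(
    aom: pd.DataFrame,
    aem: pd.DataFrame,
    el: pd.DataFrame,
    classes: pd.Series,
    cfg: FilterConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Apply abundance and editing-level group-mean filters.

    ``el`` is on the 0..1 scale here; its group means are evaluated on
    the percent scale.  Missing EL values are imputed as 0 first.
    """
    cfg = cfg or FilterConfig()
    if el.isna().any().any():
        n_missing = int(el.isna().sum().sum())
        logger.info("imputing %d missing editing levels as 0", n_missing)
        el = el.fillna(0.0)
    aom_keep = filter_by_group_mean(aom, classes, cfg.count_group_mean_min)
    aem_keep = filter_by_group_mean(aem, classes, cfg.count_group_mean_min)
    el_keep = filter_by_group_mean(el, classes, cfg.el_group_mean_min, scale=100.0)
    return aom[aom_keep], aem[aem_keep], el[el_keep]


def assemble_datasets(
    aom: pd.DataFrame,
    aem: pd.DataFrame,
    el: pd.DataFrame,
    metadata: pd.DataFrame,
) -> dict[str, FeatureMatrix]:
    """Build the AOM-only, editing (AEM+EL) and combined datasets.

    Inputs are samples x features with filters already applied; ``el``
    on the 0..1 scale is rescaled to percent here.  Columns are carried
    over bit-exactly (counts) or by the single x100 rescale (EL).
    """
    for m in (aem, el):
        if not m.index.equals(aom.index):
            raise FeatureError("sample index mismatch across families")
    el_pct = el.fillna(0.0) * 100.0

    families: Mapping[str, pd.DataFrame] = {
        KIND_AOM: aom,
        KIND_AEM: aem,
        KIND_EL: el_pct,
    }
    all_ids: list[str] = []
    for fam in families.values():
        all_ids.extend(fam.columns)
    if len(set(all_ids)) != len(all_ids):
        seen: set[str] = set()
        dup = next(f for f in all_ids if f in seen or seen.add(f))
        raise FeatureError(f"feature id {dup!r} appears in more than one family")

    def _build(kinds: Sequence[str]) -> FeatureMatrix:
        values = pd.concat([families[k] for k in kinds], axis=1)
        kind_series = pd.Series(
            {f: k for k in kinds for f in families[k].columns}, dtype=object
        ).reindex(values.columns)
        return FeatureMatrix(values=values, kinds=kind_series, metadata=metadata.copy())

    return {
        "aom": _build([KIND_AOM]),
        "editing": _build([KIND_AEM, KIND_EL]),
        "combined": _build([KIND_AOM, KIND_AEM, KIND_EL]),
    }


def build_datasets(
    aom: pd.DataFrame,
    aem: pd.DataFrame,
    el: pd.DataFrame,
    metadata: pd.DataFrame,
    cfg: FilterConfig | None = None,
) -> dict[str, FeatureMatrix]:
    """Filter the three families, then assemble the analysis datasets."""
    aom_f, aem_f, el_f = apply_filters(aom, aem, el, metadata["class"], cfg)
    return assemble_datasets(aom_f, aem_f, el_f, metadata)
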