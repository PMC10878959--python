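"""Batch-effect correction, quantile normalization and PCA diagnostics.

Count features from multi-study cohorts carry strong between-batch
shifts.  Correction happens on the raw count scale, with the class kept
as a preserved covariate so biological signal is never removed.  Two
backends honour the same contract (same shape, non-negative integers):

* ``"combat-seq"`` — an adapter around the ComBat-seq implementation in
  the Bioconductor ``sva`` package, invoked through ``Rscript``;
* ``"fallback"`` — a light-weight within-class location adjustment that
  aligns per-batch log1p feature means to the grand mean of the class,
  rounds back to counts and floors at zero.

Editing-level features are ratios, not counts, so they bypass count
batch correction and are only quantile-normalized.

Quantile normalization follows the common dialect: each column (sample)
is mapped onto the vector of row-wise means of the column-sorted
matrix, tied values receiving the mean of the reference values their
ranks span.

The pipeline order is fixed: batch-correct counts, merge with percent
editing levels, quantile-normalize all features jointly.
"""

from __future__ import annotations

import dataclasses
import logging
import subprocess
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .features import KIND_EL, FeatureMatrix

logger = logging.getLogger(__name__)

BACKENDS = ("fallback", "combat-seq")


class NormalizeError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class BatchDesign:
    """Per-sample batch and class labels; the class is preserved."""

    batch: pd.Series
    group: pd.Series

    def __post_init__(self) -> None:
        if self.batch.isna().any() or self.group.isna().any():
            raise NormalizeError("every sample needs batch and class labels")
        if not self.batch.index.equals(self.group.index):
            raise NormalizeError("batch and group must share the sample index")

    @classmethod
    def from_metadata(cls, metadata: pd.DataFrame) -> "BatchDesign":
        return cls(batch=metadata["batch"], group=metadata["class"])


def correct_batch_counts(
    counts: pd.DataFrame, design: BatchDesign, backend: str = "fallback"
) -> pd.DataFrame:
    """Remove batch shifts from a samples x features count matrix."""
    if backend not in BACKENDS:
        raise NormalizeError(f"unknown backend {backend!r}; choose from {BACKENDS}")
    if not design.batch.index.equals(pd.Index(counts.index)):
        raise NormalizeError("design samples do not match the count matrix")
    if counts.shape[1] == 0:
        return counts.copy()
    n_batches = design.batch.nunique()
    if n_batches < 2:
        warnings.warn("single batch: batch correction is the identity", stacklevel=2)
        return counts.copy()
    if backend == "combat-seq":
        return _combat_seq_r(counts, design)
    return _fallback_correct(counts, design)


def _fallback_correct(counts: pd.DataFrame, design: BatchDesign) -> pd.DataFrame:
    """Align per-batch log1p feature means to the class grand mean."""
    x = np.log1p(counts.to_numpy(dtype=float))
    out = x.copy()
    batch = design.batch.to_numpy()
    group = design.group.to_numpy()
    for cls in np.unique(group):
        in_cls = group == cls
        grand = x[in_cls].mean(axis=0)
        for b in np.unique(batch):
            stratum = in_cls & (batch == b)
            if not stratum.any():
                continue
            shift = x[stratum].mean(axis=0) - grand
            out[stratum] -= shift
    corrected = np.rint(np.expm1(out))
    corrected = np.maximum(corrected, 0).astype(np.int64)
    return pd.DataFrame(corrected, index=counts.index, columns=counts.columns)


_COMBAT_R = """
suppressMessages(library(sva))
args <- commandArgs(trailingOnly = TRUE)
counts <- as.matrix(read.delim(args[1], row.names = 1, check.names = FALSE))
meta <- read.delim(args[2], stringsAsFactors = FALSE)
corrected <- ComBat_seq(counts, batch = meta$batch, group = meta$group)
write.table(corrected, args[3], sep = "\t", quote = FALSE, col.names = NA)
"""


def _combat_seq_r(counts: pd.DataFrame, design: BatchDesign) -> pd.DataFrame:
    """Run ComBat-seq (Bioconductor sva) through Rscript on a temp TSV."""
    with tempfile.TemporaryDirectory(prefix="miredit_combat_") as tmp:
        tmpdir = Path(tmp)
        counts_path = tmpdir / "counts.tsv"
        meta_path = tmpdir / "meta.tsv"
        out_path = tmpdir / "corrected.tsv"
        script = tmpdir / "combat_seq.R"
        counts.T.to_csv(counts_path, sep="\t")  # features x samples for R
        pd.DataFrame(
            {"batch": design.batch.to_numpy(), "group": design.group.to_numpy()}
        ).to_csv(meta_path, sep="\t", index=False)
        script.write_text(_COMBAT_R)
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script), str(counts_path), str(meta_path), str(out_path)],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise NormalizeError(f"ComBat-seq backend failed:\n{proc.stderr[-2000:]}")
        corrected = pd.read_csv(out_path, sep="\t", index_col=0).T
    corrected.index = counts.index
    corrected.columns = counts.columns
    return corrected.round().clip(lower=0).astype(np.int64)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a features x samples matrix across its columns.

    Every column is mapped to the common reference distribution (row
    means of the column-sorted matrix); tied values within a column get
    the mean of the reference values spanned by their ranks.
    """
    x = matrix.to_numpy(dtype=float)
    if x.shape[1] <= 1:
        return matrix.copy()
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty_like(col)
        mapped[order] = ref
        # average the reference over tied runs
        ranks = stats.rankdata(col, method="dense")
        sums = np.bincount(ranks, weights=mapped)
        cnts = np.bincount(ranks)
        with np.errstate(invalid="ignore"):
            means = sums / np.maximum(cnts, 1)
        out[:, j] = means[ranks]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def pca_scores(matrix: pd.DataFrame, k: int = 3) -> tuple[pd.DataFrame, np.ndarray]:
    """Scores of the k leading principal components of samples x features."""
    if k <= 0:
        raise NormalizeError("k must be positive")
    if k > min(matrix.shape):
        raise NormalizeError(f"k={k} exceeds min(n_samples, n_features)")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(matrix.to_numpy(dtype=float))
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(scores, index=matrix.index, columns=cols),
        pca.explained_variance_ratio_,
    )


def normalize_features(
    fm: FeatureMatrix, backend: str = "fallback"
) -> FeatureMatrix:
    """Batch-correct count columns, then quantile-normalize the dataset.

    EL (percent) columns skip count correction because they are ratios.
    Quantile normalization operates with samples as columns and is
    applied per feature family (counts vs editing levels), so that
    editing-level features stay on the percent scale instead of being
    mapped onto the count reference distribution.
    """
    design = BatchDesign.from_metadata(fm.metadata)
    count_cols = [f for f in fm.values.columns if fm.kinds[f] != KIND_EL]
    el_cols = [f for f in fm.values.columns if fm.kinds[f] == KIND_EL]
    values = fm.values.astype(float)
    if count_cols:
        corrected = correct_batch_counts(fm.values[count_cols], design, backend=backend)
        values[count_cols] = quantile_normalize(corrected.T).T
    if el_cols:
        values[el_cols] = quantile_normalize(fm.values[el_cols].T).T
    logger.info(
        "normalization order: batch correction (%d count features, backend=%s) "
        "-> per-family quantile normalization (%d count + %d EL features)",
        len(count_cols),
        backend,
        len(count_cols),
        len(el_cols),
    )
    return FeatureMatrix(values=values, kinds=fm.kinds.copy(), metadata=fm.metadata.copy())
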