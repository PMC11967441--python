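"""Expression summarisation and sample-level quality control.

FPKM computation, per-stage replicate averaging, abundance binning
(not expressed < 1, low [1, 10), moderate [10, 100), high >= 100 FPKM),
replicate correlation, sample PCA, rule-based replicate-outlier flagging,
and the 2^-ddCt relative-expression utility for qPCR validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "compute_fpkm",
    "stage_mean_fpkm",
    "classify_expression",
    "sample_correlation",
    "pca_samples",
    "flag_outlier_replicates",
    "ddct",
    "zscore_rows",
    "AbundanceBins",
    "QCReport",
]

ABUNDANCE_THRESHOLDS = (1.0, 10.0, 100.0)
ABUNDANCE_LABELS = ("not_expressed", "low", "moderate", "high")


@dataclass
class AbundanceBins:
    """Per-gene abundance categories and per-column expressed-gene counts."""

    bins: pd.DataFrame
    expressed_counts: pd.Series
    thresholds: tuple[float, float, float] = ABUNDANCE_THRESHOLDS


@dataclass
class QCReport:
    correlation: pd.DataFrame
    correlation_method: str
    pca_coordinates: pd.DataFrame
    variance_explained: np.ndarray
    flagged: list[dict] = field(default_factory=list)


def compute_fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    totals: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of exonic length per million assigned fragments.

    FPKM_gj = counts_gj * 1e9 / (L_g * N_j).  ``totals`` defaults to the
    per-sample column sums (total assigned fragments).
    """
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise KeyError(f"genes missing a length: {', '.join(map(str, missing[:5]))}")
    lengths = lengths.reindex(counts.index).astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if totals is None:
        totals = counts.sum(axis=0).astype(float)
    else:
        totals = totals.reindex(counts.columns).astype(float)
    if (totals <= 0).any():
        raise ValueError("per-sample fragment totals must be positive")
    return counts.astype(float).mul(1e9).div(lengths, axis=0).div(totals, axis=1)


def stage_mean_fpkm(
    fpkm: pd.DataFrame,
    sheet: pd.DataFrame,
    exclude: set[str] | None = None,
) -> pd.DataFrame:
    """Average FPKM over surviving replicates, per line x stage group.

    Columns of the result are ``{line}_{stage}``; ``exclude`` removes flagged
    replicates (e.g. a PCA outlier) before averaging, so a group that loses a
    replicate is averaged over the remaining ones.
    """
    exclude = exclude or set()
    out = {}
    for (line, stage), grp in sheet.groupby(["line", "stage"], sort=False):
        cols = [s for s in grp["sample"] if s in fpkm.columns and s not in exclude]
        if not cols:
            raise ValueError(f"group {line}/{stage} has no surviving replicates")
        out[f"{line}_{stage}"] = fpkm[cols].mean(axis=1)
    return pd.DataFrame(out, index=fpkm.index)


def classify_expression(values: pd.DataFrame) -> AbundanceBins:
    """Bin each value into abundance classes; count expressed genes per column.

    A gene is expressed in a column when its value is >= 1 FPKM; bins are
    left-closed: [0,1) not expressed, [1,10) low, [10,100) moderate,
    [100,inf) high.
    """
    arr = values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("expression values must be non-negative")
    idx = np.digitize(arr, ABUNDANCE_THRESHOLDS, right=False)
    labels = np.asarray(ABUNDANCE_LABELS, dtype=object)[idx]
    bins = pd.DataFrame(labels, index=values.index, columns=values.columns)
    expressed = pd.Series((arr >= 1.0).sum(axis=0), index=values.columns, name="expressed")
    return AbundanceBins(bins=bins, expressed_counts=expressed)


def _log2p1(matrix: pd.DataFrame) -> pd.DataFrame:
    return np.log2(matrix + 1.0)


def sample_correlation(
    matrix: pd.DataFrame,
    method: str = "pearson",
    log_transform: bool = True,
) -> pd.DataFrame:
    """Pairwise sample-sample correlation on log2(x+1)-transformed expression.

    Spearman uses average ranks for ties.  A zero-variance column under
    Pearson yields NaN entries (undefined), never 0.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    if method not in {"pearson", "spearman"}:
        raise ValueError(f"unknown correlation method {method!r}")
    data = _log2p1(matrix) if log_transform else matrix
    corr = data.corr(method=method)
    # pandas fills self-correlation of a constant column with 1; keep that but
    # make sure off-diagonal undefined entries stay NaN (pandas already does).
    np.fill_diagonal(corr.values, 1.0)
    return corr


def pca_samples(
    matrix: pd.DataFrame,
    log_transform: bool = True,
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample coordinates from PCA of the gene-expression matrix.

    Genes expressed in no sample are dropped; values are log2(x+1)
    transformed and gene-centred.  Returns (coordinates, variance explained
    per component as fractions).
    """
    expressed = matrix.loc[(matrix > 0).any(axis=1)]
    data = _log2p1(expressed) if log_transform else expressed
    nonconstant = data.loc[data.std(axis=1) > 0]
    if nonconstant.shape[0] < 2:
        raise ValueError("need at least two non-constant genes for PCA")
    X = nonconstant.to_numpy(dtype=float).T  # samples x genes
    n_components = min(n_components, min(X.shape) - 1) or 1
    model = PCA(n_components=n_components, svd_solver="full")
    coords = model.fit_transform(X - X.mean(axis=0))
    frame = pd.DataFrame(
        coords, index=matrix.columns, columns=[f"PC{i + 1}" for i in range(coords.shape[1])]
    )
    return frame, model.explained_variance_ratio_


def flag_outlier_replicates(
    corr: pd.DataFrame,
    sheet: pd.DataFrame,
    min_sibling_corr: float = 0.95,
) -> list[dict]:
    """Flag replicates poorly correlated with their line x stage siblings.

    A replicate is flagged when even its best same-group sibling correlation
    falls below ``min_sibling_corr`` — agreeing well with at least one
    sibling keeps it, so a single bad replicate does not drag down its whole
    group.  Groups of size one are never flagged, and a non-positive
    threshold disables the check.
    """
    flagged = []
    if min_sibling_corr <= 0:
        return flagged
    for (line, stage), grp in sheet.groupby(["line", "stage"], sort=False):
        names = [s for s in grp["sample"] if s in corr.index]
        if len(names) < 2:
            logger.warning("group %s/%s has a single replicate; outlier check skipped", line, stage)
            continue
        sub = corr.loc[names, names]
        for name in names:
            sibs = [n for n in names if n != name]
            best = float(sub.loc[name, sibs].max())
            if best < min_sibling_corr:
                flagged.append(
                    {"sample": name, "line": line, "stage": stage,
                     "best_sibling_correlation": best,
                     "mean_sibling_correlation": float(sub.loc[name, sibs].mean()),
                     "threshold": min_sibling_corr}
                )
    return flagged


def ddct(ct: pd.DataFrame, calibrator: str) -> pd.Series:
    """Relative expression by the 2^-ddCt method.

    ``ct`` needs columns ``ct_target`` and ``ct_reference`` indexed by sample;
    ddCt = (Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_calibrator and
    relative expression is 2^-ddCt, so the calibrator maps to 1.
    """
    for col in ("ct_target", "ct_reference"):
        if col not in ct.columns:
            raise KeyError(f"Ct table missing column {col!r}")
        if not np.isfinite(ct[col]).all():
            raise ValueError(f"non-finite Ct values in {col!r}")
    if calibrator not in ct.index:
        raise KeyError(f"calibrator sample {calibrator!r} not in Ct table")
    dct = ct["ct_target"] - ct["ct_reference"]
    ddct_values = dct - dct.loc[calibrator]
    return pd.Series(2.0 ** (-ddct_values), index=ct.index, name="relative_expression")


def zscore_rows(matrix: pd.DataFrame, sd_floor: float = 1e-12) -> tuple[pd.DataFrame, pd.Series]:
    """Row-wise z-score (population sd); returns (z, constant-row mask)."""
    arr = matrix.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    mask = sd[:, 0] < sd_floor
    safe_sd = np.where(sd < sd_floor, 1.0, sd)
    z = (arr - mean) / safe_sd
    return (
        pd.DataFrame(z, index=matrix.index, columns=matrix.columns),
        pd.Series(mask, index=matrix.index, name="constant"),
    )
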