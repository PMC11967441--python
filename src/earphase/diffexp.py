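"""Negative-binomial two-group differential expression and DEG set algebra.

The model is the standard bulk RNA-seq one: fragment counts K_gj follow
NB(mean = s_j * mu_g(group), dispersion alpha_g) with Var = mu + alpha*mu^2.
Size factors come from the median-of-ratios estimator, dispersions from a
per-gene method-of-moments with optional shrinkage toward the trimmed mean of
log dispersions, and each gene gets a Wald test of log2 fold change between
the two groups with Benjamini-Hochberg FDR control.  Genes are called
differentially expressed at fold change >= 2 (inclusive) and adjusted
p < 0.05 (strict).

`NegativeBinomialWaldDE` is a scikit-learn style estimator: X is the
(samples x genes) count matrix, y the two-level group factor; fitted
per-gene results land in ``results_``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "median_of_ratios_size_factors",
    "estimate_dispersions",
    "NegativeBinomialWaldDE",
    "nb_wald_contrast",
    "bh_adjust",
    "call_degs",
    "build_deg_sets",
    "venn_partition",
    "DEGSets",
]

ALPHA_FLOOR = 1e-8


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    Reference genes are those with strictly positive counts in every sample;
    s_j = median_g counts_gj / geometric-mean_g(counts_g.).
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in all samples; "
            "supply a pseudo-reference fallback or filter samples"
        )
    ref = arr[positive]
    log_geomean = np.log(ref).mean(axis=1, keepdims=True)
    ratios = np.log(ref) - log_geomean
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    groups: pd.Series | np.ndarray | None = None,
    shrinkage: float = 0.2,
    alpha_floor: float = ALPHA_FLOOR,
) -> pd.Series:
    """Per-gene NB dispersion by method of moments on normalised counts.

    alpha_g = max((s^2 - mbar) / mbar^2, alpha_floor) where mbar is the mean
    normalised count and s^2 the (within-group, when ``groups`` is given)
    sample variance.

    With ``shrinkage`` > 0 the raw estimates are moderated: log dispersions
    are shrunk toward their 20% trimmed mean (computed over genes with a
    positive raw estimate) and never allowed below that central value, and
    genes whose raw estimate is non-positive (no evidence of overdispersion,
    which at few replicates is mostly sampling noise) fall back to the
    center.  Downward errors in alpha inflate the Wald statistic far more
    than upward errors deflate it, so the one-sided bound is what keeps the
    test calibrated at n = 3 replicates.  With ``shrinkage`` = 0 the raw
    floored moment estimator is returned unchanged.
    """
    norm = counts.to_numpy(dtype=float) / size_factors.reindex(counts.columns).to_numpy()
    mbar = norm.mean(axis=1)
    if groups is None:
        resid = norm - mbar[:, None]
        dof = norm.shape[1] - 1
    else:
        groups = np.asarray(groups)
        resid = np.empty_like(norm)
        dof = 0
        for level in np.unique(groups):
            cols = groups == level
            if cols.sum() < 2:
                raise ValueError(
                    f"group {level!r} has a single replicate; "
                    "supply a global fallback dispersion instead"
                )
            resid[:, cols] = norm[:, cols] - norm[:, cols].mean(axis=1, keepdims=True)
            dof += cols.sum() - 1
    s2 = (resid**2).sum(axis=1) / max(dof, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 - mbar) / np.square(mbar)
    raw = np.where(np.isfinite(raw), raw, 0.0)
    if shrinkage <= 0 or len(raw) < 2:
        return pd.Series(np.maximum(raw, alpha_floor), index=counts.index, name="dispersion")
    positive = raw > 0
    if positive.any():
        center = float(stats.trim_mean(np.log(raw[positive]), 0.2))
    else:
        center = float(np.log(alpha_floor))
    shrunk = np.exp(
        (1.0 - shrinkage) * np.log(np.where(positive, raw, 1.0)) + shrinkage * center
    )
    alpha = np.where(positive, np.maximum(shrunk, np.exp(center)), np.exp(center))
    return pd.Series(np.maximum(alpha, alpha_floor), index=counts.index, name="dispersion")


def _nb_group_mle(
    counts: np.ndarray,
    size_factors: np.ndarray,
    alpha: np.ndarray,
    n_iter: int = 50,
    tol: float = 1e-10,
) -> np.ndarray:
    """Vectorised Newton MLE of the NB mean per gene with fixed dispersion.

    Model: K_j ~ NB(mean s_j * mu, dispersion alpha); solves
    d/dmu sum_j [K_j log(s_j mu) - (K_j + 1/alpha) log(1 + alpha s_j mu)] = 0.
    Genes with all-zero counts return mu = 0.
    """
    K = counts
    s = size_factors[None, :]
    ksum = K.sum(axis=1)
    mu = np.maximum((K / s).mean(axis=1), 1e-8)
    zero = ksum == 0
    a = alpha
    for _ in range(n_iter):
        m = s * mu[:, None]
        denom = 1.0 + a[:, None] * m
        score = (K / np.maximum(mu[:, None], 1e-300)).sum(axis=1) - (
            (K + 1.0 / a[:, None]) * a[:, None] * s / denom
        ).sum(axis=1)
        # derivative of the score wrt mu
        d_score = -(K / np.maximum(mu[:, None] ** 2, 1e-300)).sum(axis=1) + (
            (K + 1.0 / a[:, None]) * (a[:, None] * s) ** 2 / denom**2
        ).sum(axis=1)
        step = np.where(d_score != 0, score / d_score, 0.0)
        new_mu = np.clip(mu - step, mu * 0.1, mu * 10.0)
        converged = np.abs(new_mu - mu) <= tol * np.maximum(mu, 1.0)
        mu = new_mu
        if converged.all():
            break
    mu[zero] = 0.0
    return mu


@dataclass
class DEGSets:
    """Named DEG sets: per-contrast calls plus phase unions and Venn regions."""

    line_specific: dict[str, dict[str, set[str]]]       # stage -> {"up","down"}
    development_specific: dict[str, dict[str, set[str]]]  # line -> {"V6|V7": set}
    all_stage_union: set[str] = field(default_factory=set)
    phase1_union: set[str] = field(default_factory=set)
    phase2_union: set[str] = field(default_factory=set)
    venn: dict[str, set[str]] = field(default_factory=dict)


class NegativeBinomialWaldDE(BaseEstimator):
    """Two-group negative-binomial Wald differential-expression test.

    Parameters
    ----------
    min_count : float
        Genes whose total normalised count is below this are not tested.
    shrinkage : float
        Weight of the shrinkage of log dispersions toward their trimmed mean.
    pseudo_mean : float
        Added to both fitted group means before forming the fold change, so
        all-zero groups give finite estimates.
    size_factors, dispersions : optional pre-computed values; estimated from
        the data when None.

    Attributes (after ``fit``)
    --------------------------
    results_ : DataFrame indexed by gene with columns base_mean, log2fc, se,
        stat, pvalue, padj, tested.
    size_factors_, dispersions_ : the values used.
    groups_ : the two group levels, in contrast order (log2fc is
        ``groups_[1]`` over ``groups_[0]``).
    """

    def __init__(
        self,
        min_count: float = 10.0,
        shrinkage: float = 0.2,
        pseudo_mean: float = 0.5,
        size_factors: pd.Series | None = None,
        dispersions: pd.Series | None = None,
    ) -> None:
        self.min_count = min_count
        self.shrinkage = shrinkage
        self.pseudo_mean = pseudo_mean
        self.size_factors = size_factors
        self.dispersions = dispersions

    def fit(self, X: pd.DataFrame, y: Sequence | pd.Series) -> "NegativeBinomialWaldDE":
        """Fit the per-gene two-mean NB model and Wald statistics.

        X is samples x genes (a transposed count matrix is accepted via
        :func:`nb_wald_contrast`); y holds exactly two group levels.
        """
        X = pd.DataFrame(X)
        y = np.asarray(y)
        levels = pd.unique(y)
        if len(levels) != 2:
            raise ValueError(f"need exactly two group levels, got {list(levels)}")
        if X.shape[0] != len(y):
            raise ValueError("X rows and y length differ")
        counts = X.T  # genes x samples
        if self.size_factors is not None:
            sf = self.size_factors.reindex(counts.columns)
        else:
            sf = median_of_ratios_size_factors(counts)
        if self.dispersions is not None:
            disp = self.dispersions.reindex(counts.index)
        else:
            disp = estimate_dispersions(counts, sf, groups=y, shrinkage=self.shrinkage)

        arr = counts.to_numpy(dtype=float)
        s = sf.to_numpy(dtype=float)
        a = np.maximum(disp.to_numpy(dtype=float), ALPHA_FLOOR)
        norm = arr / s[None, :]
        base_mean = norm.mean(axis=1)
        tested = norm.sum(axis=1) >= self.min_count

        mask_a = y == levels[0]
        mask_b = y == levels[1]
        if mask_a.sum() == 0 or mask_b.sum() == 0:
            raise ValueError("both groups must be non-empty")

        n_genes = arr.shape[0]
        mu_a = np.zeros(n_genes)
        mu_b = np.zeros(n_genes)
        idx = np.where(tested)[0]
        if len(idx):
            mu_a[idx] = _nb_group_mle(arr[idx][:, mask_a], s[mask_a], a[idx])
            mu_b[idx] = _nb_group_mle(arr[idx][:, mask_b], s[mask_b], a[idx])

        eps = self.pseudo_mean
        mu_a_t = mu_a + eps
        mu_b_t = mu_b + eps
        beta = np.log(mu_b_t) - np.log(mu_a_t)  # natural-log fold change

        # expected Fisher information of log mu per group at the guarded mean
        def info(mu: np.ndarray, mask: np.ndarray) -> np.ndarray:
            m = s[mask][None, :] * mu[:, None]
            return (m / (1.0 + a[:, None] * m)).sum(axis=1)

        with np.errstate(divide="ignore", invalid="ignore"):
            var = 1.0 / info(mu_a_t, mask_a) + 1.0 / info(mu_b_t, mask_b)
        se = np.sqrt(var)
        stat = np.where(se > 0, beta / se, 0.0)
        pvalue = 2.0 * stats.norm.sf(np.abs(stat))

        log2fc = beta / np.log(2.0)
        padj = np.full(n_genes, np.nan)
        if tested.any():
            padj[tested] = bh_adjust(pvalue[tested])
        pvalue = np.where(tested, pvalue, np.nan)

        self.results_ = pd.DataFrame(
            {
                "base_mean": base_mean,
                "log2fc": np.where(tested, log2fc, np.nan),
                "se": np.where(tested, se / np.log(2.0), np.nan),
                "stat": np.where(tested, stat, np.nan),
                "pvalue": pvalue,
                "padj": padj,
                "tested": tested,
            },
            index=counts.index,
        )
        self.size_factors_ = sf
        self.dispersions_ = disp
        self.groups_ = (levels[0], levels[1])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X=None) -> pd.DataFrame:
        """Return the fitted per-gene results table."""
        check_is_fitted(self, "results_")
        return self.results_


def nb_wald_contrast(
    counts: pd.DataFrame,
    groups: pd.Series | Sequence,
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    min_count: float = 10.0,
    shrinkage: float = 0.2,
) -> pd.DataFrame:
    """Functional wrapper: genes x samples counts in, per-gene DE table out."""
    est = NegativeBinomialWaldDE(
        min_count=min_count,
        shrinkage=shrinkage,
        size_factors=size_factors,
        dispersions=dispersions,
    )
    est.fit(counts.T, np.asarray(groups))
    return est.results_


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    result: pd.DataFrame,
    min_fc: float = 2.0,
    alpha: float = 0.05,
) -> dict[str, set[str]]:
    """DEG call: |log2FC| >= log2(min_fc) (inclusive) and padj < alpha (strict)."""
    tested = result[result["tested"] & result["padj"].notna()]
    sig = tested[(tested["padj"] < alpha) & (tested["log2fc"].abs() >= np.log2(min_fc))]
    return {
        "up": set(sig.index[sig["log2fc"] > 0]),
        "down": set(sig.index[sig["log2fc"] < 0]),
    }


def build_deg_sets(
    line_specific: dict[str, dict[str, set[str]]],
    development_specific: dict[str, dict[str, set[str]]],
    stage_order: Sequence[str],
    phase1_stages: Sequence[str],
) -> DEGSets:
    """Assemble the named DEG sets and the stage-wise Venn partition.

    ``line_specific`` maps stage -> {"up": set, "down": set} for the
    between-line contrast at that stage; ``development_specific`` maps
    line -> {"V6|V7": {"up":..., "down":...}}.  Phase unions follow the
    supplied contiguous Phase-I stage list.
    """
    missing = [s for s in stage_order if s not in line_specific]
    if missing:
        raise ValueError(f"stages missing a line contrast: {missing}")
    phase1 = list(phase1_stages)
    phase2 = [s for s in stage_order if s not in phase1]
    per_stage = {s: line_specific[s]["up"] | line_specific[s]["down"] for s in stage_order}
    all_union = set().union(*per_stage.values())
    p1 = set().union(*(per_stage[s] for s in phase1)) if phase1 else set()
    p2 = set().union(*(per_stage[s] for s in phase2)) if phase2 else set()
    venn = venn_partition({s: per_stage[s] for s in stage_order})
    return DEGSets(
        line_specific=line_specific,
        development_specific=development_specific,
        all_stage_union=all_union,
        phase1_union=p1,
        phase2_union=p2,
        venn=venn,
    )


def venn_partition(sets: dict[str, set]) -> dict[str, set]:
    """Exclusive Venn regions over k named sets (k <= 6).

    Each element of the union lands in exactly one region keyed by the
    sorted '+'-joined names of the sets containing it.
    """
    if not sets:
        raise ValueError("need at least one set")
    if len(sets) > 6:
        raise ValueError("Venn partition supported for at most 6 sets")
    names = list(sets)
    regions: dict[str, set] = {
        "+".join(combo): set()
        for r in range(1, len(names) + 1)
        for combo in itertools.combinations(names, r)
    }
    for element in set().union(*sets.values()):
        signature = "+".join(n for n in names if element in sets[n])
        regions[signature].add(element)
    return regions
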