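"""Phylogeny-vs-environment variance partitioning of growth strategies.

Phylogeny enters as the leading principal coordinates (classical MDS) of
the patristic distance matrix; environment as the leading principal
components of the taxon × treatment binary strategy-membership matrix. A
0/1 membership vector y is then regressed on both score blocks with an
ordinary linear model, and each block's contribution is its marginal
(type-II) sum of squares over the total sum of squares: the increase in
residual SS when the block is dropped from the full model. With correlated
blocks a commonality remainder ("shared") keeps the accounting exact:
frac_phylo + frac_env + shared + residual = 1, residual = 1 − R² of the
full model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .trees import TreeArrays

log = logging.getLogger("qsip_growth")


@dataclass
class ComponentBasis:
    source: str  # "phylogeny" | "environment"
    scores: pd.DataFrame  # taxon × k
    explained_fraction: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.explained_fraction) > 1e-9):
            raise ValidationError("explained fractions must be non-increasing")


@dataclass
class PartitionResult:
    strategy: str
    frac_phylo: float
    frac_env: float
    shared: float
    residual: float
    r2_full: float
    n: int
    details: dict = field(default_factory=dict)


def phylo_components(tree, taxa, k: int = 4) -> ComponentBasis:
    """Top-k principal coordinates of the patristic distance matrix.

    Negative eigenvalues (possible for non-Euclidean distances) are dropped
    from the explained-variance denominator and logged. The study-scale
    expectation is that four axes carry over 80% of the phylogenetic
    variance; a shortfall is logged, not an error.
    """
    import warnings as _warnings

    from skbio import DistanceMatrix
    from skbio.stats.ordination import pcoa
    ta = TreeArrays.from_phylogeny(tree) if not isinstance(tree, TreeArrays) else tree
    taxa = list(taxa)
    if k >= len(taxa):
        raise ValidationError(f"k={k} must be < number of taxa ({len(taxa)})")
    missing = [t for t in taxa if t not in ta.tip_index]
    if missing:
        raise ValidationError(f"taxa not in tree: {missing[:5]}")
    idx = np.array([ta.tip_index[t] for t in taxa])
    dist = ta.cophenetic()[np.ix_(idx, idx)]
    with _warnings.catch_warnings():
        # full spectrum wanted: the negative/positive eigenvalue split feeds
        # the explained-variance denominator
        _warnings.filterwarnings("ignore", message=".*EIGH.*")
        res = pcoa(DistanceMatrix(dist, ids=taxa), method="eigh")
    eig = res.eigvals.to_numpy()
    neg = eig < -1e-10 * max(abs(eig).max(), 1.0)
    if neg.any():
        log.info("PCoA: dropping %d negative eigenvalue(s) from the "
                 "explained-variance denominator", int(neg.sum()))
    pos_total = eig[eig > 0].sum()
    explained = np.clip(eig[:k], 0, None) / pos_total
    if explained.sum() < 0.80:
        log.info("first %d phylogenetic axes carry %.1f%% of variance "
                 "(study-scale datasets exceeded 80%%)", k, 100 * explained.sum())
    scores = res.samples.iloc[:, :k].copy()
    scores.index = taxa
    scores.columns = [f"phylo_PC{i+1}" for i in range(k)]
    return ComponentBasis("phylogeny", scores, explained)


def environment_components(strategy_matrix: pd.DataFrame, k: int = 2) -> ComponentBasis:
    """Top-k PCA scores of the taxon × treatment binary membership matrix."""
    from sklearn.decomposition import PCA
    X = strategy_matrix.to_numpy(dtype=float)
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValidationError("strategy matrix must be binary")
    if k > X.shape[1]:
        raise ValidationError(f"k={k} exceeds number of treatments {X.shape[1]}")
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    explained = pca.explained_variance_ratio_
    if explained.sum() < 0.65:
        log.info("first %d environment axes carry %.1f%% of variance "
                 "(study-scale datasets exceeded 65%%)", k, 100 * explained.sum())
    df = pd.DataFrame(scores, index=strategy_matrix.index,
                      columns=[f"env_PC{i+1}" for i in range(k)])
    return ComponentBasis("environment", df, explained)


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def partition(y, phylo: ComponentBasis, env: ComponentBasis,
              strategy: str = "") -> PartitionResult:
    """Type-II variance partition of a 0/1 membership vector.

    ``y`` is aligned to the score rows by index when it is a Series. The
    nested-model ΔR² fractions coincide with the type-II fractions by
    construction here (both are the R² drop when a block is removed); under
    orthogonal blocks the shared component is zero.
    """
    if isinstance(y, pd.Series):
        common = phylo.scores.index.intersection(env.scores.index).intersection(y.index)
        yv = y.loc[common].to_numpy(dtype=float)
        P = phylo.scores.loc[common].to_numpy()
        E = env.scores.loc[common].to_numpy()
    else:
        yv = np.asarray(y, dtype=float)
        P = phylo.scores.to_numpy()
        E = env.scores.to_numpy()
    n = len(yv)
    if not (len(P) == len(E) == n):
        raise ValidationError("y, phylo scores and env scores are not row-aligned")
    ones = np.ones((n, 1))
    X_full = np.hstack([ones, P, E])
    rank = np.linalg.matrix_rank(X_full)
    if rank < X_full.shape[1]:
        names = ["intercept"] + list(phylo.scores.columns) + list(env.scores.columns)
        raise ValidationError(
            f"design matrix rank {rank} < {X_full.shape[1]} columns; "
            f"collinear among {names}")
    tss = float(((yv - yv.mean()) ** 2).sum())
    if tss == 0:
        raise ValidationError("membership vector y has zero variance")
    rss_full = _rss(yv, X_full)
    rss_no_p = _rss(yv, np.hstack([ones, E]))
    rss_no_e = _rss(yv, np.hstack([ones, P]))
    frac_p = (rss_no_p - rss_full) / tss
    frac_e = (rss_no_e - rss_full) / tss
    r2_full = 1 - rss_full / tss
    shared = r2_full - frac_p - frac_e
    residual = 1 - r2_full
    return PartitionResult(
        strategy=strategy, frac_phylo=frac_p, frac_env=frac_e,
        shared=shared, residual=residual, r2_full=r2_full, n=n,
        details={"rss_full": rss_full, "rss_no_phylo": rss_no_p,
                 "rss_no_env": rss_no_e, "tss": tss,
                 "delta_r2_phylo": frac_p, "delta_r2_env": frac_e})
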