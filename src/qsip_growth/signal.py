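"""Binary-trait phylogenetic signal: Fritz–Purvis D, Blomberg's K,
Pagel's λ, and the nearest taxon index (NTI).

All four indices share the same ingredients — a rooted tree with branch
lengths and a 0/1 trait on its tips — and permutation or simulation null
models:

* D scales the observed sum of sister-clade differences between the mean
  expected under random tip shuffling (D = 1) and under Brownian evolution
  thresholded at the observed prevalence (D = 0); smaller D means stronger
  phylogenetic clumping.
* K compares the trait's variance structure with the Brownian expectation on
  the same tree (K = 1 under Brownian motion; K → 0 for random traits).
* λ scales the off-diagonal tree covariance to maximise a Gaussian GLS
  likelihood; λ = 0 is independence, λ = 1 full Brownian covariance.
* NTI is minus the standardised effect size of the mean nearest-taxon
  patristic distance of the trait's members against equal-size random tip
  sets; positive NTI with small p indicates terminal clustering.

Binary traits are fed to K and λ as continuous 0/1 values. Permutation
p-values use the add-one convention, p = (1 + #{null at least as extreme}) /
(n_null + 1), so p is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .errors import ValidationError
from .trees import TreeArrays

__all__ = ["SignalResult", "sum_sister_differences", "phylo_d", "blomberg_k",
           "pagel_lambda", "nti"]


@dataclass
class SignalResult:
    index_name: str
    estimate: float
    p_value: float
    n_null: int
    null_mean: float
    null_sd: float
    n_taxa: int
    extras: dict = field(default_factory=dict)


def _as_arrays(tree) -> TreeArrays:
    return tree if isinstance(tree, TreeArrays) else TreeArrays.from_phylogeny(tree)


def _check_binary(x: np.ndarray):
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValidationError("trait must be binary (0/1)")
    prev = x.mean()
    if not 0 < prev < 1:
        raise ValidationError(f"degenerate trait prevalence {prev}")
    return prev


def threshold_at_count(values: np.ndarray, m: int) -> np.ndarray:
    """Binarise each column of ``values`` so exactly ``m`` entries are 1.

    The m largest values get 1; ties are broken by rank (stable argsort), so
    every null replicate matches the observed prevalence exactly.
    """
    vals = np.atleast_2d(values.T).T
    out = np.zeros_like(vals)
    order = np.argsort(-vals, axis=0, kind="stable")
    rows = order[:m]
    np.put_along_axis(out, rows, 1.0, axis=0)
    return out if values.ndim > 1 else out[:, 0]


def sum_sister_differences(tree, trait) -> float:
    """Observed Σd: summed sister-clade differences of node-averaged values."""
    ta = _as_arrays(tree)
    if ta.n_tips < 4:
        raise ValidationError("need at least 4 tips")
    x = ta.trait_vector(trait)
    return float(ta.sister_diff_sums(x)[0])


def phylo_d(tree, trait, n_null: int = 1000, seed: int = 0,
            rng: np.random.Generator | None = None) -> SignalResult:
    """Fritz–Purvis dispersion D of a binary trait.

    D = (Σd_obs − mean Σd_Brownian) / (mean Σd_random − mean Σd_Brownian);
    1 means the tips look shuffled at random, 0 means as clumped as a
    thresholded Brownian trait of the same prevalence. ``p_value`` is the
    random-null probability of a trait at least as clumped as observed;
    the Brownian-null analogue is in ``extras["p_brownian"]``.
    """
    if n_null < 100:
        raise ValidationError("n_null must be >= 100 for a stable D")
    ta = _as_arrays(tree)
    if ta.n_tips < 4:
        raise ValidationError("need at least 4 tips")
    x = ta.trait_vector(trait)
    _check_binary(x)
    m = int(x.sum())
    rng = rng or np.random.default_rng(seed)

    sd_obs = float(ta.sister_diff_sums(x)[0])
    perms = np.stack([rng.permutation(x) for _ in range(n_null)], axis=1)
    sd_rand = ta.sister_diff_sums(perms)
    bm = ta.simulate_bm(n_null, rng)
    sd_brown = ta.sister_diff_sums(threshold_at_count(bm, m))

    denom = sd_rand.mean() - sd_brown.mean()
    d = (sd_obs - sd_brown.mean()) / denom
    p_random = (1 + int((sd_rand <= sd_obs).sum())) / (n_null + 1)
    p_brownian = (1 + int((sd_brown <= sd_obs).sum())) / (n_null + 1)
    return SignalResult(
        index_name="D", estimate=float(d), p_value=p_random, n_null=n_null,
        null_mean=float(sd_rand.mean()), null_sd=float(sd_rand.std(ddof=1)),
        n_taxa=ta.n_tips,
        extras={"sd_obs": sd_obs, "p_random": p_random, "p_brownian": p_brownian,
                "brownian_mean": float(sd_brown.mean()),
                "brownian_sd": float(sd_brown.std(ddof=1)),
                "prevalence": m / ta.n_tips})


def _k_statistic(X: np.ndarray, Ci: np.ndarray, w: np.ndarray,
                 expected: float) -> np.ndarray:
    """Blomberg's K for each column of X given the inverse covariance."""
    a = (w @ X) / w.sum()
    R = X - a[None, :]
    num = (R * R).sum(axis=0)
    den = (R * (Ci @ R)).sum(axis=0)
    return (num / den) / expected


def blomberg_k(tree, trait, n_null: int = 1000, seed: int = 0) -> SignalResult:
    """Blomberg's K with a tip-shuffling permutation test.

    K = (MSE0/MSE)_observed / (MSE0/MSE)_Brownian-expected, where MSE0 uses
    deviations from the GLS grand mean and MSE the Brownian covariance C;
    the expectation is (tr C − n/Σ C⁻¹) / (n − 1). p is the add-one fraction
    of permuted K at least as large as observed.
    """
    ta = _as_arrays(tree)
    if ta.n_tips < 4:
        raise ValidationError("need at least 4 tips")
    x = ta.trait_vector(trait)
    if np.ptp(x) == 0:
        raise ValidationError("trait has zero variance")
    C = ta.vcv()
    try:
        Ci = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("singular Brownian covariance matrix") from exc
    n = ta.n_tips
    expected = (np.trace(C) - n / Ci.sum()) / (n - 1)
    w = Ci @ np.ones(n)
    k_obs = float(_k_statistic(x[:, None], Ci, w, expected)[0])
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(x) for _ in range(n_null)], axis=1)
    k_null = _k_statistic(perms, Ci, w, expected)
    p = (1 + int((k_null >= k_obs).sum())) / (n_null + 1)
    return SignalResult(index_name="K", estimate=k_obs, p_value=p, n_null=n_null,
                        null_mean=float(k_null.mean()),
                        null_sd=float(k_null.std(ddof=1)), n_taxa=n)


def _lambda_loglik(lam: float, y: np.ndarray, C: np.ndarray,
                   diag: np.ndarray) -> float:
    """Profile Gaussian GLS log-likelihood at covariance λ·C off-diagonal."""
    n = len(y)
    V = lam * C
    V[np.diag_indices(n)] = diag
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2 * np.log(np.diag(cf[0])).sum()
    Vi_y = cho_solve(cf, y)
    Vi_1 = cho_solve(cf, np.ones(n))
    a = (np.ones(n) @ Vi_y) / (np.ones(n) @ Vi_1)
    r = y - a
    sigma2 = float(r @ cho_solve(cf, r)) / n
    if sigma2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def _fit_lambda(y: np.ndarray, C: np.ndarray, diag: np.ndarray):
    res = minimize_scalar(lambda l: -_lambda_loglik(l, y, C.copy(), diag),
                          bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-6})
    candidates = [(0.0, _lambda_loglik(0.0, y, C.copy(), diag)),
                  (1.0, _lambda_loglik(1.0, y, C.copy(), diag)),
                  (float(res.x), -float(res.fun))]
    lam, ll = max(candidates, key=lambda t: t[1])
    if not np.isfinite(ll):
        raise ValidationError("λ likelihood is degenerate on this tree/trait")
    return lam, ll


def pagel_lambda(tree, trait, n_null: int = 1000, seed: int = 0) -> SignalResult:
    """Maximum-likelihood Pagel's λ ∈ [0, 1] with a permutation test.

    λ multiplies the off-diagonal entries of the Brownian covariance while
    the diagonal is kept; the mean and scale are profiled out. p is the
    add-one fraction of tip-shuffled λ̂ at least as large as observed.
    """
    ta = _as_arrays(tree)
    if ta.n_tips < 4:
        raise ValidationError("need at least 4 tips")
    y = ta.trait_vector(trait)
    if np.ptp(y) == 0:
        raise ValidationError("trait has zero variance")
    C = ta.vcv()
    diag = np.diag(C).copy()
    lam_obs, ll_obs = _fit_lambda(y, C, diag)
    rng = np.random.default_rng(seed)
    lam_null = np.empty(n_null)
    for i in range(n_null):
        lam_null[i], _ = _fit_lambda(rng.permutation(y), C, diag)
    p = (1 + int((lam_null >= lam_obs).sum())) / (n_null + 1)
    null_sd = float(lam_null.std(ddof=1)) if n_null > 1 else float("nan")
    return SignalResult(index_name="lambda", estimate=float(lam_obs), p_value=p,
                        n_null=n_null, null_mean=float(lam_null.mean()),
                        null_sd=null_sd, n_taxa=ta.n_tips,
                        extras={"loglik": ll_obs})


def mntd(dist: np.ndarray, idx: np.ndarray) -> float:
    """Mean distance from each member to its nearest other member."""
    sub = dist[np.ix_(idx, idx)].astype(float)
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def nti(tree, member_set, n_null: int = 1000, seed: int = 0) -> SignalResult:
    """Nearest taxon index of a tip set with an equal-size random-set null.

    NTI = −(MNTD_obs − null mean)/null sd; p = (1 + #{null MNTD ≤ obs}) /
    (n_null + 1), so NTI > 0 with p < 0.05 indicates terminal phylogenetic
    clustering. The degenerate all-tips set returns NTI = 0.
    """
    ta = _as_arrays(tree)
    members = sorted(member_set)
    missing = [m for m in members if m not in ta.tip_index]
    if missing:
        raise ValidationError(f"member(s) not tree tips: {missing[:5]}")
    if len(members) < 2:
        raise ValidationError("member set needs at least 2 tips")
    idx = np.array([ta.tip_index[m] for m in members])
    dist = ta.cophenetic()
    obs = mntd(dist, idx)
    rng = np.random.default_rng(seed)
    null = np.empty(n_null)
    for i in range(n_null):
        null[i] = mntd(dist, rng.permutation(ta.n_tips)[:len(idx)])
    sd = null.std(ddof=1)
    est = 0.0 if sd == 0 else -(obs - null.mean()) / sd
    p = (1 + int((null <= obs).sum())) / (n_null + 1)
    return SignalResult(index_name="NTI", estimate=float(est), p_value=p,
                        n_null=n_null, null_mean=float(null.mean()),
                        null_sd=float(sd), n_taxa=ta.n_tips,
                        extras={"mntd_obs": obs, "n_members": len(idx)})
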