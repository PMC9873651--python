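"""¹⁸O-qSIP estimation: buoyant-density shifts → excess atom fraction → growth.

The chain per taxon and treatment/day cell:

1. Weighted-average density (WAD) of the taxon in every tube, using the
   in-window fractions: W = Σ_f x_f y_if / Σ_f y_if, with x_f the fraction
   density and y_if the taxon's absolute 16S copies in fraction f.
2. W_LIGHT = mean WAD over the ¹⁶O replicate tubes; from it the taxon's GC
   content and light/heavy DNA molecular weights.
3. Per ¹⁸O tube, the labelled molecular weight M_LAB = (W_LAB/W_LIGHT)·M_LIGHT
   and the excess atom fraction
   EAF = (M_LAB − M_LIGHT)/(M_HEAVY − M_LIGHT) · (1 − c), c the natural ¹⁸O
   abundance; tube EAFs are averaged for the point estimate.
4. Unlabelled copies N_LIGHT = N_TOTAL·(M_HEAVY − M_LAB)/(M_HEAVY − M_LIGHT)
   (clamped to [0, N_TOTAL]); under exponential growth the rate is
   g = ln(N_TOTAL/N_LIGHT)/t and the production of new gene copies is
   dN/dt = N_TOTAL·(1 − e^{−g t})/t.

Uncertainty comes from resampling replicate tubes with replacement,
independently within the ¹⁶O and ¹⁸O arms, re-running the whole chain each
iteration; the replicate tube is the independent unit. With three tubes per
arm a plain percentile interval of the resampled statistic is badly
anti-conservative (the bootstrap variance of a mean at n=3 is only
(n−1)/n of the sampling variance, and the resampled-mean distribution has
thin tails), so the default interval is t-calibrated: point estimate ±
t_{df}·SE_boot, with SE_boot the bootstrap standard deviation inflated by
sqrt(n/(n−1)) and df = n16 + n18 − 2. The literal percentile 2.5/97.5
interval is available via ``ci_method="percentile"``. A taxon is an
"incorporator" in a treatment when the lower 95% bound of g is positive
for at least one incubation interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import QsipError, ValidationError
from .model import DAY_TO_INTERVAL, INTERVAL_DAYS, QsipExperiment
from .util import rng_for

log = logging.getLogger("qsip_growth")


@dataclass(frozen=True)
class QsipConstants:
    """Calibration constants of the density↔GC↔molecular-weight relations.

    GC = (W_LIGHT − 1.66)/0.098; M_LIGHT = 0.496·GC + 307.691 g/mol;
    full ¹⁸O labelling adds 12.07747 g/mol; natural ¹⁸O abundance 0.002000429.
    """

    density_intercept: float = 1.66
    density_slope: float = 0.098
    mw_gc_slope: float = 0.496
    mw_intercept: float = 307.691
    heavy_increment: float = 12.07747
    natural_abundance: float = 0.002000429


DEFAULT_CONSTANTS = QsipConstants()


# ---------------------------------------------------------------------------
# elementary operations (scalar or vectorised over taxa)
# ---------------------------------------------------------------------------

def wad(densities, copies):
    """Copy-weighted mean buoyant density; NaN where a taxon has no copies."""
    dens = np.asarray(densities, dtype=float)
    y = np.atleast_2d(np.asarray(copies, dtype=float))
    tot = y.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (y * dens[None, :]).sum(axis=1) / tot
    w[tot == 0] = np.nan
    return w if np.ndim(copies) > 1 else float(w[0])


def taxon_tube_wad(experiment: QsipExperiment, tube_id: str,
                   window: bool = True) -> pd.Series:
    """Per-taxon WAD in one tube over its in-window fractions.

    Taxa with zero copies in the tube are omitted (logged, not an error).
    """
    dens, copies = experiment.tube_profile(tube_id, window=window)
    if len(dens) < 2:
        raise ValidationError(
            f"tube {tube_id!r} has {len(dens)} in-window fraction(s); need >= 2")
    w = wad(dens, copies.to_numpy())
    out = pd.Series(w, index=copies.index, name=tube_id)
    n_zero = int(out.isna().sum())
    if n_zero:
        log.debug("tube %s: %d taxa with zero copies omitted", tube_id, n_zero)
    return out.dropna()


def molecular_weights(w_light, const: QsipConstants = DEFAULT_CONSTANTS):
    """GC content and light/heavy DNA molecular weights from unlabelled WAD.

    GC far outside [0, 1] signals a density calibration problem: a warning
    beyond ±0.1, an error beyond ±0.5.
    """
    w = np.asarray(w_light, dtype=float)
    gc = (w - const.density_intercept) / const.density_slope
    finite = gc[np.isfinite(gc)]
    if finite.size and ((finite < -0.5).any() or (finite > 1.5).any()):
        raise QsipError(
            f"GC content outside [-0.5, 1.5] (min {finite.min():.3g}, "
            f"max {finite.max():.3g}); density calibration suspect")
    if finite.size and ((finite < -0.1).any() or (finite > 1.1).any()):
        log.warning("GC content outside [-0.1, 1.1] for %d taxa; "
                    "density calibration suspect",
                    int(((finite < -0.1) | (finite > 1.1)).sum()))
    m_light = const.mw_gc_slope * gc + const.mw_intercept
    m_heavy = m_light + const.heavy_increment
    if np.ndim(w_light) == 0:
        return float(gc), float(m_light), float(m_heavy)
    return gc, m_light, m_heavy


def excess_atom_fraction(w_lab, w_light, m_light, m_heavy,
                         const: QsipConstants = DEFAULT_CONSTANTS):
    """Labelled molecular weight and excess ¹⁸O atom fraction.

    Negative EAF is allowed (sampling noise); values below −0.05 are logged.
    """
    w_lab = np.asarray(w_lab, dtype=float)
    m_lab = (w_lab / np.asarray(w_light, dtype=float)) * np.asarray(m_light, dtype=float)
    eaf = (m_lab - m_light) / (np.asarray(m_heavy) - np.asarray(m_light)) \
        * (1.0 - const.natural_abundance)
    flat = np.atleast_1d(eaf)
    n_low = int((flat[np.isfinite(flat)] < -0.05).sum())
    if n_low:
        log.warning("%d EAF value(s) below -0.05; check gradient calibration", n_low)
    if np.ndim(w_lab) == 0 and np.ndim(m_light) == 0:
        return float(m_lab), float(eaf)
    return m_lab, eaf


def unlabeled_copies(n_total, m_light, m_lab, m_heavy):
    """N_LIGHT = N_TOTAL·(M_HEAVY − M_LAB)/(M_HEAVY − M_LIGHT), clamped.

    M_LAB beyond M_HEAVY (over-labelling noise) clamps to 0 with a warning.
    """
    frac = (np.asarray(m_heavy, dtype=float) - np.asarray(m_lab, dtype=float)) / (
        np.asarray(m_heavy, dtype=float) - np.asarray(m_light, dtype=float))
    flat = np.atleast_1d(frac)
    n_over = int((flat[np.isfinite(flat)] < 0).sum())
    if n_over:
        log.warning("%d taxa with M_LAB > M_HEAVY; N_LIGHT clamped to 0", n_over)
    out = np.asarray(n_total, dtype=float) * np.clip(frac, 0.0, 1.0)
    return float(out) if np.ndim(out) == 0 else out


def growth_rate(n_total, n_light, t):
    """Exponential growth rate g = ln(N_TOTAL/N_LIGHT)/t (1/day).

    N_LIGHT = 0 yields +inf (fully labelled within t); N_LIGHT > N_TOTAL
    yields negative g, both left to the caller to flag.
    """
    if t <= 0:
        raise ValidationError("incubation time must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.log(np.asarray(n_total, dtype=float) /
                   np.asarray(n_light, dtype=float)) / t
    return float(g) if np.ndim(g) == 0 else g


def production_rate(n_total, g, t):
    """New gene copies per g soil per day: dN/dt = N_TOTAL·(1 − e^{−g t})/t."""
    if t <= 0:
        raise ValidationError("incubation time must be positive")
    out = np.asarray(n_total, dtype=float) * (1.0 - np.exp(-np.asarray(g) * t)) / t
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# per-cell estimation with bootstrap
# ---------------------------------------------------------------------------

def _tube_matrices(exp: QsipExperiment, tubes: list[str]):
    """WAD and in-window total-copy matrices (taxa × tubes) for a tube list."""
    taxa = exp.feature_table.taxa
    wads = np.full((len(taxa), len(tubes)), np.nan)
    ntot = np.zeros((len(taxa), len(tubes)))
    for j, tube in enumerate(tubes):
        dens, copies = exp.tube_profile(tube, window=True)
        arr = copies.to_numpy()
        wads[:, j] = wad(dens, arr)
        ntot[:, j] = arr.sum(axis=1)
    return np.array(taxa, dtype=object), wads, ntot


def _nanmean_cols(mat: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Mean over resampled columns, ignoring NaN.

    mat: (n_taxa, n_tubes); idx: (n_boot, m) column indices.
    Returns (n_taxa, n_boot).
    """
    picked = mat[:, idx]  # (n_taxa, n_boot, m)
    with np.errstate(invalid="ignore"):
        return np.nanmean(picked, axis=2)


def _chain(w_light, w_lab, n_total, t, const):
    """Vectorised WAD → EAF → g → production chain on aligned arrays."""
    gc, m_light, m_heavy = molecular_weights(w_light, const)
    m_lab, eaf = excess_atom_fraction(w_lab, w_light, m_light, m_heavy, const)
    n_light = unlabeled_copies(n_total, m_light, m_lab, m_heavy)
    g = growth_rate(n_total, n_light, t)
    prod = production_rate(n_total, g, t)
    return gc, eaf, n_light, g, prod


def estimate_growth(exp: QsipExperiment, n_boot: int = 1000,
                    ci_level: float = 0.95, seed: int = 0,
                    const: QsipConstants = DEFAULT_CONSTANTS,
                    treatments=None, days=None,
                    ci_method: str = "t") -> pd.DataFrame:
    """Per-taxon growth estimates for every (treatment, interval) cell.

    Returns a tidy frame with one row per taxon × treatment × interval,
    carrying the full chain (W_light, W_lab, GC, EAF, N_TOTAL, N_LIGHT, g,
    production), percentile bootstrap CI bounds on g, and the incorporator
    flag (bootstrap lower bound of g positive in ≥1 interval of the
    treatment). Taxa without copies in at least one tube of each isotope arm
    are skipped.
    """
    if not 0 < ci_level < 1:
        raise ValidationError("ci_level must be in (0, 1)")
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    if ci_method not in ("t", "percentile"):
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    alpha = 100 * (1 - ci_level) / 2
    sdf = exp.manifest_frame()
    treatments = treatments or sorted(sdf["treatment"].unique(),
                                      key=str)
    rows = []
    for trt in treatments:
        cell_days = days or sorted(d for d in sdf.loc[
            (sdf["treatment"] == trt) & (sdf["day"] > 0), "day"].unique())
        for day in cell_days:
            interval = DAY_TO_INTERVAL[int(day)]
            t = INTERVAL_DAYS[interval]
            t16 = exp.tubes(trt, day, "16O")
            t18 = exp.tubes(trt, day, "18O")
            if not t16 or not t18:
                log.warning("cell (%s, day %s): missing an isotope arm; skipped",
                            trt, day)
                continue
            taxa, w16, n16 = _tube_matrices(exp, t16)
            _, w18, n18 = _tube_matrices(exp, t18)

            with np.errstate(invalid="ignore"):
                w_light = np.nanmean(w16, axis=1)
                w_lab = np.nanmean(w18, axis=1)
            n_total = np.concatenate([n16, n18], axis=1).mean(axis=1)
            usable = np.isfinite(w_light) & np.isfinite(w_lab) & (n_total > 0)

            gc, m_light, m_heavy = molecular_weights(
                np.where(usable, w_light, np.nan), const)
            # per-tube EAF, then average (replicate tube = independent unit)
            m_lab_t, eaf_t = excess_atom_fraction(
                w18, w_light[:, None], m_light[:, None], m_heavy[:, None], const)
            with np.errstate(invalid="ignore"):
                eaf = np.nanmean(eaf_t, axis=1)
            m_lab = m_light + eaf / (1 - const.natural_abundance) * (m_heavy - m_light)
            n_light = unlabeled_copies(n_total, m_light, m_lab, m_heavy)
            g = growth_rate(n_total, n_light, t)
            prod = production_rate(n_total, g, t)

            ci_lo = np.full(len(taxa), np.nan)
            ci_hi = np.full(len(taxa), np.nan)
            g_med = np.full(len(taxa), np.nan)
            if len(t16) >= 2 and len(t18) >= 2:
                rng = rng_for(seed, "bootstrap", trt, day)
                i16 = rng.integers(0, len(t16), size=(n_boot, len(t16)))
                i18 = rng.integers(0, len(t18), size=(n_boot, len(t18)))
                wl_b = _nanmean_cols(w16, i16)           # (taxa, boot)
                gc_b = (wl_b - const.density_intercept) / const.density_slope
                ml_b = const.mw_gc_slope * gc_b + const.mw_intercept
                mh_b = ml_b + const.heavy_increment
                w18_b = w18[:, i18]                      # (taxa, boot, m)
                with np.errstate(invalid="ignore", divide="ignore"):
                    eaf_b = np.nanmean(
                        ((w18_b / wl_b[:, :, None]) * ml_b[:, :, None]
                         - ml_b[:, :, None]) / (mh_b - ml_b)[:, :, None]
                        * (1 - const.natural_abundance), axis=2)
                nt_b = (n16[:, i16].sum(axis=2) + n18[:, i18].sum(axis=2)) / (
                    i16.shape[1] + i18.shape[1])
                frac_b = np.clip(1 - eaf_b / (1 - const.natural_abundance), 0, 1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    g_b = -np.log(frac_b) / t
                g_b[~np.isfinite(nt_b) | (nt_b <= 0)] = np.nan
                with np.errstate(invalid="ignore"):
                    ok = np.isfinite(g_b).any(axis=1)
                    g_med[ok] = np.nanmedian(g_b[ok], axis=1)
                    if ci_method == "percentile":
                        ci_lo[ok] = np.nanpercentile(g_b[ok], alpha, axis=1)
                        ci_hi[ok] = np.nanpercentile(g_b[ok], 100 - alpha, axis=1)
                    else:
                        from scipy.stats import t as t_dist
                        n_min = min(len(t16), len(t18))
                        infl = np.sqrt(n_min / (n_min - 1))
                        df = len(t16) + len(t18) - 2
                        tq = t_dist.ppf(1 - (1 - ci_level) / 2, df)
                        se = np.nanstd(g_b[ok], axis=1, ddof=1) * infl
                        ci_lo[ok] = g[ok] - tq * se
                        ci_hi[ok] = g[ok] + tq * se

            cell = pd.DataFrame({
                "taxon": taxa, "treatment": trt, "interval": interval,
                "W_light": w_light, "W_lab": w_lab, "GC": gc, "EAF": eaf,
                "N_TOTAL": n_total, "N_LIGHT": n_light, "g": g,
                "production": prod, "g_boot_median": g_med,
                "ci_low": ci_lo, "ci_high": ci_hi,
                "n_tubes_16O": len(t16), "n_tubes_18O": len(t18),
            })
            rows.append(cell[usable])
    if not rows:
        raise QsipError("no estimable (treatment, day) cells in the experiment")
    out = pd.concat(rows, ignore_index=True)
    incorp = identify_incorporators(out)
    out["incorporator"] = [
        (t, trt) in incorp for t, trt in zip(out["taxon"], out["treatment"])]
    return out


def bootstrap_growth(exp: QsipExperiment, taxon: str, treatment: str,
                     interval: str, n_iter: int = 1000, seed: int = 0,
                     ci_level: float = 0.95,
                     const: QsipConstants = DEFAULT_CONSTANTS,
                     ci_method: str = "t"):
    """Bootstrap (median, ci_low, ci_high) of g for one taxon and cell.

    Resamples replicate tubes with replacement independently within the two
    isotope arms and re-runs the full chain each iteration. Deterministic
    given the seed. Requires ≥2 replicate tubes per arm.
    """
    day = INTERVAL_DAYS[interval]
    t16 = exp.tubes(treatment, day, "16O")
    t18 = exp.tubes(treatment, day, "18O")
    if len(t16) < 2 or len(t18) < 2:
        raise ValidationError(
            f"cell ({treatment}, {interval}) has {len(t16)} ¹⁶O and {len(t18)} "
            f"¹⁸O tubes; bootstrap needs >= 2 in each arm")
    est = estimate_growth(exp, n_boot=n_iter, ci_level=ci_level, seed=seed,
                          const=const, treatments=[treatment], days=[day],
                          ci_method=ci_method)
    row = est[(est["taxon"] == taxon) & (est["interval"] == interval)]
    if row.empty:
        raise QsipError(f"taxon {taxon!r} not estimable in ({treatment}, {interval})")
    r = row.iloc[0]
    return float(r["g_boot_median"]), float(r["ci_low"]), float(r["ci_high"])


def identify_incorporators(estimates: pd.DataFrame,
                           require_all_intervals: bool = False,
                           min_rate: float = 1e-9) -> set:
    """(taxon, treatment) pairs whose growth is significantly positive.

    Default rule: the 95% bootstrap lower bound of g exceeds zero in at
    least one incubation interval; ``require_all_intervals`` switches to all
    intervals with a CI. ``min_rate`` (1/day) guards against floating-point
    dust on exactly-zero rates; 1e-9/day is far below any biological rate.
    """
    if "ci_low" not in estimates:
        raise ValidationError("estimates lack bootstrap CI columns")
    pos = estimates.assign(sig=estimates["ci_low"] > min_rate)
    agg = pos.groupby(["taxon", "treatment"])["sig"].agg(
        "all" if require_all_intervals else "any")
    return set(agg[agg].index)


@dataclass
class CommunitySummary:
    treatment: str
    interval: str
    total_production: float
    phylum_production: pd.Series
    phylum_share: pd.Series


def community_summaries(estimates: pd.DataFrame, taxonomy) -> CommunitySummary:
    """Phylum-level cumulative production and shares for one cell.

    The estimates must share a single treatment and interval; cumulative
    phylum growth is the sum of taxon productions, and shares are
    relativised by the treatment's total.
    """
    if estimates.empty:
        raise ValidationError("empty estimate list")
    trts = estimates["treatment"].unique()
    ints = estimates["interval"].unique()
    if len(trts) != 1 or len(ints) != 1:
        raise ValidationError("estimates must share one treatment and interval")
    phyla = taxonomy.reindex(list(estimates["taxon"]))["phylum"].to_numpy()
    prod = estimates["production"].to_numpy()
    by_phylum = pd.Series(prod).groupby(phyla).sum()
    total = float(by_phylum.sum())
    share = by_phylum / total if total != 0 else by_phylum * np.nan
    return CommunitySummary(treatment=trts[0], interval=ints[0],
                            total_production=total,
                            phylum_production=by_phylum, phylum_share=share)


def density_dependence(estimates: pd.DataFrame,
                       initial_abundance: pd.Series):
    """OLS of per-capita growth (production/N_TOTAL) on initial abundance.

    Returns (slope, R², two-sided p for slope = 0). A negative significant
    slope indicates density-dependent selection.
    """
    import statsmodels.api as sm
    df = estimates.set_index("taxon")
    common = df.index.intersection(initial_abundance.index)
    if len(common) < 3:
        raise ValidationError("need >= 3 taxa with initial abundances")
    y = (df.loc[common, "production"] / df.loc[common, "N_TOTAL"]).to_numpy()
    x = initial_abundance.loc[common].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("initial abundances have zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return float(res.params[1]), float(res.rsquared), float(res.pvalues[1])
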