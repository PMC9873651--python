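"""Synthetic ¹⁸O-qSIP experiments with known ground truth.

The generator emulates the study design: four climate treatments × three
replicate tubes × {¹⁶O, ¹⁸O} water × harvests at days 1, 3 and 6, plus
unfractionated day-0 soils, with every tube separated into 20 density
fractions. Each taxon's DNA forms a Gaussian profile over the density
gradient; its centre sits at the taxon's GC-determined unlabelled density
in ¹⁶O tubes and shifts with the true ¹⁸O excess atom fraction in ¹⁸O
tubes. Copy numbers follow exponential growth from the taxon's initial
population; measurement noise enters as a lognormal factor on the
fraction-level qPCR totals and as multinomial sequencing at a configurable
depth.

Ground truth is parameterised by the interval-average growth rate g; the
true EAF at harvest day t follows as (1 − e^{−g t})·(1 − c) with c the
natural ¹⁸O abundance, because under the exponential-labelling model the
unlabelled copies are exactly the initial ones. Gaussian profile mass is
integrated over fraction bins (not point-evaluated), with the outer bins
extended to ±infinity, so fraction copies of a tube sum exactly to the
tube total and WAD recovery is unbiased on coarse grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError, ValidationError
from .model import (DAY_TO_INTERVAL, FeatureTable, FractionSample, Phylogeny,
                    TaxonomyMap, TREATMENTS)
from .qsip import DEFAULT_CONSTANTS, QsipConstants
from .trees import TreeArrays, simulate_yule
from .util import rng_for

STRATEGY_TEMPLATES = {
    # interval-average g (1/day) for intervals 0-1d, 0-3d, 0-6d; chosen so the
    # production of new copies peaks in the strategy's defining interval while
    # cumulative turnover stays below ~37%, keeping labelled DNA inside the
    # density window the study sequences (>99% of copies in-window)
    "rapid": (0.35, 0.13, 0.065),
    "intermediate": (0.10, 0.155, 0.078),
    "slow": (0.05, 0.07, 0.075),
    "inert": (0.0, 0.0, 0.0),
}

PHYLA = (
    ("Actinobacteria", "Actinobacteria"),
    ("Firmicutes", "Bacilli"),
    ("Bacteroidetes", "Sphingobacteriia"),
    ("Acidobacteria", "Acidobacteria_Gp6"),
    ("Proteobacteria", "Gammaproteobacteria"),
    ("Proteobacteria", "Alphaproteobacteria"),
    ("Chloroflexi", "Anaerolineae"),
    ("Planctomycetes", "Planctomycetia"),
)


def default_density_grid(n_fractions: int = 20) -> np.ndarray:
    """20 evenly spaced densities over 1.6775–1.7475 g/mL, of which exactly
    11 fall in the default [1.695, 1.735] analysis window."""
    return np.linspace(1.6775, 1.7475, n_fractions)


@dataclass
class SimulationConfig:
    n_taxa: int = 60
    n_fractions: int = 20
    density_grid: Optional[np.ndarray] = None
    fraction_sigma: float = 0.006  # g/mL spread of a taxon's DNA within a tube
    treatments: tuple = TREATMENTS
    replicates: int = 3
    days: tuple = (1, 3, 6)
    label_strength: float = 0.98  # atom fraction 18O of the added water
    qpcr_noise_cv: float = 0.10  # lognormal CV on fraction qPCR totals
    sequencing_depth: int = 30000  # multinomial reads per sample; 0 = exact
    seed: int = 0
    constants: QsipConstants = field(default_factory=lambda: DEFAULT_CONSTANTS)

    def __post_init__(self):
        if self.density_grid is None:
            self.density_grid = default_density_grid(self.n_fractions)
        self.density_grid = np.asarray(self.density_grid, dtype=float)
        if self.density_grid.ndim != 1 or len(self.density_grid) != self.n_fractions:
            raise ConfigError("density_grid length must equal n_fractions")
        if not (np.diff(self.density_grid) > 0).all():
            raise ConfigError("density_grid must be strictly increasing")
        if not 0 < self.label_strength <= 1:
            raise ConfigError("label_strength must be in (0, 1]")
        if min(self.n_taxa, self.replicates, self.n_fractions) < 1 \
                or self.fraction_sigma <= 0:
            raise ConfigError("config values must be positive")
        if self.qpcr_noise_cv < 0 or self.sequencing_depth < 0:
            raise ConfigError("noise parameters must be >= 0")


@dataclass
class GroundTruth:
    """Per-taxon generating parameters and the labels they imply."""

    taxa: pd.DataFrame        # index taxon: gc, w_light, n0, phylum, class
    rates: pd.DataFrame       # (taxon, treatment, interval): g, day, eaf, n_total
    strategies: pd.DataFrame  # (taxon, treatment): strategy (or "inert")

    def rate_lookup(self):
        return self.rates.set_index(["taxon", "treatment", "interval"])


def _true_eaf(g: float, day: float, label_strength: float,
              const: QsipConstants) -> float:
    labelled = 1.0 - np.exp(-g * day)
    if labelled > label_strength + 1e-12:
        raise ConfigError(
            f"g={g}/d over {day} d implies {labelled:.3f} of copies labelled, "
            f"more than the water's atom fraction {label_strength}")
    return labelled * (1.0 - const.natural_abundance)


def build_ground_truth(strategy_map: pd.DataFrame, config: SimulationConfig,
                       jitter: float = 0.0) -> GroundTruth:
    """Ground truth from a taxon × treatment strategy-label frame.

    Labels are drawn from ``STRATEGY_TEMPLATES``; ``jitter`` multiplies the
    template rates by independent lognormal factors and the stored strategy
    label is recomputed from the jittered trajectory, so truth and labels
    stay consistent.
    """
    rng = rng_for(config.seed, "ground_truth")
    taxa = list(strategy_map.index)
    gc = rng.uniform(0.45, 0.62, size=len(taxa))
    w_light = config.constants.density_intercept + config.constants.density_slope * gc
    n0 = 10 ** rng.uniform(5.5, 7.0, size=len(taxa))
    phy = [PHYLA[i % len(PHYLA)] for i in range(len(taxa))]
    taxa_df = pd.DataFrame({
        "gc": gc, "w_light": w_light, "n0": n0,
        "phylum": [p for p, _ in phy], "class": [c for _, c in phy],
    }, index=pd.Index(taxa, name="taxon"))

    rate_rows, strat_rows = [], []
    for taxon in taxa:
        for trt in config.treatments:
            label = strategy_map.loc[taxon, trt]
            base = np.array(STRATEGY_TEMPLATES[label], dtype=float)
            if jitter > 0 and label != "inert":
                base = base * np.exp(rng.normal(0, jitter, size=3))
            n0_i = taxa_df.loc[taxon, "n0"]
            prods = [n0_i * (np.exp(g * d) - 1) / d
                     for g, d in zip(base, config.days)]
            realized = ("inert" if label == "inert"
                        else ("rapid", "intermediate", "slow")[int(np.argmax(prods))])
            strat_rows.append({"taxon": taxon, "treatment": trt,
                               "strategy": realized})
            for g, day in zip(base, config.days):
                interval = DAY_TO_INTERVAL[day]
                rate_rows.append({
                    "taxon": taxon, "treatment": trt, "interval": interval,
                    "day": float(day), "g": float(g),
                    "eaf": _true_eaf(g, day, config.label_strength,
                                     config.constants),
                    "n_total": float(n0_i * np.exp(g * day))})
    return GroundTruth(taxa=taxa_df, rates=pd.DataFrame(rate_rows),
                       strategies=pd.DataFrame(strat_rows))


def random_ground_truth(config: SimulationConfig, p_inert: float = 0.3,
                        jitter: float = 0.10) -> GroundTruth:
    """Random strategy labels per taxon/treatment at the given inert rate."""
    rng = rng_for(config.seed, "strategy_labels")
    taxa = [f"OTU{i:04d}" for i in range(1, config.n_taxa + 1)]
    labels = rng.choice(["rapid", "intermediate", "slow"],
                        size=(len(taxa), len(config.treatments)))
    inert = rng.random((len(taxa), len(config.treatments))) < p_inert
    labels = np.where(inert, "inert", labels)
    sm = pd.DataFrame(labels, index=taxa, columns=list(config.treatments))
    return build_ground_truth(sm, config, jitter=jitter)


# ---------------------------------------------------------------------------
# gradient simulation
# ---------------------------------------------------------------------------

def _bin_probabilities(centers: np.ndarray, grid: np.ndarray,
                       sigma: float) -> np.ndarray:
    """Gaussian mass per fraction bin for each profile centre.

    Bin edges are midpoints between grid densities, with the outer edges at
    ±infinity so each row sums to exactly 1 (mass conservation).
    """
    mid = (grid[1:] + grid[:-1]) / 2
    edges = np.concatenate([[-np.inf], mid, [np.inf]])
    z = (edges[None, :] - centers[:, None]) / sigma
    cdf = norm.cdf(z)
    return np.diff(cdf, axis=1)


def _labelled_center(w_light: np.ndarray, eaf: np.ndarray,
                     const: QsipConstants) -> np.ndarray:
    """Invert the EAF equation: profile centre of a taxon in an ¹⁸O tube."""
    gc = (w_light - const.density_intercept) / const.density_slope
    m_light = const.mw_gc_slope * gc + const.mw_intercept
    m_heavy = m_light + const.heavy_increment
    m_lab = m_light + eaf / (1 - const.natural_abundance) * (m_heavy - m_light)
    if (m_lab > m_heavy + 1e-9).any():
        raise ConfigError("true EAF implies M_LAB > M_HEAVY; "
                          "inconsistent with label_strength")
    return w_light * m_lab / m_light


def simulate_qsip_experiment(config: SimulationConfig, truth: GroundTruth):
    """Emit (FeatureTable, manifest samples, taxonomy, truth) for a full design."""
    taxa = list(truth.taxa.index)
    w_light = truth.taxa["w_light"].to_numpy()
    n0 = truth.taxa["n0"].to_numpy()
    grid = config.density_grid
    rates = truth.rate_lookup()
    sigma_ln = np.sqrt(np.log(1 + config.qpcr_noise_cv ** 2))

    columns: dict[str, np.ndarray] = {}
    samples: list[FractionSample] = []

    def _relative(copies: np.ndarray, rng, token) -> np.ndarray:
        tot = copies.sum()
        if tot <= 0:
            return np.zeros_like(copies)
        p = copies / tot
        if config.sequencing_depth == 0:
            return p
        counts = rng.multinomial(config.sequencing_depth, p)
        return counts / config.sequencing_depth

    for trt in config.treatments:
        for rep in range(1, config.replicates + 1):
            # unfractionated day-0 soil (natural-abundance water arm)
            rng = rng_for(config.seed, "tube", trt, 0, "16O", rep)
            tube = f"{trt}_0d_16O_r{rep}"
            tot0 = n0.sum()
            meas0 = tot0 * (np.exp(rng.normal(-sigma_ln**2 / 2, sigma_ln))
                            if sigma_ln > 0 else 1.0)
            sid = f"{tube}_unfrac"
            columns[sid] = _relative(n0, rng, "day0")
            samples.append(FractionSample(
                sample_id=sid, tube_id=tube, treatment=trt, replicate=rep,
                isotope="16O", day=0.0, fraction_index=None,
                buoyant_density=float("nan"), total_copies=float(meas0)))
            for day in config.days:
                interval = DAY_TO_INTERVAL[day]
                sub = rates.loc[[(t, trt, interval) for t in taxa]]
                g = sub["g"].to_numpy()
                eaf = sub["eaf"].to_numpy()
                n_t = n0 * np.exp(g * day)
                for iso in ("16O", "18O"):
                    rng = rng_for(config.seed, "tube", trt, day, iso, rep)
                    tube = f"{trt}_{day}d_{iso}_r{rep}"
                    centers = (w_light if iso == "16O"
                               else _labelled_center(w_light, eaf,
                                                     config.constants))
                    probs = _bin_probabilities(centers, grid,
                                               config.fraction_sigma)
                    copies = n_t[:, None] * probs  # taxa × fractions
                    totals = copies.sum(axis=0)
                    noise = (np.exp(rng.normal(-sigma_ln**2 / 2, sigma_ln,
                                               size=len(grid)))
                             if sigma_ln > 0 else np.ones(len(grid)))
                    for f in range(len(grid)):
                        sid = f"{tube}_f{f + 1}"
                        columns[sid] = _relative(copies[:, f], rng, f)
                        samples.append(FractionSample(
                            sample_id=sid, tube_id=tube, treatment=trt,
                            replicate=rep, isotope=iso, day=float(day),
                            fraction_index=f + 1,
                            buoyant_density=float(grid[f]),
                            total_copies=float(totals[f] * noise[f])))

    table = FeatureTable(pd.DataFrame(columns, index=pd.Index(taxa, name="otu_id")))
    taxonomy = TaxonomyMap(truth.taxa[["phylum", "class"]])
    return table, samples, taxonomy, truth


def simulate_experiment_tree(truth: GroundTruth, seed: int) -> Phylogeny:
    """Yule tree whose tips are exactly the truth's taxa."""
    phylo = simulate_yule(len(truth.taxa), seed)
    for lf, name in zip(sorted(phylo.tree.leaf_node_iter(),
                               key=lambda l: l.taxon.label), truth.taxa.index):
        lf.taxon.label = name
    return Phylogeny(phylo.tree)


# ---------------------------------------------------------------------------
# binary trait simulation
# ---------------------------------------------------------------------------

def simulate_binary_trait(tree, model: str, prevalence: float,
                          signal: float = 1.0, seed: int = 0,
                          rng: np.random.Generator | None = None) -> dict:
    """Binary trait on the tree tips with exact target prevalence.

    Models: "random" (uniform shuffle), "brownian_threshold" (Brownian
    trait cut at the prevalence quantile), "lambda_scaled" (multivariate
    normal with off-diagonal covariance scaled by ``signal`` ∈ [0, 1],
    interpolating identity → full Brownian, then thresholded).
    """
    ta = tree if isinstance(tree, TreeArrays) else TreeArrays.from_phylogeny(tree)
    if not 0 < prevalence < 1:
        raise ValidationError("prevalence must be in (0, 1)")
    n = ta.n_tips
    m = int(round(prevalence * n))
    if not 0 < m < n:
        raise ValidationError(f"prevalence {prevalence} rounds to a degenerate "
                              f"count on {n} tips")
    rng = rng or np.random.default_rng(seed)
    if model == "random":
        x = np.zeros(n)
        x[rng.permutation(n)[:m]] = 1.0
    elif model == "brownian_threshold":
        from .signal import threshold_at_count
        x = threshold_at_count(ta.simulate_bm(1, rng)[:, 0], m)
    elif model == "lambda_scaled":
        from .signal import threshold_at_count
        if not 0 <= signal <= 1:
            raise ValidationError("signal must be in [0, 1]")
        C = ta.vcv()
        V = signal * C
        V[np.diag_indices(n)] = np.diag(C)
        L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
        x = threshold_at_count(L @ rng.standard_normal(n), m)
    else:
        raise ValidationError(f"unknown trait model {model!r}")
    return {name: int(v) for name, v in zip(ta.tip_names, x)}


# ---------------------------------------------------------------------------
# end-to-end scenario with designated strategy shifts
# ---------------------------------------------------------------------------

def make_strategy_scenario(config: Optional[SimulationConfig] = None):
    """Noise-free fixture whose strategy and shift tables are known exactly.

    The taxon roster contains stable representatives of each strategy, one
    taxon per shift situation 1–6 (shifting in every non-control treatment),
    one eT-only accelerated taxon, one taxon inert in the control, and one
    taxon inert everywhere. Returns a dict with the experiment components,
    the ground truth, and the expected strategy/shift tables.
    """
    if config is None:
        # wide-gradient validation geometry: the whole labelled profile stays
        # on-grid, so estimated productions equal the generating ones and the
        # expected tables are exact
        config = SimulationConfig(n_taxa=12, qpcr_noise_cv=0.0,
                                  sequencing_depth=0, seed=101,
                                  density_grid=np.linspace(1.64, 1.80, 20),
                                  fraction_sigma=0.01)
    if config.qpcr_noise_cv != 0 or config.sequencing_depth != 0:
        raise ConfigError("the strategy scenario is defined noise-free")
    window = (float(config.density_grid[0]), float(config.density_grid[-1]))
    others = [t for t in config.treatments if t != "Contr"]

    roster = [
        ("stable_rapid", {"Contr": "rapid", **{t: "rapid" for t in others}}),
        ("stable_intermediate",
         {"Contr": "intermediate", **{t: "intermediate" for t in others}}),
        ("stable_slow", {"Contr": "slow", **{t: "slow" for t in others}}),
        ("sit1_slow_to_rapid",
         {"Contr": "slow", **{t: "rapid" for t in others}}),
        ("sit2_int_to_rapid",
         {"Contr": "intermediate", **{t: "rapid" for t in others}}),
        ("sit3_slow_to_int",
         {"Contr": "slow", **{t: "intermediate" for t in others}}),
        ("sit4_rapid_to_slow",
         {"Contr": "rapid", **{t: "slow" for t in others}}),
        ("sit5_rapid_to_int",
         {"Contr": "rapid", **{t: "intermediate" for t in others}}),
        ("sit6_int_to_slow",
         {"Contr": "intermediate", **{t: "slow" for t in others}}),
        ("accel_eT_only",
         {"Contr": "intermediate", "eT": "rapid",
          **{t: "intermediate" for t in others if t != "eT"}}),
        ("inert_in_control",
         {"Contr": "inert", **{t: "rapid" for t in others}}),
        ("inert_everywhere",
         {"Contr": "inert", **{t: "inert" for t in others}}),
    ]
    while len(roster) < config.n_taxa:
        roster.append((f"filler_{len(roster):03d}",
                       {t: "intermediate" for t in config.treatments}))
    strategy_map = pd.DataFrame(
        {t: [labels[t] for _, labels in roster] for t in config.treatments},
        index=[name for name, _ in roster])
    truth = build_ground_truth(strategy_map, config, jitter=0.0)
    table, samples, taxonomy, truth = simulate_qsip_experiment(config, truth)
    tree = simulate_experiment_tree(truth, config.seed)

    expected_assignments = truth.strategies[
        truth.strategies["strategy"] != "inert"].reset_index(drop=True)
    from .strategies import SITUATIONS
    shift_rows = []
    for trt in sorted(others, key=str):
        for taxon in sorted(strategy_map.index):
            a = strategy_map.loc[taxon, "Contr"]
            b = strategy_map.loc[taxon, trt]
            comparison = f"Contr-{trt}"
            if "inert" in (a, b):
                shift_rows.append({"taxon": taxon, "comparison": comparison,
                                   "shift": "not_comparable",
                                   "situation": np.nan})
            elif a == b:
                shift_rows.append({"taxon": taxon, "comparison": comparison,
                                   "shift": "unchanged", "situation": np.nan})
            else:
                code = SITUATIONS[(a, b)]
                shift_rows.append({
                    "taxon": taxon, "comparison": comparison,
                    "shift": "accelerated" if code <= 3 else "delayed",
                    "situation": float(code)})
    expected_shifts = pd.DataFrame(shift_rows)
    return {"feature_table": table, "samples": samples, "taxonomy": taxonomy,
            "tree": tree, "truth": truth, "config": config, "window": window,
            "expected_assignments": expected_assignments,
            "expected_shifts": expected_shifts}
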