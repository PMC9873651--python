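# Methods

This note documents the models, parameter choices and numerical decisions
behind `qsip_growth`, and what the synthetic-data tests do and do not show
about real data.

## The qSIP growth model

DNA built during incubation in 98 atom% H₂¹⁸O is denser than pre-existing
DNA. For each taxon *i* and tube, the copy-weighted mean buoyant density
over the analysis window, W = Σ_f x_f·y_if / Σ_f y_if, summarises its
position in the gradient; y_if is the taxon's absolute copy number in
fraction f, obtained as relative abundance (sequencing) × total 16S copies
(qPCR). The pipeline stores only proportions and derives absolute copies
on demand, so the qPCR rescaling lives in a single code path.

The density→GC→molecular-weight calibration (GC = (W−1.66)/0.098,
M_LIGHT = 0.496·GC + 307.691 g/mol, full-labelling increment
12.07747 g/mol, natural-abundance correction 0.002000429) follows the
standard qSIP procedure; all four constants sit in a `QsipConstants`
dataclass and can be overridden for other gradients or amplicons.

Growth assumes exponential dynamics with fully labelled new copies:
unlabelled copies stay at their initial number, so
N_LIGHT/N_TOTAL = (M_HEAVY − M_LAB)/(M_HEAVY − M_LIGHT) and
g = ln(N_TOTAL/N_LIGHT)/t. A consequence worth knowing: g is a function of
EAF and t alone — N_TOTAL cancels — while the production rate
N_TOTAL·(1−e^(−g·t))/t scales with abundance. N_LIGHT is clamped to
[0, N_TOTAL] with a warning rather than an error because noisy gradients
routinely put M_LAB slightly outside [M_LIGHT, M_HEAVY].

Aggregation over replicates: W_LIGHT is the mean of per-tube WADs over the
¹⁶O tubes of a treatment/day; EAF is computed per ¹⁸O tube against that
W_LIGHT and then averaged (per-tube-then-average; the alternative order is
a config choice away, `excess_atom_fraction` is pure). N_TOTAL is the mean
over tubes of both arms of the taxon's in-window copy sum, since isotope
does not affect abundance.

## Bootstrap uncertainty and the incorporator call

Replicate tubes are the independent unit, so the bootstrap resamples tubes
with replacement, independently in the two isotope arms, and re-runs the
whole chain (1000 iterations by default; seeds derive deterministically
from a master seed per treatment/day cell, shared across taxa because the
tube — not the taxon — is what is resampled).

With three tubes per arm, the *plain percentile* interval of the resampled
statistic is structurally anti-conservative: the bootstrap variance of a
mean at n = 3 is (n−1)/n of the sampling variance, and the resampled-mean
distribution has thin tails. Monte Carlo on the linearised statistic gives
~80% actual coverage for a nominal 95% interval and a ~27% family
false-positive rate for the three-interval incorporator test on inert
taxa. The default interval is therefore *t-calibrated*: point estimate ±
t_df·SE_boot, where SE_boot is the bootstrap standard deviation inflated
by √(n/(n−1)) and df = n₁₆ + n₁₈ − 2. The same Monte Carlo gives 95.4%
coverage and a 6.7% family false-positive rate at 3+3 tubes. The literal
percentile interval remains available (`ci_method="percentile"`) for
comparison with legacy qSIP outputs. Incorporator rule: lower bound of g
above zero in ≥1 interval of the treatment (configurable to all-intervals
and other CI levels); an epsilon of 1e−9/day guards against
floating-point dust on exactly-zero rates in noise-free data.

## Strategy classification and shifts

Strategy = argmax of the three interval-mean production rates (rapid ↔
0–1 d, intermediate ↔ 0–3 d, slow ↔ 0–6 d); ties break toward the earlier
interval (a measure-zero event on real data). Production, not g, is the
peak metric because community growth summaries are production-based; a
config switch selects g instead. Shifts between control and a treatment
map strategy pairs to situations 1–6; "core" shifted taxa hold the same
direction in all three comparisons. Reported percentages round half-up to
integers; exact proportions are always emitted alongside.

For pooled (all-treatment) analyses an OTU carries a strategy label if it
exhibited that strategy in *any* treatment, so the three binary labels are
non-exclusive.

## Phylogenetic signal

All indices take a rooted tree with branch lengths and a binary trait;
binary values are handed to K and λ as continuous 0/1, matching common
practice for presence/absence traits.

* **Σd and D.** Node values propagate up the tree by averaging daughters
  (branch lengths ignored); each node contributes the summed absolute
  deviation of its children from their mean (= |left−right| for
  bifurcations). D scales the observed Σd between the mean under tip
  shuffling (D = 1) and under Brownian simulation thresholded at the
  observed prevalence (D = 0); thresholding picks exactly the observed
  number of 1s, ties broken by rank. Both one-sided permutation p values
  (vs random, vs Brownian) are reported since conventions differ.
* **K** uses the GLS grand mean, the Brownian covariance C (shared
  root-to-MRCA path lengths), and the expectation
  (tr C − n/ΣC⁻¹)/(n−1); permutation p is the add-one fraction of
  tip-shuffled K at least as large as observed.
* **λ** maximises the profile Gaussian GLS log-likelihood over λ ∈ [0, 1]
  (off-diagonal of C scaled, diagonal kept; mean and scale profiled out)
  with a bounded scalar optimiser (xatol 1e−6) plus explicit endpoint
  checks, so boundary optima are exact.
* **NTI** is −SES of the mean nearest-taxon patristic distance against
  equal-prevalence random tip sets; the degenerate all-tips set returns 0
  by convention. Abundance-weighted MNTD is not implemented.

All permutation tests default to 1000 nulls and use the add-one p-value
convention; every result is deterministic given (tree, trait, seed,
n_null).

## Variance partitioning

Phylogeny is represented by the first k=4 principal coordinates of the
patristic distance matrix (negative eigenvalues are dropped from the
explained-variance denominator and logged); environment by the first k=2
principal components of the taxon × treatment binary membership matrix.
The 0/1 membership vector is fit by an ordinary linear model — a linear
probability model, deliberately not logistic — on both blocks. A block's
fraction is its marginal (type-II) sum of squares over the total sum of
squares, i.e. the R² drop when the block is removed. Because the blocks
are generally correlated, an explicit commonality term keeps the
accounting exact: frac_phylo + frac_env + shared + residual = 1 with
residual = 1 − R²_full; under orthogonal blocks shared = 0 and type-II
equals the nested-model ΔR². Note the environment matrix is built from
the same strategy distributions the model predicts; this mirrors the
study design and is kept, but the design matrix is overridable.

The "over 80%"/"over 65%" cumulative-variance figures for k=4/k=2
describe study-scale data; the package logs a note, not an error, when a
dataset falls short.

## The synthetic-data generator

Each tube is simulated as: per-taxon copies N_t = N₀·e^(g·t); a Gaussian
density profile centred at the taxon's unlabelled density (¹⁶O arms) or
at the EAF-implied labelled density (¹⁸O arms, inverting the EAF
equation), with within-tube spread `fraction_sigma` = 0.006 g/mL; profile
mass *integrated* over fraction bins (outer bins extended to ±∞), so
fraction copies sum exactly to the tube total and WAD recovery is
unbiased on coarse grids. Noise enters as a lognormal factor (CV 0.10) on
fraction qPCR totals and multinomial sequencing at depth 30 000 per
sample; zero-noise settings reproduce the analytic model exactly.
Unfractionated day-0 samples supply initial abundances.

Ground truth is parameterised by interval-average g; true EAF at day t is
(1 − e^(−g·t))·(1 − 0.002000429), capped by the water's atom fraction
(0.98) — a configuration error if a requested g implies more labelling
than the water allows. Default strategy templates (g per day for 0–1/0–3/
0–6 d: rapid 0.35/0.13/0.065, intermediate 0.10/0.155/0.078, slow
0.05/0.07/0.075) keep cumulative turnover below ~37%, which together with
GC ~ U(0.45, 0.62) keeps essentially all DNA inside the sequenced density
window — the regime the study reports (>99% of gene copies in the selected
fractions). Optional lognormal jitter perturbs templates per taxon; the
stored strategy label is always recomputed from the jittered trajectory so
truth and labels cannot disagree.

The default 20-fraction grid spans 1.6775–1.7475 g/mL evenly, placing
exactly 11 fractions in the closed [1.695, 1.735] window. Window bounds
are treated as inclusive; the bound convention is configurable.

**Validation geometries.** Exactness tests (EAF/g recovery to 1e−6; the
noise-free strategy/shift fixture) use a wider 20-fraction grid
(1.64–1.80 g/mL, sigma 0.01) with a fully covering window, because with
the study window the tails of near-window-edge profiles are truncated,
biasing WADs at the ~1e−4 g/mL level — three orders of magnitude above
the 1e−6 target but irrelevant to the 0.05-level accuracy statements,
which are tested on the study geometry. This also bounds what the tests
show about real data: truncation bias for strongly labelled, high-GC taxa
is a property of the real method too, and accuracy claims here are
median-level, not worst-case. The generator likewise does not emulate
compositional artefacts of amplicon sequencing, chimeras, primer bias, or
between-tube density calibration offsets.

**Strategy classification under noise** is only as good as the margin
between interval productions: with the default templates and noise,
adjacent-strategy confusions are common (the fixture-level exactness
claims hold only in the noise-free scenario). The incorporator call and
EAF/g point accuracy are the robust quantities.

## Problem sizes in the test suite

The suite runs the D calibration at 200 traits × 199 nulls on a 100-tip
tree, bootstrap coverage on 100 simulated 3+3-tube datasets at 1000
iterations, and recovery on one 100-taxon community; signal unit tests use
40–100 replicates at 100–500 nulls. These sizes give Monte-Carlo error
comfortably inside the asserted tolerances (e.g. ±0.1 on mean D, where the
SE at 200 traits is ~0.01–0.02) while keeping the whole suite in the tens
of seconds.
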