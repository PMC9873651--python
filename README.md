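# qsip-growth

Taxon-resolved growth-rate inference from ¹⁸O quantitative stable isotope
probing (qSIP), with growth-strategy classification, phylogenetic-signal
statistics, and phylogeny-versus-environment variance partitioning — the
analysis chain used to ask how soil bacteria respond to rewetting under
long-term warming and CO₂ enrichment.

## The problem

When dry soil is rewetted, dissolved organic matter floods the community
and bacteria resume growth on very different schedules: some taxa peak
within a day, others only after several days. ¹⁸O-qSIP makes those
schedules measurable at the taxon level. Soils are incubated with
isotopically heavy water (98 atom% H₂¹⁸O) or natural-abundance water;
growing taxa incorporate ¹⁸O into new DNA, which becomes denser. After
isopycnic (CsCl) ultracentrifugation, each tube is split into ~20 density
fractions; 16S amplicon sequencing of the fractions plus qPCR totals give
each taxon's copy number per fraction, and the copy-weighted mean density
(the weighted average density, WAD) shifts upward with ¹⁸O uptake.

The chain from fractions to ecology:

1. **WAD** per taxon and tube over the analysis window (default
   1.695–1.735 g/mL): W = Σ_f x_f·y_if / Σ_f y_if.
2. **Molecular weights** from the unlabelled WAD:
   GC = (W_LIGHT − 1.66)/0.098, M_LIGHT = 0.496·GC + 307.691 g/mol,
   M_HEAVY = M_LIGHT + 12.07747.
3. **Excess atom fraction (EAF)** of ¹⁸O per labelled tube:
   M_LAB = (W_LAB/W_LIGHT)·M_LIGHT and
   EAF = (M_LAB − M_LIGHT)/(M_HEAVY − M_LIGHT)·(1 − 0.002000429).
4. **Growth**, assuming exponential growth with fully labelled new copies:
   N_LIGHT = N_TOTAL·(M_HEAVY − M_LAB)/(M_HEAVY − M_LIGHT),
   g = ln(N_TOTAL/N_LIGHT)/t, and the production of new 16S copies
   dN/dt = N_TOTAL·(1 − e^(−g·t))/t.
5. **Uncertainty** by resampling replicate tubes (the independent unit)
   with replacement within each isotope arm; a taxon is an *incorporator*
   when the lower 95% bound of g clears zero in at least one interval.
6. **Strategies**: incorporators are classified rapid / intermediate /
   slow by the interval (0–1, 0–3, 0–6 d) of peak production; comparing a
   taxon's strategy between control and a climate treatment yields
   *accelerated* (slow→rapid, intermediate→rapid, slow→intermediate;
   situations 1–3) or *delayed* (rapid→slow, rapid→intermediate,
   intermediate→slow; situations 4–6) shifts.
7. **Phylogenetic signal** of each binary strategy trait: Fritz–Purvis D
   (1 = random tip shuffle, 0 = Brownian clumping), Blomberg's K and
   Pagel's λ (Brownian-covariance signal), and the nearest taxon index
   (NTI, terminal clustering), all with permutation or simulation nulls.
8. **Variance partitioning**: strategy membership (0/1) is regressed on
   the first four principal coordinates of the patristic distance matrix
   (phylogeny) and the first two principal components of the
   taxon × treatment membership matrix (environment); marginal (type-II)
   sums of squares give each block's variance fraction.

Everything is verifiable without the original sequence data: the
`simulate` module generates full density-gradient experiments (Gaussian
fraction profiles whose centres shift with true EAF, exponential growth,
qPCR and sequencing noise) with known ground truth, plus Yule trees and
binary traits of controlled phylogenetic signal.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seeds fixed; outputs under `results/`):

```bash
python analysis/01_simulate_experiment.py   # inputs + ground truth
python analysis/02_growth_rates.py          # qSIP chain + bootstrap
python analysis/03_classify_strategies.py   # strategies and shifts
python analysis/04_phylogenetic_signal.py   # D, K, lambda, NTI
python analysis/05_variance_partition.py    # phylogeny vs environment
```

With the default 100-taxon community (30% inert taxon-treatment cells),
`02_growth_rates.py` prints

```
1200 taxon-cells estimated; 263 of 400 taxon-treatment pairs are
incorporators (95% CI of g above zero in >=1 interval)
```

— the bootstrap flags roughly the 261 truly growing cells while the inert
cells stay unflagged. `03_classify_strategies.py` then reports
per-treatment strategy proportions and shift counts, e.g.

```
Contr-eT: 8 accelerated, 16 delayed
core strategy-changed taxa: 3 always accelerated, 0 always delayed
```

and `05_variance_partition.py` summarises, per strategy, how much of the
membership variance the phylogenetic and environmental score blocks carry:

```
slow: phylogeny 0.1%, environment 90.3%, shared 1.9%, unexplained 7.7%
```

Because this synthetic community assigns strategies without phylogenetic
structure, the signal indices in `04_phylogenetic_signal.py` hover near
their random-endpoint calibrations (D ≈ 1, K ≈ 0, λ ≈ 0, NTI ≈ 0); traits
with controlled signal for exercising the indices come from
`simulate.simulate_binary_trait(model="lambda_scaled", signal=...)`.

A `qsip-growth` console command exposes the same stages
(`simulate`, `qsip`, `classify`, `signal`, `varpart`, `all`) on a YAML
config with `--seed`, `--window`, `--iters`, `--nulls`, `--out` overrides;
every report carries a provenance header (version, config hash, seed).

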