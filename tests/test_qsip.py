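"""Unit and property tests of the WAD → EAF → growth chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsip_growth import qsip
from qsip_growth.errors import QsipError, ValidationError
from qsip_growth.qsip import (community_summaries, density_dependence,
                              excess_atom_fraction, growth_rate,
                              identify_incorporators, molecular_weights,
                              production_rate, unlabeled_copies, wad)


class TestWad:
    def test_single_occupied_fraction(self):
        assert wad([1.70, 1.71], [[0.0, 5e6]]) == pytest.approx(1.71)

    def test_symmetric_split(self):
        assert wad([1.695, 1.715], [[3e5, 3e5]]) == pytest.approx(1.705)

    def test_hand_weighted_mean(self):
        # (10*1.700 + 30*1.710 + 60*1.720) / 100 = 1.7150
        assert wad([1.700, 1.710, 1.720], [[10, 30, 60]]) == pytest.approx(1.7150)

    def test_zero_taxon_is_nan(self):
        w = wad([1.70, 1.71], [[0.0, 0.0], [1.0, 1.0]])
        assert np.isnan(w[0]) and w[1] == pytest.approx(1.705)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=1e6),
           st.integers(min_value=0, max_value=2**31 - 1))
    def test_scale_invariance(self, c, seed):
        """Multiplying all copies of a tube by a constant leaves WAD (and
        hence EAF and g) unchanged."""
        rng = np.random.default_rng(seed)
        dens = np.sort(rng.uniform(1.69, 1.74, 8))
        y = rng.uniform(0, 1e5, 8)
        assert wad(dens, [y * c]) == pytest.approx(wad(dens, [y]), rel=1e-9)


class TestMolecularWeights:
    def test_intercept_case(self):
        gc, ml, mh = molecular_weights(1.66)
        assert gc == pytest.approx(0.0)
        assert ml == pytest.approx(307.691)
        assert mh == pytest.approx(319.76847)

    def test_slope_endpoint(self):
        gc, ml, _ = molecular_weights(1.758)
        assert gc == pytest.approx(1.0)
        assert ml == pytest.approx(308.187)

    def test_arithmetic_oracle(self):
        gc, ml, mh = molecular_weights(1.7094)
        assert gc == pytest.approx(0.5040816326530624, abs=1e-12)
        assert ml == pytest.approx(307.9410244897959, abs=1e-9)
        assert mh == pytest.approx(320.0184944897959, abs=1e-9)

    def test_implausible_gc_errors(self):
        with pytest.raises(QsipError, match="calibration"):
            molecular_weights(1.60)  # GC ~ -0.61


class TestEafChain:
    def test_no_shift_is_zero(self):
        _, eaf = excess_atom_fraction(1.71, 1.71, 307.9, 319.98)
        assert eaf == pytest.approx(0.0, abs=1e-15)

    def test_full_labeling_bound(self):
        # M_LAB = M_HEAVY gives EAF = 1 - 0.002000429
        ml, mh = 307.941, 320.01849
        w_light = 1.7094
        w_lab = w_light * mh / ml
        _, eaf = excess_atom_fraction(w_lab, w_light, ml, mh)
        assert eaf == pytest.approx(0.997999571, abs=1e-9)

    def test_arithmetic_oracle(self):
        m_lab, eaf = excess_atom_fraction(1.7154, 1.7094,
                                          307.9410244897959,
                                          320.0184944897959)
        assert m_lab == pytest.approx(309.02189856662915, abs=1e-9)
        assert eaf == pytest.approx(0.08931604590900315, abs=1e-12)

    def test_unlabeled_copy_limits(self):
        assert unlabeled_copies(1e6, 307.9, 307.9, 319.98) == pytest.approx(1e6)
        assert unlabeled_copies(1e6, 307.9, 319.98, 319.98) == pytest.approx(0.0)
        # overlabelled M_LAB clamps to zero
        assert unlabeled_copies(1e6, 307.9, 321.0, 319.98) == 0.0

    def test_unlabeled_copies_oracle(self):
        n_light = unlabeled_copies(1e6, 307.941, 310.0, 320.018)
        assert n_light == pytest.approx(829510.6400596151, rel=1e-12)

    def test_growth_rate_cases(self):
        assert growth_rate(1e6, 1e6, 1.0) == pytest.approx(0.0)
        assert growth_rate(2e6, 1e6, 1.0) == pytest.approx(np.log(2))
        assert growth_rate(1e6, 829510.6400596151, 3.0) == pytest.approx(
            0.062306447452605246, abs=1e-15)
        assert growth_rate(1e6, 0.0, 1.0) == np.inf

    def test_production_cases(self):
        assert production_rate(1e6, 0.0, 3.0) == 0.0
        assert production_rate(1e6, np.log(2), 1.0) == pytest.approx(5.0e5)
        assert production_rate(1e6, 0.062306447452605246, 3.0) == pytest.approx(
            56829.786646794906, rel=1e-12)

    def test_production_approaches_ntotal_g_for_small_gt(self):
        g, t = 1e-6, 1.0
        assert production_rate(1e6, g, t) == pytest.approx(1e6 * g, rel=1e-5)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=0.9),
           st.floats(min_value=1e-4, max_value=0.09))
    def test_g_strictly_increasing_in_eaf(self, eaf, deaf):
        """For fixed N_TOTAL and t the estimated g grows with EAF."""
        def g_of(e):
            frac = 1 - e / (1 - 0.002000429)
            return -np.log(frac) / 3.0
        assert g_of(eaf + deaf) > g_of(eaf)


class TestBootstrap:
    def test_identical_tubes_degenerate_ci(self, scenario_estimates):
        """Noise-free scenario: replicate tubes are identical, so the CI
        collapses onto the point estimate."""
        est = scenario_estimates
        growing = est[est["g"] > 1e-6]
        assert np.allclose(growing["ci_low"], growing["g"], atol=1e-9)
        assert np.allclose(growing["ci_high"], growing["g"], atol=1e-9)

    def test_zero_enrichment_ci_straddles_zero(self, wide_grid):
        """Inert community with noise: W_lab = W_light in expectation, the
        CI must straddle zero for almost all taxa."""
        from qsip_growth.io import assemble_experiment
        from qsip_growth.qsip import estimate_growth
        from qsip_growth.simulate import (SimulationConfig,
                                          build_ground_truth,
                                          simulate_experiment_tree,
                                          simulate_qsip_experiment)
        cfg = SimulationConfig(n_taxa=20, seed=21, treatments=("Contr",),
                               days=(1,), **wide_grid)
        sm = pd.DataFrame({"Contr": ["inert"] * 20},
                          index=[f"t{i}" for i in range(20)])
        truth = build_ground_truth(sm, cfg)
        tb, ss, tx, truth = simulate_qsip_experiment(cfg, truth)
        exp = assemble_experiment(tb, ss, simulate_experiment_tree(truth, 1),
                                  tx, window=(1.0, 2.0))
        est = estimate_growth(exp, n_boot=500, seed=5)
        straddle = (est["ci_low"] <= 0) & (est["ci_high"] >= 0)
        assert straddle.mean() >= 0.9

    def test_requires_two_replicates_per_arm(self, scenario):
        from qsip_growth.io import assemble_experiment
        from qsip_growth.qsip import bootstrap_growth
        from qsip_growth.model import FeatureTable
        keep = [s for s in scenario["samples"]
                if not (s.isotope == "16O" and s.replicate > 1 and s.day > 0)]
        keep_ids = {s.sample_id for s in keep}
        table = FeatureTable(scenario["feature_table"].df[
            [c for c in scenario["feature_table"].df.columns
             if c in keep_ids]])
        exp = assemble_experiment(table, keep, scenario["tree"],
                                  scenario["taxonomy"],
                                  window=scenario["window"])
        with pytest.raises(ValidationError, match="bootstrap needs"):
            bootstrap_growth(exp, "stable_rapid", "Contr", "0-1d", n_iter=50)

    def test_deterministic_given_seed(self, scenario_experiment):
        from qsip_growth.qsip import bootstrap_growth
        a = bootstrap_growth(scenario_experiment, "stable_rapid", "Contr",
                             "0-1d", n_iter=100, seed=42)
        b = bootstrap_growth(scenario_experiment, "stable_rapid", "Contr",
                             "0-1d", n_iter=100, seed=42)
        assert a == b


class TestIncorporators:
    def test_rule_on_ci_bounds(self):
        df = pd.DataFrame({
            "taxon": ["a", "b"], "treatment": ["Contr"] * 2,
            "interval": ["0-1d"] * 2,
            "ci_low": [0.1, -0.1], "ci_high": [0.4, 0.4]})
        inc = identify_incorporators(df)
        assert inc == {("a", "Contr")}

    def test_simulation_confusion(self, noisy_dataset):
        """>=90% of growing taxa and <=10% of inert taxa flagged under the
        default study geometry and noise (n=3 tubes per arm)."""
        truth, est = noisy_dataset["truth"], noisy_dataset["estimates"]
        inert = set(truth.strategies.loc[
            truth.strategies["strategy"] == "inert", "taxon"])
        growing = set(truth.taxa.index) - inert
        inc = {t for t, _ in identify_incorporators(est)}
        assert len(inc & growing) / len(growing) >= 0.9
        assert len(inc & inert) / len(inert) <= 0.1


class TestCommunityAndDensity:
    def test_phylum_shares(self, scenario):
        tax = scenario["taxonomy"]
        df = pd.DataFrame({
            "taxon": list(tax.df.index[:2]), "treatment": ["Contr"] * 2,
            "interval": ["0-1d"] * 2, "production": [30.0, 70.0]})
        cs = community_summaries(df, tax)
        assert cs.total_production == pytest.approx(100.0)
        assert cs.phylum_share.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_taxon_share_one(self, scenario):
        tax = scenario["taxonomy"]
        df = pd.DataFrame({"taxon": [tax.df.index[0]], "treatment": ["eT"],
                           "interval": ["0-3d"], "production": [5.0]})
        cs = community_summaries(df, tax)
        assert cs.phylum_share.iloc[0] == pytest.approx(1.0)

    def test_five_taxon_sums_match_manual(self, scenario):
        tax = scenario["taxonomy"]
        taxa = list(tax.df.index[:5])
        prods = [1.0, 2.0, 4.0, 8.0, 16.0]
        df = pd.DataFrame({"taxon": taxa, "treatment": ["Contr"] * 5,
                           "interval": ["0-6d"] * 5, "production": prods})
        cs = community_summaries(df, tax)
        manual = {}
        for t, p in zip(taxa, prods):
            manual[tax.phylum(t)] = manual.get(tax.phylum(t), 0) + p
        for phylum, total in manual.items():
            assert cs.phylum_production[phylum] == pytest.approx(total)

    def test_empty_errors(self, scenario):
        with pytest.raises(ValidationError):
            community_summaries(pd.DataFrame(columns=["treatment"]),
                                scenario["taxonomy"])

    def test_exact_linear_r2_one(self):
        taxa = [f"t{i}" for i in range(6)]
        n_tot = np.full(6, 1e6)
        init = pd.Series(np.linspace(1e4, 1e5, 6), index=taxa)
        percap = 0.5 - 2e-6 * init.to_numpy()  # exactly linear
        df = pd.DataFrame({"taxon": taxa, "N_TOTAL": n_tot,
                           "production": percap * n_tot})
        slope, r2, p = density_dependence(df, init)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert slope == pytest.approx(-2e-6, rel=1e-9)

    def test_four_point_closed_form_ols(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([0.1, 0.25, 0.2, 0.4])
        taxa = list("abcd")
        df = pd.DataFrame({"taxon": taxa, "N_TOTAL": np.ones(4),
                           "production": y})
        slope, r2, _ = density_dependence(df, pd.Series(x, index=taxa))
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        beta = sxy / sxx
        assert slope == pytest.approx(beta, rel=1e-12)
        assert r2 == pytest.approx(sxy**2 / (sxx * ((y - y.mean())**2).sum()),
                                   rel=1e-12)

    def test_null_p_roughly_uniform(self):
        """Permutation-style null: independent rates and abundances give
        p < 0.05 in about 5% of replicates."""
        rng = np.random.default_rng(3)
        taxa = [f"t{i}" for i in range(40)]
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            init = pd.Series(rng.uniform(1e4, 1e6, 40), index=taxa)
            df = pd.DataFrame({"taxon": taxa, "N_TOTAL": np.ones(40),
                               "production": rng.normal(0.2, 0.05, 40)})
            _, _, p = density_dependence(df, init)
            hits += p < 0.05
        assert hits / n_rep == pytest.approx(0.05, abs=0.025)

    def test_zero_variance_predictor_errors(self):
        taxa = list("abc")
        df = pd.DataFrame({"taxon": taxa, "N_TOTAL": np.ones(3),
                           "production": [0.1, 0.2, 0.3]})
        with pytest.raises(ValidationError, match="variance"):
            density_dependence(df, pd.Series([5.0, 5.0, 5.0], index=taxa))


class TestRecovery:
    def test_noise_free_exact_recovery(self, wide_grid):
        """Zero noise on the wide validation gradient: EAF and g match the
        generating values to 1e-6 (single growing taxon at g=0.5/d)."""
        from qsip_growth.io import assemble_experiment
        from qsip_growth.qsip import estimate_growth
        from qsip_growth.simulate import (SimulationConfig,
                                          build_ground_truth,
                                          simulate_experiment_tree,
                                          simulate_qsip_experiment)
        cfg = SimulationConfig(n_taxa=4, qpcr_noise_cv=0.0,
                               sequencing_depth=0, seed=3,
                               treatments=("Contr",), **wide_grid)
        sm = pd.DataFrame({"Contr": ["rapid", "intermediate", "slow",
                                     "inert"]},
                          index=["t1", "t2", "t3", "t4"])
        truth = build_ground_truth(sm, cfg)
        truth.rates.loc[(truth.rates["taxon"] == "t1")
                        & (truth.rates["interval"] == "0-1d"), "g"] = 0.5
        truth.rates.loc[(truth.rates["taxon"] == "t1")
                        & (truth.rates["interval"] == "0-1d"), "eaf"] = \
            (1 - np.exp(-0.5)) * (1 - 0.002000429)
        tb, ss, tx, truth = simulate_qsip_experiment(cfg, truth)
        exp = assemble_experiment(tb, ss, simulate_experiment_tree(truth, 3),
                                  tx, window=(1.0, 2.0))
        est = estimate_growth(exp, n_boot=10, seed=0)
        m = est.merge(truth.rates, on=["taxon", "treatment", "interval"])
        assert (m["EAF"] - m["eaf"]).abs().max() < 1e-6
        assert (m["g_x"] - m["g_y"]).abs().max() < 1e-6

    def test_default_noise_median_eaf_error(self, noisy_dataset):
        """Study geometry and default noise, 100 taxa: median absolute EAF
        error stays below 0.05."""
        truth, est = noisy_dataset["truth"], noisy_dataset["estimates"]
        m = est.merge(truth.rates, on=["taxon", "treatment", "interval"])
        assert (m["EAF"] - m["eaf"]).abs().median() < 0.05
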