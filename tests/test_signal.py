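"""Phylogenetic-signal statistics against brute-force and R oracles."""

import subprocess
import textwrap

import numpy as np
import pytest

from qsip_growth.errors import ValidationError
from qsip_growth.signal import (blomberg_k, mntd, nti, pagel_lambda, phylo_d,
                                sum_sister_differences)
from qsip_growth.simulate import simulate_binary_trait
from qsip_growth.trees import TreeArrays


class TestSisterDifferences:
    def test_root_split_trait(self, balanced4):
        # node means: AB=1, CD=0, root=0.5 -> |1-1|+|0-0|+|1-0| = 1
        assert sum_sister_differences(
            balanced4, {"A": 1, "B": 1, "C": 0, "D": 0}) == pytest.approx(1.0)

    def test_alternating_trait_larger(self, balanced4):
        sd_alt = sum_sister_differences(
            balanced4, {"A": 1, "B": 0, "C": 1, "D": 0})
        assert sd_alt == pytest.approx(2.0)
        assert sd_alt > 1.0

    def test_constant_trait_zero(self, balanced4):
        assert sum_sister_differences(
            balanced4, {"A": 1, "B": 1, "C": 1, "D": 1}) == 0.0

    def test_too_few_tips(self):
        import dendropy
        from qsip_growth.model import Phylogeny
        t = Phylogeny(dendropy.Tree.get(data="(A:1,B:1);", schema="newick"))
        with pytest.raises(ValidationError):
            sum_sister_differences(t, {"A": 1, "B": 0})


class TestPhyloD:
    def test_shuffled_traits_mean_one(self, yule100):
        """Random tip shuffles are the D = 1 calibration point."""
        rng = np.random.default_rng(1)
        vals = [phylo_d(yule100,
                        simulate_binary_trait(yule100, "random", 0.3, rng=rng),
                        n_null=199, seed=100 + i).estimate
                for i in range(60)]
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)

    def test_brownian_traits_mean_zero(self, yule100):
        """Thresholded Brownian traits are the D = 0 calibration point."""
        rng = np.random.default_rng(2)
        vals = [phylo_d(yule100,
                        simulate_binary_trait(yule100, "brownian_threshold",
                                              0.3, rng=rng),
                        n_null=199, seed=200 + i).estimate
                for i in range(60)]
        assert np.mean(vals) == pytest.approx(0.0, abs=0.1)

    def test_monotone_in_signal_strength(self, yule100):
        """D decreases as the generating covariance moves from identity
        toward full Brownian (the rapid-to-slow clumping gradient)."""
        means = []
        for sig in (0.0, 0.5, 1.0):
            rng = np.random.default_rng(33)
            vals = [phylo_d(yule100,
                            simulate_binary_trait(yule100, "lambda_scaled",
                                                  0.3, signal=sig, rng=rng),
                            n_null=149, seed=300 + i).estimate
                    for i in range(40)]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_relabel_symmetry(self, yule100):
        """Swapping 0s and 1s leaves D unchanged up to Monte-Carlo error."""
        trait = simulate_binary_trait(yule100, "lambda_scaled", 0.3,
                                      signal=0.7, seed=9)
        flipped = {k: 1 - v for k, v in trait.items()}
        d1 = phylo_d(yule100, trait, n_null=499, seed=1).estimate
        d2 = phylo_d(yule100, flipped, n_null=499, seed=2).estimate
        assert d1 == pytest.approx(d2, abs=0.2)

    def test_degenerate_prevalence_rejected(self, yule100):
        with pytest.raises(ValidationError):
            phylo_d(yule100, {n: 1 for n in yule100.tip_names}, n_null=199)

    def test_deterministic_given_seed(self, yule100):
        trait = simulate_binary_trait(yule100, "random", 0.3, seed=4)
        a = phylo_d(yule100, trait, n_null=199, seed=11)
        b = phylo_d(yule100, trait, n_null=199, seed=11)
        assert a.estimate == b.estimate and a.p_value == b.p_value


class TestBlombergK:
    def test_fourtip_closed_form(self, balanced4):
        """Direct matrix-formula evaluation on ((A,B),(C,D)): the
        alternating trait gives K = 0.6, the root-split trait K = 1.8."""
        k_alt = blomberg_k(balanced4, {"A": 1, "B": 0, "C": 1, "D": 0},
                           n_null=100, seed=0).estimate
        k_split = blomberg_k(balanced4, {"A": 1, "B": 1, "C": 0, "D": 0},
                             n_null=100, seed=0).estimate
        assert k_alt == pytest.approx(0.6, abs=1e-12)
        assert k_split == pytest.approx(1.8, abs=1e-12)

    def test_brownian_calibration(self, yule100):
        """Mean K over Brownian traits is ~1 on any tree."""
        rng = np.random.default_rng(12)
        traits = yule100.simulate_bm(60, rng)
        ks = [blomberg_k(yule100, traits[:, i], n_null=100,
                         seed=i).estimate for i in range(60)]
        assert np.mean(ks) == pytest.approx(1.0, abs=0.15)

    def test_shuffled_traits_low_k_high_p(self, yule100):
        rng = np.random.default_rng(13)
        bm = yule100.simulate_bm(1, rng)[:, 0]
        results = []
        for i in range(30):
            perm = rng.permutation(bm)
            results.append(blomberg_k(yule100, perm, n_null=199, seed=i))
        assert np.mean([r.p_value > 0.05 for r in results]) >= 0.9
        assert np.mean([r.estimate for r in results]) < 1.0

    def test_k_lambda_positively_correlated(self, yule100):
        """K and lambda weaken together on the same traits (the joint
        rapid-to-slow pattern)."""
        from scipy.stats import spearmanr
        rng = np.random.default_rng(14)
        ks, lams = [], []
        for sig in np.linspace(0, 1, 40):
            trait = simulate_binary_trait(yule100, "lambda_scaled", 0.3,
                                          signal=float(sig), rng=rng)
            x = np.array([trait[n] for n in yule100.tip_names], dtype=float)
            ks.append(blomberg_k(yule100, x, n_null=100, seed=1).estimate)
            lams.append(pagel_lambda(yule100, x, n_null=1, seed=1).estimate)
        rho = spearmanr(ks, lams).statistic
        assert rho > 0.5


class TestPagelLambda:
    def test_lambda_zero_is_iid_gaussian_loglik(self, yule100):
        """At lambda = 0 the profile log-likelihood equals the
        independent-observations Gaussian likelihood."""
        from qsip_growth.signal import _lambda_loglik
        rng = np.random.default_rng(3)
        y = rng.standard_normal(yule100.n_tips)
        C = yule100.vcv()
        diag = np.diag(C).copy()
        ll = _lambda_loglik(0.0, y, C.copy(), diag)
        # independent Gaussian with per-tip variance sigma2 * diag(C)
        z = y / np.sqrt(diag)
        mu = (z / np.sqrt(diag)).sum() / (1 / diag).sum()
        r = (y - mu) / np.sqrt(diag)
        s2 = (r @ r) / len(y)
        ll_iid = (-0.5 * (len(y) * np.log(2 * np.pi * s2)
                          + np.log(diag).sum() + len(y)))
        assert ll == pytest.approx(ll_iid, abs=1e-8)

    def test_brownian_traits_hit_upper_boundary(self, yule100):
        rng = np.random.default_rng(4)
        traits = yule100.simulate_bm(20, rng)
        lams = [pagel_lambda(yule100, traits[:, i], n_null=1,
                             seed=i).estimate for i in range(20)]
        assert np.median(lams) > 0.9

    def test_shuffled_traits_near_zero(self, yule100):
        rng = np.random.default_rng(5)
        bm = yule100.simulate_bm(1, rng)[:, 0]
        lams = [pagel_lambda(yule100, rng.permutation(bm), n_null=1,
                             seed=i).estimate for i in range(20)]
        assert np.median(lams) < 0.1


class TestNti:
    def test_hand_mntd_on_five_tips(self, tree5):
        """((A:1,B:1):2,((C:1,D:1):1,E:2):1): d(A,C)=6 so MNTD({A,C})=6;
        {C,D,E} has nearest distances 2,2,4 giving MNTD 8/3."""
        ta = TreeArrays.from_phylogeny(tree5)
        dist = ta.cophenetic()
        idx = np.array([ta.tip_index["A"], ta.tip_index["C"]])
        assert mntd(dist, idx) == pytest.approx(6.0)
        idx3 = np.array([ta.tip_index[n] for n in "CDE"])
        assert mntd(dist, idx3) == pytest.approx(8.0 / 3.0)

    def test_all_tips_gives_zero(self, yule100):
        r = nti(yule100, set(yule100.tip_names), n_null=199, seed=0)
        assert r.estimate == 0.0

    def test_clade_is_clustered(self, yule100):
        """A small clade's members are nearer each other than random sets:
        NTI > 0 with small p."""
        # take one internal node's descendant tips as the member set
        depth = yule100.node_depths()
        for nd in yule100.postorder_internal:
            tips = [t for t in range(yule100.n_tips)
                    if _descends(yule100, t, nd)]
            if 5 <= len(tips) <= 15:
                members = {yule100.tip_names[t] for t in tips}
                break
        r = nti(yule100, members, n_null=499, seed=3)
        assert r.estimate > 0 and r.p_value < 0.05

    def test_random_subsets_standardized(self, yule100):
        """NTI of random subsets has mean ~0 and sd ~1."""
        rng = np.random.default_rng(8)
        vals = []
        for i in range(100):
            members = set(rng.choice(yule100.tip_names, 20, replace=False))
            vals.append(nti(yule100, members, n_null=199,
                            seed=1000 + i).estimate)
        assert np.mean(vals) == pytest.approx(0.0, abs=0.25)
        assert np.std(vals) == pytest.approx(1.0, abs=0.25)

    def test_small_member_set_rejected(self, yule100):
        with pytest.raises(ValidationError):
            nti(yule100, {yule100.tip_names[0]}, n_null=199)


def _descends(ta, tip, ancestor):
    node = tip
    while node != -1:
        if node == ancestor:
            return True
        node = ta.parent[node]
    return False


class TestAgainstR:
    def test_k_lambda_mntd_match_r_packages(self, tmp_path):
        """phytools::phylosig (K, lambda) and picante::mntd agree with this
        implementation on a 10-tip tree with a mixed-signal trait."""
        from qsip_growth.trees import simulate_yule
        phylo = simulate_yule(10, seed=42)
        ta = TreeArrays.from_phylogeny(phylo)
        rng = np.random.default_rng(0)
        y = ta.simulate_bm(1, rng)[:, 0] + 0.7 * rng.standard_normal(10)
        k_py = blomberg_k(ta, y, n_null=10, seed=0).estimate
        lam_py = pagel_lambda(ta, y, n_null=1, seed=0).estimate
        members = ta.tip_names[:4]
        mntd_py = nti(ta, set(members), n_null=10, seed=0).extras["mntd_obs"]

        (tmp_path / "tree.nwk").write_text(phylo.as_newick() + "\n")
        trait_lines = "\n".join(f"{n},{float(v)!r}"
                                for n, v in zip(ta.tip_names, y))
        (tmp_path / "trait.csv").write_text("tip,value\n" + trait_lines + "\n")
        rscript = textwrap.dedent(f"""
            suppressMessages({{library(phytools); library(picante)}})
            tree <- read.tree("{tmp_path}/tree.nwk")
            tr <- read.csv("{tmp_path}/trait.csv")
            y <- setNames(tr$value, tr$tip)
            k <- phylosig(tree, y, method = "K")
            lam <- phylosig(tree, y, method = "lambda")
            samp <- matrix(as.numeric(tree$tip.label %in%
                           c({', '.join(repr(m) for m in members)})),
                           nrow = 1, dimnames = list("s",tree$tip.label))
            m <- mntd(samp, cophenetic(tree))
            cat(sprintf("%.15g", c(as.numeric(k), lam$lambda, m)),
                sep = "\\n")
        """)
        out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                             text=True, check=True)
        k_r, lam_r, mntd_r = map(float, out.stdout.strip().split("\n"))
        assert k_py == pytest.approx(k_r, rel=1e-6)
        assert lam_py == pytest.approx(lam_r, abs=0.05)
        assert mntd_py == pytest.approx(mntd_r, rel=1e-9)
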