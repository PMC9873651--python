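import dendropy
import numpy as np
import pytest

from qsip_growth.io import assemble_experiment
from qsip_growth.model import Phylogeny
from qsip_growth.qsip import estimate_growth
from qsip_growth.simulate import (SimulationConfig, make_strategy_scenario,
                                  random_ground_truth,
                                  simulate_experiment_tree,
                                  simulate_qsip_experiment)
from qsip_growth.trees import TreeArrays, simulate_yule


def tree_from_newick(newick: str) -> Phylogeny:
    return Phylogeny(dendropy.Tree.get(data=newick, schema="newick"))


@pytest.fixture(scope="session")
def balanced4():
    """((A,B),(C,D)) with unit branches: the hand-oracle tree."""
    return tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def tree5():
    """Five tips with known patristic distances (A-B 2, C-D 2, C-E 4...)."""
    return tree_from_newick("((A:1,B:1):2,((C:1,D:1):1,E:2):1);")


@pytest.fixture(scope="session")
def yule100():
    return TreeArrays.from_phylogeny(simulate_yule(100, seed=7))


@pytest.fixture(scope="session")
def scenario():
    return make_strategy_scenario()


@pytest.fixture(scope="session")
def scenario_experiment(scenario):
    return assemble_experiment(scenario["feature_table"], scenario["samples"],
                               scenario["tree"], scenario["taxonomy"],
                               window=scenario["window"])


@pytest.fixture(scope="session")
def scenario_estimates(scenario_experiment):
    return estimate_growth(scenario_experiment, n_boot=200, seed=0)


@pytest.fixture(scope="session")
def noisy_dataset():
    """100 taxa, default study geometry and noise, one treatment arm."""
    cfg = SimulationConfig(n_taxa=100, seed=11, treatments=("Contr",))
    truth = random_ground_truth(cfg, p_inert=0.3)
    table, samples, taxonomy, truth = simulate_qsip_experiment(cfg, truth)
    tree = simulate_experiment_tree(truth, cfg.seed)
    exp = assemble_experiment(table, samples, tree, taxonomy)
    est = estimate_growth(exp, n_boot=500, seed=0)
    return {"config": cfg, "truth": truth, "experiment": exp, "estimates": est}


@pytest.fixture(scope="session")
def wide_grid():
    """Validation geometry: the whole labelled profile stays on-grid."""
    return dict(density_grid=np.linspace(1.64, 1.80, 20), n_fractions=20,
                fraction_sigma=0.01)
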