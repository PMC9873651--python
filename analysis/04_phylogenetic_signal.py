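#!/usr/bin/env python
"""Phylogenetic conservation of the growth strategies.

Builds pooled binary strategy traits (an OTU carries a strategy label if it
exhibited that strategy in any treatment), then computes Fritz-Purvis D,
Blomberg's K, Pagel's lambda and NTI with permutation nulls — the
pooled-tree analysis — and per-treatment NTI for each strategy member set —
the treatment-resolved analysis. Writes signal_pooled.tsv and
signal_by_treatment.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from qsip_growth import io
from qsip_growth.signal import blomberg_k, nti, pagel_lambda, phylo_d
from qsip_growth.strategies import STRATEGIES, pooled_trait_labels
from qsip_growth.trees import TreeArrays


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--nulls", type=int, default=1000)
    ap.add_argument("--experiment", type=Path,
                    default=Path("results/experiment"))
    ap.add_argument("--assignments", type=Path,
                    default=Path("results/strategy_assignments.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    tree = io.read_tree(args.experiment / "tree.nwk")
    ta = TreeArrays.from_phylogeny(tree)
    assign = pd.read_csv(args.assignments, sep="\t", comment="#")
    labels = pooled_trait_labels(assign)

    pooled = []
    print(f"pooled signal ({args.nulls} nulls):")
    for strat in STRATEGIES:
        trait = {t: int(labels.loc[t, strat]) if t in labels.index else 0
                 for t in ta.tip_names}
        members = {t for t, v in trait.items() if v}
        if not 0 < len(members) < ta.n_tips:
            continue
        res = {
            "D": phylo_d(ta, trait, n_null=args.nulls, seed=args.seed),
            "K": blomberg_k(ta, trait, n_null=args.nulls, seed=args.seed),
            "lambda": pagel_lambda(ta, trait, n_null=args.nulls,
                                   seed=args.seed),
            "NTI": nti(ta, members, n_null=args.nulls, seed=args.seed),
        }
        line = ", ".join(f"{k}={r.estimate:.2f} (p={r.p_value:.3f})"
                         for k, r in res.items())
        print(f"  {strat} (n={len(members)}): {line}")
        for k, r in res.items():
            pooled.append({"strategy": strat, "num_taxa": len(members),
                           "index": k, "estimate": r.estimate,
                           "p_value": r.p_value, "n_null": r.n_null})
    io._write_tsv(pd.DataFrame(pooled).set_index("strategy"),
                  args.out / "signal_pooled.tsv")

    by_trt = []
    for (trt, strat), sub in assign.groupby(["treatment", "strategy"]):
        members = set(sub["taxon"]) & set(ta.tip_names)
        if not 2 <= len(members) < ta.n_tips:
            continue
        r = nti(ta, members, n_null=args.nulls, seed=args.seed)
        by_trt.append({"treatment": trt, "strategy": strat,
                       "num_taxa": len(members), "NTI": r.estimate,
                       "p_value": r.p_value})
    io._write_tsv(pd.DataFrame(by_trt).set_index("treatment"),
                  args.out / "signal_by_treatment.tsv")
    print(f"per-treatment NTI written for {len(by_trt)} strategy cells")


if __name__ == "__main__":
    main()
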