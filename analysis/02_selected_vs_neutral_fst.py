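#!/usr/bin/env python
"""Does polygenic stabilizing selection inflate F_ST at the trait loci?

Replicates the simulation many times, estimates per-locus Weir-Cockerham
theta from a genotype sample at the final generation, and compares the
mean theta of selected vs neutral loci.  A matched control with the
selection effect switched off (effect_x=0) checks that the ordering is a
fair coin under pure drift.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from polyfst.simulate import SimParams, run_simulation, sim_fst_summary

RESULTS = Path(__file__).resolve().parent.parent / "results"


def replicate(n_rep, seed0, **kw):
    rows = []
    for rep in range(n_rep):
        params = SimParams(seed=seed0 + rep, **kw)
        result = run_simulation(params)
        _, mean_sel, mean_neu = sim_fst_summary(result, sample_size=200)
        rows.append({"replicate": rep, "mean_theta_selected": mean_sel,
                     "mean_theta_neutral": mean_neu})
    return pd.DataFrame(rows)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-rep", type=int, default=50)
    args = ap.parse_args()

    sel = replicate(args.n_rep, args.seed * 1000, n_individuals=1000, n_generations=200)
    neu = replicate(args.n_rep, args.seed * 1000 + 500, n_individuals=1000,
                    n_generations=200, effect_x=0.0)

    RESULTS.mkdir(exist_ok=True)
    sel.assign(condition="selection").pipe(
        lambda d: pd.concat([d, neu.assign(condition="drift_only")])
    ).to_csv(RESULTS / "sim_fst_ordering.tsv", sep="\t", index=False)

    f_sel = (sel.mean_theta_selected > sel.mean_theta_neutral).mean()
    f_neu = (neu.mean_theta_selected > neu.mean_theta_neutral).mean()
    print(f"under selection: selected-set mean theta exceeds neutral in {f_sel:.0%} of "
          f"{args.n_rep} replicates (mean {sel.mean_theta_selected.mean():.3f} "
          f"vs {sel.mean_theta_neutral.mean():.3f})")
    print(f"drift-only control: ordering holds in {f_neu:.0%} (label exchangeability => ~50%)")


if __name__ == "__main__":
    main()
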