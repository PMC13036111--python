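#!/usr/bin/env python
"""Simulate the study dataset from the planted ground-truth network.

Builds the default 18-item two-community Ising network (5 MW items,
13 PSVU items, three planted bridge edges with MW5-PSVU8 dominant),
draws 1989 respondents, expands them to 1-5 Likert scores, and writes:

    results/truth_network.json   the planted network (the answer key)
    scratch/likert_data.csv      person x item Likert table (large; regenerable)
    results/simulation_summary.json

Later drivers re-load the Likert table and recover the network from it.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from symptomnet import (
    GroundTruthSpec,
    expand_to_likert,
    generate_dataset,
    make_ground_truth,
    save_network,
    spawn_seeds,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7,
                        help="sampling seed (respondents and Likert expansion)")
    parser.add_argument("--truth-seed", type=int, default=0,
                        help="seed of the planted network itself")
    parser.add_argument("--n", type=int, default=1989)
    args = parser.parse_args()

    data_seed, likert_seed = spawn_seeds(args.seed, 2)
    spec = GroundTruthSpec(seed=args.truth_seed)
    truth = make_ground_truth(spec)
    binary = generate_dataset(truth, n=args.n, seed=data_seed)
    likert = expand_to_likert(binary, seed=likert_seed)

    results = ROOT / "results"
    scratch = ROOT / "scratch"
    results.mkdir(exist_ok=True)
    scratch.mkdir(exist_ok=True)

    save_network(truth, results / "truth_network.json")
    pd.DataFrame(likert.values, columns=likert.item_labels).to_csv(
        scratch / "likert_data.csv", index=False
    )
    (results / "community_map.csv").write_text(
        "item,community\n"
        + "\n".join(f"{lab},{truth.community[lab]}" for lab in truth.item_labels)
        + "\n"
    )

    n_edges = int((truth.weights != 0).sum() // 2)
    summary = {
        "seed": args.seed,
        "n_persons": args.n,
        "n_items": truth.p,
        "n_true_edges": n_edges,
        "bridge_edges": spec.bridges,
    }
    with open(results / "simulation_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    print(f"Planted network: {truth.p} items, {n_edges} edges, "
          f"bridges {[f'{a}-{b} ({w})' for a, b, w in spec.bridges]}")
    print(f"Simulated {args.n} respondents -> scratch/likert_data.csv")


if __name__ == "__main__":
    main()
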