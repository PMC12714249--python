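"""Sweep the forest hyperparameters and look for accuracy plateaus.

ntree from 50 to 350 and mtry from 3 to 14, each point evaluated with a
reduced Monte-Carlo run; accuracy typically plateaus well before the
defaults (ntree 215, mtry 6), which is the point of checking.
"""

import argparse
import warnings
from pathlib import Path

from benthicmap import run_pipeline
from benthicmap.config import PipelineConfig
from benthicmap.rfmc import MCParams, extract_training_table, tune_hyperparameters


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-sim", type=int, default=15,
                        help="Monte-Carlo runs per grid point.")
    args = parser.parse_args()

    config = PipelineConfig(seed=args.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import dataclasses

        probe = dataclasses.replace(config, mc=MCParams(n_sim=1, base_seed=args.seed))
        result = run_pipeline(probe)
        table = result.table
        mc = MCParams(n_sim=args.n_sim, base_seed=args.seed)

        ntree_curve = tune_hyperparameters(
            table, {"ntree": [50, 100, 150, 215, 275, 350]}, mc=mc
        )
        mtry_curve = tune_hyperparameters(
            table, {"mtry": list(range(3, 15))}, mc=mc
        )

    out = Path("results")
    out.mkdir(exist_ok=True)
    ntree_curve.to_csv(out / "tuning_ntree.csv", index=False)
    mtry_curve.to_csv(out / "tuning_mtry.csv", index=False)

    print("ntree sweep (mean validation accuracy +- sd):")
    print(ntree_curve.round(3).to_string(index=False))
    print("mtry sweep:")
    print(mtry_curve.round(3).to_string(index=False))
    print(f"curves in {out}/tuning_ntree.csv and {out}/tuning_mtry.csv")


if __name__ == "__main__":
    main()
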