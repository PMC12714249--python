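"""Generate the synthetic island study area and write the raw inputs.

Produces the three inputs a field campaign would supply — fine-resolution
bathymetry with island shoals, a summer stack of thermal scenes with
cloud/shadow QA flags, and a drop-camera ground-truth table in four benthic
cover classes — and reports what was generated. Rasters land under
scratch/ (they are bulky); the ground-truth table is copied to results/.
"""

import argparse
import shutil
import warnings
from pathlib import Path

import numpy as np

from benthicmap import PipelineConfig
from benthicmap.pipeline import write_synthetic_inputs
from benthicmap.thermal import cloud_fraction, mask_clouds


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("scratch/fixture"))
    args = parser.parse_args()

    config = PipelineConfig(seed=args.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = write_synthetic_inputs(config, args.out)

    from benthicmap import synthgrid

    depth = synthgrid.generate_bathymetry(config.synth)
    coll = synthgrid.generate_thermal_collection(config.synth, depth)
    fracs = [cloud_fraction(mask_clouds(s), coll.aoi_mask) for s in coll.scenes]

    print(f"study area: {depth.shape[0]}x{depth.shape[1]} cells at "
          f"{depth.cell_size:g} m; depth {depth.values.min():.1f} to "
          f"{depth.values.max():.1f} m (negative = emergent land)")
    print(f"land/intertidal (<1 m): {(depth.values < 1).mean():.1%} of cells; "
          f"deep water (>50 m): {(depth.values > 50).mean():.1%}")
    print(f"thermal scenes: {len(coll.scenes)} at "
          f"{coll.scenes[0].temperature.cell_size:g} m; AOI cloud fractions "
          f"{min(fracs):.2f}-{max(fracs):.2f} "
          f"({sum(f > 0.25 for f in fracs)} exceed the 25% rejection level)")

    import pandas as pd

    truth = pd.read_csv(out / "truth.csv")
    results = Path("results")
    results.mkdir(exist_ok=True)
    shutil.copy(out / "truth.csv", results / "ground_truth.csv")
    print(f"ground truth: {len(truth)} observations from "
          f"{truth['drop_id'].nunique()} drops; class counts "
          f"{truth['class'].value_counts().to_dict()}")
    print(f"inputs written to {out}; ground truth copied to {results}/ground_truth.csv")


if __name__ == "__main__":
    main()
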