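#!/usr/bin/env python
"""Pixel-wise texture prediction maps from a synthetic skin image.

Trains on the RC arm with all six models for the dorsal region and applies
each retained model to every pixel of a generated 64x64 skin cube, writing
blue-to-orange PNG maps (plus scale sidecars) under
``results/maps_run/maps/``.
"""

import json
from pathlib import Path

import pandas as pd

from hsitex import RunConfig, run_pipeline

SEED = 7


def main() -> None:
    cfg = RunConfig(out_dir="results/maps_run", seed=SEED, n_samples=300,
                    n_bands=600, regions=("dorsal",), wavelengths="rc",
                    make_maps=True, map_rows=64, map_cols=64)
    out = run_pipeline(cfg)
    best = pd.read_csv(out / "best.csv")
    print("prediction maps (dorsal region, retained models):")
    for png in sorted((out / "maps").glob("*.png")):
        side = json.loads(Path(str(png) + ".json").read_text())
        row = best[best.indicator == side["indicator"]].iloc[0]
        print(f"  {side['indicator']:<12} ({row.model:<6}) value range "
              f"{side['vmin']:8.2f} .. {side['vmax']:8.2f}  -> {png}")


if __name__ == "__main__":
    main()
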