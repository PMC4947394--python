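#!/usr/bin/env python
"""Generate the synthetic VS/UVS species panel used by the later stages.

Writes results/species.csv: 11 UVS and 7 VS species with pigment λmax
values, oil-droplet cutoffs, and ocular-media parameters drawn from the
ranges spanned by published avian microspectrophotometry.
"""

import argparse
from pathlib import Path

import numpy as np

from tetrachroma.synthetic import GeneratorConfig, make_species_params

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

table = make_species_params(
    GeneratorConfig(seed=args.seed, n_species=18, class_mix=11 / 18)
)
args.out_dir.mkdir(parents=True, exist_ok=True)
table.to_csv(args.out_dir / "species.csv", index=False)

r = np.corrcoef(table["sws1_lmax"], table["c_cut"])[0, 1]
print(f"wrote {len(table)} species ({(table['class'] == 'UVS').sum()} UVS, "
      f"{(table['class'] == 'VS').sum()} VS) to {args.out_dir / 'species.csv'}")
print(f"SWS1 λmax vs C-droplet λcut correlation across the panel: r = {r:.2f} "
      "(the coordinated-tuning pattern seen across real bird species)")
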