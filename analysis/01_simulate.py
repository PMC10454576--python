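#!/usr/bin/env python
"""Generate the three synthetic datasets every downstream step consumes:
a 46-genotype control/salt trait panel with planted tolerance classes, a
two-genotype x four-timepoint DE contrast set with planted screen genes,
and an FPKM matrix with planted co-expression modules.

Writes results/sim/ (pipeline inputs) plus truth.json (planted ground
truth; read only by the evaluation steps, never by the pipeline).
"""

import argparse
import json
from pathlib import Path

from saltpipe.cli import _simulate
from saltpipe.io import RunConfig

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results/sim"))
args = parser.parse_args()

data = _simulate(args.seed, args.outdir, RunConfig(seed=args.seed))
truth = json.loads((args.outdir / "truth.json").read_text())
print(f"wrote {args.outdir}: trait panel "
      f"({data['panel']['genotype'].nunique()} genotypes x "
      f"{data['panel']['trait'].nunique()} traits), "
      f"{data['de']['contrast'].nunique()} DE contrasts, "
      f"expression matrix {data['expr'].fpkm.shape[0]} genes x "
      f"{data['expr'].fpkm.shape[1]} samples")
print("planted classes:", {c: list(truth['panel_classes'].values()).count(c)
                           for c in set(truth['panel_classes'].values())})
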