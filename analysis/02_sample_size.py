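#!/usr/bin/env python
"""Minimum survey size at the study design parameters.

Evaluates n0 = Z²·P(1-P)·Deff/e² and the household adjustment chain, and
writes results/sample_size.csv.  At the defaults (alpha 0.05, prevalence
0.15, design effect 1.5, margin 0.05, target share 0.15, household size 4.5,
valid rate 0.90) the minimum is 484 households.
"""

import argparse
from pathlib import Path

import pandas as pd

from settlescan.sample_size import SampleSizeParams, base_individuals, minimum_households

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

params = SampleSizeParams()
res = minimum_households(params)
print(f"n0 = {res['n0']:.1f} individuals -> minimum {res['households']} households")

rows = [{"alpha": params.alpha, "prevalence": params.prevalence, "deff": params.deff,
         "moe": params.moe, "p_target": params.p_target, "hh_size": params.hh_size,
         "valid_rate": params.valid_rate, "n0": round(res["n0"], 2),
         "households": res["households"]}]
# sensitivity: how the minimum moves with the margin of error
for moe in (0.03, 0.04, 0.06):
    p = SampleSizeParams(moe=moe)
    r = minimum_households(p)
    rows.append({**rows[0], "moe": moe, "n0": round(base_individuals(p), 2),
                 "households": r["households"]})
    print(f"  margin {moe:.2f}: {r['households']} households")

args.out.mkdir(parents=True, exist_ok=True)
pd.DataFrame(rows).to_csv(args.out / "sample_size.csv", index=False)
print(f"wrote {args.out}/sample_size.csv")
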