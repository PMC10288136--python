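#!/usr/bin/env python
"""Evaluate the comfort chain at every design point.

For each sampled operating condition the lumped cab model produces the
per-segment microclimate, the thermoregulation solver is run to steady
state, and the sensation model turns the skin temperatures into 14 local
votes, the overall vote and the 7-site mean skin temperature.  Appends
the responses to the design and writes evaluations.csv.
"""

from pathlib import Path

import pandas as pd

from cabtherm import ChainEvaluator, StudyConfig
from cabtherm.pipeline import load_design, stage_evaluate

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"

design = load_design(OUT)
chain = ChainEvaluator(StudyConfig())
responses = stage_evaluate(design, chain)
table = pd.concat([design.frame, responses], axis=1)
table.to_csv(OUT / "evaluations.csv", index=False)

print(f"evaluated {design.n} conditions -> {OUT / 'evaluations.csv'}")
print("OTSV range over the design: "
      f"[{responses['otsv'].min():.2f}, {responses['otsv'].max():.2f}]")
print("MST range: "
      f"[{responses['mst'].min():.2f}, {responses['mst'].max():.2f}] degC")
cold = responses[["head", "l_hand", "r_hand"]].mean(axis=1)
warm = responses[["l_lower_leg", "r_lower_leg"]].mean(axis=1)
frac = float((cold < warm).mean())
print(f"head/hands vote below the calves at {100*frac:.0f}% of the conditions")
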