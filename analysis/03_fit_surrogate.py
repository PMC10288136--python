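#!/usr/bin/env python
"""Fit the RBF surrogates and score them on a 10% holdout.

Each response (14 local votes, overall vote, mean skin temperature)
gets a thin-plate-spline interpolant over the normalised design box;
6 of the 60 points are held out and the fit on the remaining 54 is
scored by holdout R-squared and RMS error.  The study's accuracy gate
is R2 >= 0.9 and RMS < 0.2 sensation units for the overall vote.
"""

from pathlib import Path

import pandas as pd

from cabtherm import StudyConfig
from cabtherm.pipeline import RESPONSE_COLUMNS, load_design, stage_surrogate

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"

cfg = StudyConfig()
design = load_design(OUT)
responses = pd.read_csv(OUT / "evaluations.csv")[RESPONSE_COLUMNS]
report, _ = stage_surrogate(cfg, design, responses)
report.scores.to_csv(OUT / "validation.csv", index=False)

print(f"holdout rows: {report.holdout_rows.tolist()}")
print(report.scores.to_string(index=False))
r2 = report.score("otsv", "r2")
rms = report.score("otsv", "rms")
gate = "PASS" if r2 >= 0.9 and rms < 0.2 else "FAIL"
print(f"OTSV surrogate: R2={r2:.4f} RMS={rms:.4f} -> accuracy gate {gate}")
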