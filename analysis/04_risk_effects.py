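#!/usr/bin/env python
"""Morph-specific road-mortality risk effects with causal adjustment.

Simulates matched DOR/reference location sets (141 per group, per morph)
from the DAG-structured covariate model and estimates the direct effect of
each road/landscape exposure with a backdoor-adjusted Firth logistic
regression.  Gray truth plants a log-traffic effect of 0.32 and a crossings
effect; melanic truth plants a habitat-split effect of 1.89.  Writes
results/risk/risk_effects.json.
"""

import json
import sys
from pathlib import Path

import roadcline as rc
from roadcline.dag import EXPOSURES

OUT = Path("results/risk")
SEED = 777


def main() -> None:
    dag = rc.default_risk_dag()
    out = {}
    for morph, truth, seed in (
        ("gray", rc.RiskTruth.default_gray(), SEED),
        ("melanic", rc.RiskTruth.default_melanic(), SEED + 1),
    ):
        ds = rc.simulate_risk_dataset(truth, 141, seed, morph=morph)
        effects = [rc.estimate_risk_effect(ds, e, dag) for e in EXPOSURES]
        out[morph] = [e.to_dict() for e in effects]
        print(f"{morph} morph (n = {len(ds.frame)}, matched design):")
        for e in effects:
            star = " *" if e.p_value < 0.05 else ""
            print(f"  {e.exposure:13s} beta {e.estimate:+.2f} +/- {e.se:.2f} "
                  f"(p = {e.p_value:.3f}){star}  adjusted for "
                  f"{', '.join(e.adjustment_set) or 'nothing'}")
    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "risk_effects.json").write_text(json.dumps(out, indent=2))
    print(f"wrote {OUT / 'risk_effects.json'}")


if __name__ == "__main__":
    sys.exit(main())
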