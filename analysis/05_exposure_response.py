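#!/usr/bin/env python
"""Exposure-response and exposure-toxicity logistic regressions.

Regresses treatment success and hepatotoxicity on log C_min and
log AUC (likelihood-ratio p-values).  The synthetic cohort carries a
positive efficacy slope and a flat toxicity model; at ~40 subjects the
efficacy trend is only sometimes detectable (as in cohorts of this
size generally), while toxicity should stay null.  Writes
results/pkpd.json and the fitted probability curve for plotting.
"""

import json
import sys
from pathlib import Path

from isapk import config

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 20) -> None:
    cfg = config.default_config(seed=seed, out_dir=str(OUT))
    cfg["stages"] = ["fit", "bayes-exposure", "pkpd"]
    config.run_pipeline(cfg)
    results = json.loads((OUT / "pkpd.json").read_text())
    for r in results:
        print(f"{r['outcome']:15s} ~ log {r['exposure']:4s}: "
              f"slope {r['slope']:+.2f}  p={r['p_value']:.3f}  n={r['n']}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 20)
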