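#!/usr/bin/env python
"""Evaluate the fitted model: log-scale MPE/RMSE and a pcVPC.

The prediction-corrected visual predictive check bins observations by
time after dose and overlays observed 5/50/95th percentiles on the
simulation-derived confidence bands.  Writes results/validation.json,
results/pcvpc.csv and results/pcvpc.png.
"""

import json
import sys
from pathlib import Path

from isapk import config

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 20) -> None:
    cfg = config.default_config(seed=seed, out_dir=str(OUT))
    cfg["stages"] = ["fit", "evaluate"]
    config.run_pipeline(cfg)
    report = json.loads((OUT / "validation.json").read_text())
    lo, hi = report["mpe_ci95"]
    print(f"MPE {report['mpe_pct']:.1f}% (CI95 {lo:.1f} to {hi:.1f})  "
          f"RMSE {report['rmse_pct']:.1f}%  n={report['n_pairs']}")
    print(f"pcVPC table and figure under {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 20)
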