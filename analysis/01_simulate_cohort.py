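#!/usr/bin/env python
"""Generate the synthetic TDM cohort that stands in for the hospital data.

41 subjects, once-daily isavuconazole 100-400 mg with an IV lead-in,
sparse mostly-trough sampling (median 4 samples, range 1-11),
concentrations from the final population model with mixed residual
error, plus outcome labels from the exposure-response model.  Writes
the NONMEM-dialect dataset, the hidden truth table and the outcome
labels under results/.
"""

import sys
from pathlib import Path

from isapk import config

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 20) -> None:
    cfg = config.default_config(seed=seed, out_dir=str(OUT))
    cfg["stages"] = ["simulate-cohort"]
    artifacts = config.run_pipeline(cfg)
    print("wrote:", ", ".join(sorted(artifacts.values())))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 20)
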