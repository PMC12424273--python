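#!/usr/bin/env python
"""Generate a synthetic mesocosm experiment (the working dataset).

Writes long-format diet and habitat records plus the tank design and
the generating ground truth under ``data/synthetic/``. All later
analysis steps read these files, so the whole analysis chain can be
reproduced from this script alone.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from nichevar.synthetic import GeneratorConfig, generate_experiment

SEED = 20260923
OUT = Path(__file__).resolve().parent.parent / "data" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = GeneratorConfig(seed=SEED)
    diet, habitat, design, truth = generate_experiment(config)
    for name, records in (("diet", diet), ("habitat", habitat)):
        frame = pd.DataFrame([dataclasses.asdict(r) for r in records])
        frame.to_csv(OUT / f"{name}.csv", index=False)
        print(f"{name}: {len(frame)} records, "
              f"{frame['individual_id'].nunique()} fish")
    design.to_frame().to_csv(OUT / "design.csv", index=False)
    with open(OUT / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    print(f"design: {len(design.tanks)} tanks in 4 treatments -> {OUT}")


if __name__ == "__main__":
    main()
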