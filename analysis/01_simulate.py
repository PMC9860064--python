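"""Simulate the 5x5 phototroph-heterotroph co-culture design.

Generates 25 strain combinations plus axenic controls in triplicate
(105 cultures, ~140 days of near-daily fluorescence, flow-cytometry counts
at days 60/100/140) and writes the tidy CSV trio plus the ground truth to
results/simulated/.
"""

import importlib
import json

common = importlib.import_module("00_common")

from cocultx.io_model import write_experiment
from cocultx.synthetic_data import SimConfig, simulate_experiment


def main() -> None:
    expset = simulate_experiment(SimConfig(seed=common.SEED))
    files = write_experiment(expset, common.DATA)
    truth_path = common.DATA / "truth.json"
    truth_path.write_text(json.dumps(expset.provenance, indent=2))
    n_co = sum(m.treatment == "coculture" for m in expset.metadata.values())
    print(f"simulated {len(expset.curves)} cultures ({n_co} co-cultures), "
          f"{len(expset.counts)} count records, seed {common.SEED}")
    for name, path in {**files, "truth": str(truth_path)}.items():
        print(f"  {name}: {path}")


if __name__ == "__main__":
    main()
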