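"""Shared plumbing for the numbered analysis drivers."""

from pathlib import Path

from cocultx.io_model import ExperimentSet, read_experiment

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATA = RESULTS / "simulated"
SEED = 17


def load_simulated() -> ExperimentSet:
    trio = [DATA / f for f in ("curves.csv", "metadata.csv", "counts.csv")]
    if not all(p.exists() for p in trio):
        raise SystemExit("simulated data missing - run analysis/01_simulate.py first")
    return read_experiment(*trio)
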