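"""End-to-end run: simulate a fixture directory, run all three flows.

Writes every synthetic input plus a ready-made config, runs the
network-pharmacology, omics and efficacy flows, and prints each flow's
headline summary.  Equivalent shell usage:

    netpharm simulate --seed 1 --out fixture/
    netpharm run-all --config fixture/config.yaml --out results/
"""

import json
import tempfile
from pathlib import Path

from netpharm.pipeline import PipelineConfig, run_all, simulate_fixture
from netpharm.simulate import SimulationSpec

with tempfile.TemporaryDirectory() as tmp:
    fixture = simulate_fixture(SimulationSpec(seed=1), Path(tmp) / "fixture")
    config = PipelineConfig.from_yaml(fixture / "config.yaml")
    out = run_all(config, Path(tmp) / "results")
    for flow in ("netpharm", "omics", "efficacy"):
        summary = json.loads((out / flow / "summary.json").read_text())
        print(f"{flow}: {json.dumps(summary, sort_keys=True)}")
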