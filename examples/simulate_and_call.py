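"""Full workflow on simulated data: generate a synthetic two-condition
experiment in which NMD is inhibited, run the pipeline, and print the global
up/down summary of predicted NMD substrates.

In condition 2 the NMD-substrate isoform of 15% of events is stabilized
(odds multiplied by 3.5); the expected signature is an excess of substrate
isoforms rising over falling.
"""

import tempfile
from pathlib import Path

import nmdsplice as ns

config = {
    "seed": 42,
    "simulate": {
        "n_genes": 300,
        "depth": 100,
        "psi_baseline": [900, 2100],   # baseline substrate ratio ~0.30
        "affected_fraction": 0.15,
        "stabilization": 3.5,
    },
}

with tempfile.TemporaryDirectory() as tmp:
    result = ns.run_pipeline(config, Path(tmp) / "run")
    print((result.out_dir / "report.txt").read_text())

    truth_hits = sum(c.nmd_direction == "nmd_up" for c in result.calls)
    print(f"events labeled nmd_up: {truth_hits} "
          f"(~0.15 x 300 affected events, minus power loss)")

# The report's per-class table shows the fraction of NMD-eligible events
# whose substrate isoform rose (frac_up) or fell (frac_down) by >= 10
# percentage points with BF10 >= 5; a large up/down enrichment is the
# signature of global NMD inhibition.
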