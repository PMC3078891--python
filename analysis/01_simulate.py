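"""Generate the synthetic two-tissue experiment with full ground truth.

Writes per-array spot tables, the probe→gene map, the term DAG with its
gene associations and GMT sets, and the planted-truth tables under
results/pipeline/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from importlib import import_module

cfg_mod = import_module("00_config")

from hibexpr import run_pipeline

if __name__ == "__main__":
    cfg = cfg_mod.config()
    manifest = run_pipeline(cfg, stages=["simulate"])
    for tissue, s in manifest["simulate"].items():
        print(f"{tissue}: {s['n_spots']} spots, {s['n_true_de']} planted DE genes")
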