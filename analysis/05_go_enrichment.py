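"""Direction-stratified GO enrichment with hierarchy pruning and resampling FDR."""

import sys
from importlib import import_module
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
cfg_mod = import_module("00_config")

from hibexpr import run_pipeline

if __name__ == "__main__":
    cfg = cfg_mod.config()
    manifest = run_pipeline(cfg, stages=["go"])
    for tissue in cfg.tissues:
        table = pd.read_csv(
            Path(cfg.outdir) / f"{tissue}_go_enrichment.tsv", sep="\t"
        )
        sig = table[table["fdr"] < 0.05]
        print(f"{tissue}: {len(sig)} categories at FDR < 0.05")
        if not sig.empty:
            cols = ["term", "direction", "n_on_array", "k_changed", "enrichment", "fdr"]
            print(sig[cols].to_string(index=False))
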