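"""RT-PCR validation: simulated Ct panel plus the published 32-gene panel.

Fits per-primer standard curves, computes efficiency-corrected relative
expression, tests groups, and reports concordance with the array calls —
for the simulated panel and for the published validation table.
"""

import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
cfg_mod = import_module("00_config")

from hibexpr import concordance, load_validation_panel, run_pipeline

if __name__ == "__main__":
    cfg = cfg_mod.config()
    manifest = run_pipeline(cfg, stages=["pcr"])
    p = manifest["pcr"]
    print(
        f"simulated panel: {p['n_confirmed']}/{p['n_genes']} confirmed "
        f"({100 * p['confirmation_rate']:.1f}%), r = {p['pearson_r']:.2f}"
    )
    verdicts, res = concordance(load_validation_panel())
    verdicts.to_csv(cfg_mod.RESULTS / "published_panel_verdicts.tsv",
                    sep="\t", index=False)
    print(
        f"published panel: {res.n_confirmed}/{res.n_total} confirmed "
        f"({100 * res.confirmation_rate:.1f}%), r = {res.pearson_r:.2f} "
        f"(p = {res.pearson_p:.2g}) over confirmed genes"
    )
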