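"""Intersect the two tissues' DE genes and classify direction concordance.

Also classifies the published liver/heart shared-gene table bundled with
the package (5 opposite, 5 down-in-both among its unique genes).
"""

import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
cfg_mod = import_module("00_config")

from hibexpr import (
    classify_direction,
    intersect_de,
    load_shared_de_genes,
    run_pipeline,
)

if __name__ == "__main__":
    cfg = cfg_mod.config()
    manifest = run_pipeline(cfg, stages=["overlap"])
    o = manifest["overlap"]
    print(
        f"synthetic overlap: {o['n_shared']} genes "
        f"(up both {o['up_both']}, down both {o['down_both']}, opposite {o['opposite']})"
    )

    raw = load_shared_de_genes()
    liver = raw[["gene_symbol", "p_liver", "log2fc_liver"]].rename(
        columns={"p_liver": "p_value", "log2fc_liver": "log2fc"}
    )
    heart = raw[["gene_symbol", "p_heart", "log2fc_heart"]].rename(
        columns={"p_heart": "p_value", "log2fc_heart": "log2fc"}
    )
    published = intersect_de(liver, heart)
    published.to_csv(cfg_mod.RESULTS / "published_shared_genes_classified.tsv",
                     sep="\t", index=False)
    print("published shared genes:", classify_direction(published))
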