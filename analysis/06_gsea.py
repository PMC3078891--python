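"""Cutoff-free verification: GSEA with exhaustive phenotype permutations.

Runs the running-sum enrichment over all generated gene sets and draws the
running-sum plot for the strongest set per tissue.
"""

import sys
from importlib import import_module
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
cfg_mod = import_module("00_config")

from hibexpr import run_pipeline
from hibexpr import io as io_mod
from hibexpr.gsea import plot_running_sum, rank_genes, signal_to_noise

if __name__ == "__main__":
    cfg = cfg_mod.config()
    manifest = run_pipeline(cfg, stages=["gsea"])
    out = Path(cfg.outdir)
    for tissue in cfg.tissues:
        table = pd.read_csv(out / f"{tissue}_gsea.tsv", sep="\t")
        print(f"{tissue}: {int((table['fdr'] < 0.05).sum())} sets at FDR < 0.05")
        best = table.sort_values("p_perm").iloc[0]
        matrix = io_mod.read_matrix(out / f"{tissue}_gene_matrix.tsv")
        gene_sets = io_mod.read_gmt(out / "gene_sets.gmt")
        ranked = rank_genes(signal_to_noise(matrix.values, matrix.groups))
        plot_running_sum(
            ranked,
            gene_sets[best["gene_set"]] & set(matrix.values.index),
            f"{tissue} {best['gene_set']}",
            path=str(cfg_mod.RESULTS / f"{tissue}_gsea_running_sum.png"),
        )
        print(f"  strongest set {best['gene_set']}: ES {best['es']:.3f}, "
              f"NES {best['nes']:.2f}, FDR {best['fdr']:.3f}")
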