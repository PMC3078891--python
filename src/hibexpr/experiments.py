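"""Canonical study-condition experiments over the synthetic generator.

These functions bundle the full analysis chain (simulate → preprocess →
differential expression → enrichment) at the conditions the pipeline is
designed around: 6 hibernating vs 5 summer samples, a few thousand spots,
~5% truly changed genes, selection at p < 0.01 and |log2FC| > 0.5 with the
exhaustive 462-relabelling permutation FDR.  They are what the analysis
drivers, the calibration tests and the results-reproduction script all run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import de as de_mod
from . import go as go_mod
from . import gsea as gsea_mod
from .preprocess import (
    ExpressionMatrix,
    background_correct,
    collapse_genes,
    detect_signal,
    filter_flags,
    gene_detection,
    map_probes,
    normalize_median,
)
from .simulate import GroundTruth, SyntheticDesign, generate_annotations, generate_array_experiment

__all__ = [
    "ArrayAnalysis",
    "run_array_analysis",
    "null_calibration",
    "signal_recovery",
    "enrichment_recovery",
]


@dataclass
class ArrayAnalysis:
    """Everything one synthetic experiment produces, end to end."""

    design: SyntheticDesign
    truth: GroundTruth
    matrix: ExpressionMatrix
    detected: pd.Series  # gene-level detection (significant signal)
    detection_rates: pd.DataFrame
    gene_table: pd.DataFrame  # collapsed, selected, per detected gene
    gene_values: pd.DataFrame  # gene-level expression (representative probes)
    fdr: de_mod.PermutationFdr

    @property
    def selected_genes(self) -> set[str]:
        return set(self.gene_table.loc[self.gene_table["selected"], "gene_symbol"])

    @property
    def background_genes(self) -> set[str]:
        return set(self.detected[self.detected].index)


def run_array_analysis(
    design: SyntheticDesign,
    p_cut: float = 0.01,
    fc_cut: float = 0.5,
    tissue: str = "heart",
    true_log2fc: pd.Series | None = None,
) -> ArrayAnalysis:
    """Simulate one experiment and run it through the full selection chain."""
    spots, probe_map, truth = generate_array_experiment(
        design, tissue=tissue, true_log2fc=true_log2fc
    )
    kept = background_correct(filter_flags(spots))
    kept, rates = detect_signal(kept)
    matrix = normalize_median(kept)
    matrix = map_probes(matrix, probe_map)
    detected = gene_detection(matrix)
    probe_table = de_mod.de_table(matrix)
    probe_table["gene_symbol"] = probe_table["probe_id"].map(matrix.probe_gene)
    gene_table = collapse_genes(probe_table, p_col="p_value")
    gene_table = gene_table[gene_table["gene_symbol"].isin(detected[detected].index)]
    gene_table = de_mod.select_de(gene_table, p_cut, fc_cut)
    gene_values = matrix.values.loc[gene_table["probe_id"]]
    gene_values.index = pd.Index(gene_table["gene_symbol"], name="gene_symbol")
    fdr = de_mod.permutation_fdr(
        gene_values, matrix.groups, p_cut, fc_cut, seed=design.seed
    )
    return ArrayAnalysis(
        design=design,
        truth=truth,
        matrix=matrix,
        detected=detected,
        detection_rates=rates,
        gene_table=gene_table,
        gene_values=gene_values,
        fdr=fdr,
    )


def null_calibration(seed: int, n_genes: int = 5000) -> dict:
    """No-effect design: the FDR estimator should report ~1 and the observed
    selection count should sit inside the permutation null distribution."""
    design = SyntheticDesign(
        n_probes=int(n_genes * 1.12), n_genes=n_genes, frac_de=0.0, seed=seed
    )
    run = run_array_analysis(design)
    perm = run.fdr.perm_counts
    return {
        "fdr": run.fdr.fdr,
        "observed_count": run.fdr.observed_count,
        "mean_perm_count": float(perm.mean()),
        "sd_perm_count": float(perm.std()),
        "n_permutations": len(perm),
        "n_background": len(run.background_genes),
    }


def signal_recovery(seed: int) -> dict:
    """Default signal design: recovery of planted genes and the operating
    point (selected fraction, experiment FDR)."""
    design = SyntheticDesign(seed=seed)
    run = run_array_analysis(design)
    truth_de = set(run.truth.de_genes["gene_symbol"])
    detected_de = truth_de & run.background_genes
    recovered = truth_de & run.selected_genes
    n_bg = len(run.background_genes)
    return {
        "n_planted": len(truth_de),
        "n_planted_detected": len(detected_de),
        "recovery_detected": len(recovered & detected_de) / len(detected_de),
        "recovery_overall": len(recovered) / len(truth_de),
        "selected_fraction": run.fdr.observed_count / n_bg,
        "fdr": run.fdr.fdr,
        "pct_up": float(
            100.0
            * (run.gene_table.loc[run.gene_table.selected, "direction"] == "up").mean()
        ),
    }


def enrichment_recovery(
    seed: int,
    n_terms: int = 20,
    enriched_terms: int = 4,
    go_fdr_cut: float = 0.05,
    n_resamples: int = 500,
) -> dict:
    """One seed of the category-recovery experiment.

    Runs direction-stratified Fisher enrichment with hierarchy pruning and
    resampling FDR over the generated DAG, then verifies the significant
    categories with the phenotype-permutation GSEA (the cutoff-free
    cross-check, run on exactly those categories).
    """
    design = SyntheticDesign(seed=seed)
    run = run_array_analysis(design)
    ann = generate_annotations(
        run.truth, n_terms=n_terms, enriched_terms=enriched_terms, seed=seed + 7
    )
    prop = go_mod.propagate_annotations(ann.dag, ann.annotations)
    background = run.background_genes
    sel = run.gene_table
    significant: dict[str, float] = {}
    sig_direction: dict[str, str] = {}
    for direction in ("up", "down"):
        changed = set(
            sel.loc[sel["selected"] & (sel["direction"] == direction), "gene_symbol"]
        )
        res = go_mod.enrich_terms(
            changed, background, prop, dag=ann.dag, direction=direction
        )
        res = go_mod.prune_hierarchy(res, ann.dag)
        if res.empty:
            continue
        res = go_mod.resampling_fdr(
            res, background, prop, n_resamples=n_resamples, seed=seed + 13
        )
        for _, row in res.iterrows():
            if row["fdr"] < go_fdr_cut:
                significant[row["term"]] = float(row["fdr"])
                sig_direction[row["term"]] = direction

    planted = dict(zip(ann.enriched["term"], ann.enriched["direction"]))
    go_planted_ok = set(planted) <= set(significant) and all(
        sig_direction.get(t) == d for t, d in planted.items()
    )
    # ancestors of a planted leaf inherit its excess by true-path
    # propagation, so they are enriched by construction, not spuriously
    planted_closure = set(planted)
    for t in planted:
        planted_closure |= go_mod.term_ancestors(ann.dag, t)
    unplanted_flagged = sorted(set(significant) - planted_closure)

    gsea_ok = True
    gsea_max_fdr = float("nan")
    test_sets = {
        t: ann.gene_sets[t] & set(run.gene_values.index)
        for t in (significant or planted)
        if t in ann.gene_sets
    }
    test_sets = {t: s for t, s in test_sets.items() if s}
    if test_sets:
        gr = gsea_mod.permutation_significance(
            ExpressionMatrix(values=run.gene_values, groups=run.matrix.groups),
            gene_sets=test_sets,
            seed=seed + 17,
        ).set_index("gene_set")
        in_run = [t for t in planted if t in gr.index]
        gsea_ok = all(
            ((gr.loc[t, "es"] > 0) == (planted[t] == "up"))
            and gr.loc[t, "fdr"] < 0.05
            for t in in_run
        )
        if in_run:
            gsea_max_fdr = float(gr.loc[in_run, "fdr"].max())
    return {
        "go_planted_recovered": bool(go_planted_ok),
        "n_unplanted_flagged": len(unplanted_flagged),
        "gsea_planted_ok": bool(gsea_ok),
        "gsea_max_planted_fdr": gsea_max_fdr,
    }
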