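"""End-to-end orchestration: simulate → preprocess → DE → overlap → GO → GSEA → PCR.

The pipeline runs each tissue independently through preprocessing and
differential expression, joins tissues for the overlap table, performs
direction-stratified GO enrichment and a phenotype-permutation GSEA, and —
when Ct data are present — the RT-PCR validation.  Every stage writes its
tables under the output directory and appends its row counts to a run
manifest, so a rerun with the same seed reproduces byte-identical outputs
and any stage can be rerun from the on-disk intermediates of the previous
ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import go as go_mod
from . import gsea as gsea_mod
from . import io as io_mod
from . import rtpcr as rtpcr_mod
from .crosstissue import classify_direction, intersect_de
from .preprocess import (
    background_correct,
    collapse_genes,
    detect_signal,
    filter_flags,
    gene_detection,
    map_probes,
    normalize_median,
)
from .simulate import (
    SyntheticDesign,
    generate_annotations,
    generate_array_experiment,
    generate_pcr_panel,
)

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = ("simulate", "preprocess", "de", "overlap", "go", "gsea", "pcr")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; seed is mandatory for stochastic stages."""

    outdir: str = "pipeline_out"
    tissues: tuple[str, ...] = ("heart", "liver")
    design: dict = field(default_factory=dict)
    n_shared_de: int = 30
    p_cut: float = 0.01
    fc_cut: float = 0.5
    min_score: float = 100.0
    min_changed: int = 5
    min_detect_fraction: float = 0.5
    go_terms: int = 20
    go_enriched_terms: int = 4
    go_resamples: int = 1000
    gsea_weight: float = 1.0
    pcr_genes: int = 12
    pcr_ct_noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_cut <= 1:
            raise ValueError("p_cut must be in (0, 1]")
        if self.fc_cut < 0:
            raise ValueError("fc_cut must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "tissues" in raw:
            raw["tissues"] = tuple(raw["tissues"])
        return cls(**raw)

    def tissue_design(self, i: int) -> SyntheticDesign:
        return SyntheticDesign(**{**self.design, "seed": self.seed + 101 * (i + 1)})


def _stage_simulate(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    rng = np.random.default_rng(cfg.seed)
    designs = [cfg.tissue_design(i) for i in range(len(cfg.tissues))]
    d0 = designs[0]
    genes = [f"Bbg{i+1:04d}" for i in range(d0.n_genes)]
    lo, hi = d0.effect_log2fc_range
    n_de = int(round(d0.frac_de * d0.n_genes))
    n_shared = min(cfg.n_shared_de, n_de)
    shared = rng.choice(d0.n_genes, size=n_shared, replace=False)
    shared_fc = rng.uniform(lo, hi, n_shared) * rng.choice([-1.0, 1.0], n_shared)

    for tissue, design in zip(cfg.tissues, designs):
        own = rng.choice(
            [i for i in range(design.n_genes) if i not in set(shared)],
            size=max(0, n_de - n_shared),
            replace=False,
        )
        fc = np.zeros(design.n_genes)
        fc[shared] = shared_fc
        fc[own] = rng.uniform(lo, hi, len(own)) * rng.choice([-1.0, 1.0], len(own))
        truth_fc = pd.Series(fc, index=genes)
        spots, probe_map, truth = generate_array_experiment(
            design, tissue=tissue, true_log2fc=truth_fc
        )
        io_mod.write_spot_table(spots, out / f"{tissue}_spots.tsv")
        io_mod.write_probe_map(probe_map, out / f"{tissue}_probe_map.tsv")
        truth.genes.to_csv(out / f"{tissue}_truth.tsv", sep="\t", index=False)
        manifest.setdefault("simulate", {})[tissue] = {
            "n_spots": int(len(spots)),
            "n_true_de": int((truth.genes["direction"] != "null").sum()),
        }
        if tissue == cfg.tissues[0]:
            ann = generate_annotations(
                truth,
                n_terms=cfg.go_terms,
                enriched_terms=cfg.go_enriched_terms,
                seed=cfg.seed + 7,
            )
            io_mod.write_obo(ann.dag, out / "terms.obo")
            io_mod.write_gene_associations(ann.annotations, out / "associations.tsv")
            io_mod.write_gmt(ann.gene_sets, out / "gene_sets.gmt")
            ann.enriched.to_csv(out / "enriched_terms_truth.tsv", sep="\t", index=False)


def _preprocess_tissue(cfg: PipelineConfig, out: Path, tissue: str):
    spots = io_mod.read_spot_table(out / f"{tissue}_spots.tsv")
    probe_map = io_mod.read_probe_map(out / f"{tissue}_probe_map.tsv")
    kept = filter_flags(spots)
    kept = background_correct(kept)
    kept, rates = detect_signal(kept)
    matrix = normalize_median(kept)
    matrix = map_probes(matrix, probe_map, min_score=cfg.min_score)
    return matrix, rates


def _stage_preprocess(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    for tissue in cfg.tissues:
        matrix, rates = _preprocess_tissue(cfg, out, tissue)
        io_mod.write_matrix(matrix, out / f"{tissue}_matrix.tsv")
        matrix.probe_gene.rename("gene_symbol").to_csv(
            out / f"{tissue}_probe_gene.tsv", sep="\t"
        )
        rates.to_csv(out / f"{tissue}_detection.tsv", sep="\t", index=False)
        detected = gene_detection(matrix, cfg.min_detect_fraction)
        detected.rename("detected").to_csv(
            out / f"{tissue}_gene_detected.tsv", sep="\t"
        )
        manifest.setdefault("preprocess", {})[tissue] = {
            "n_probes_kept": int(len(matrix.values)),
            "mean_detection_rate": float(rates["detection_rate"].mean()),
            "n_genes_detected": int(detected.sum()),
        }


def _load_tissue(out: Path, tissue: str):
    matrix = io_mod.read_matrix(out / f"{tissue}_matrix.tsv")
    pg = pd.read_csv(out / f"{tissue}_probe_gene.tsv", sep="\t", index_col=0)[
        "gene_symbol"
    ]
    matrix.probe_gene = pg
    detected = pd.read_csv(
        out / f"{tissue}_gene_detected.tsv", sep="\t", index_col=0
    )["detected"]
    return matrix, detected


def _stage_de(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    for tissue in cfg.tissues:
        matrix, detected = _load_tissue(out, tissue)
        probe_table = de_mod.de_table(matrix)
        probe_table["gene_symbol"] = probe_table["probe_id"].map(matrix.probe_gene)
        gene_table = collapse_genes(probe_table, p_col="p_value")
        gene_table = gene_table[gene_table["gene_symbol"].isin(detected[detected].index)]
        gene_table = de_mod.select_de(gene_table, cfg.p_cut, cfg.fc_cut)
        summary = de_mod.de_summary(gene_table, n_background=int(detected.sum()))
        gene_values = matrix.values.loc[gene_table["probe_id"]]
        gene_values.index = gene_table["gene_symbol"].to_numpy()
        gene_values.index.name = "gene_symbol"
        io_mod.write_matrix(
            type(matrix)(values=gene_values, groups=matrix.groups),
            out / f"{tissue}_gene_matrix.tsv",
        )
        fdr = de_mod.permutation_fdr(
            gene_values, matrix.groups, cfg.p_cut, cfg.fc_cut, seed=cfg.seed
        )
        summary["experiment_fdr"] = fdr.fdr
        summary["mean_perm_selected"] = fdr.mean_perm_count
        gene_table["experiment_fdr"] = fdr.fdr
        gene_table.to_csv(out / f"{tissue}_de_genes.tsv", sep="\t", index=False)
        io_mod.write_json(summary, out / f"{tissue}_de_summary.json")
        manifest.setdefault("de", {})[tissue] = summary


def _stage_overlap(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    if len(cfg.tissues) < 2:
        return
    a, b = cfg.tissues[0], cfg.tissues[1]
    de_a = pd.read_csv(out / f"{a}_de_genes.tsv", sep="\t")
    de_b = pd.read_csv(out / f"{b}_de_genes.tsv", sep="\t")
    overlap = intersect_de(de_a, de_b, names=(a, b))
    overlap.to_csv(out / "overlap.tsv", sep="\t", index=False)
    manifest["overlap"] = {
        "n_shared": int(len(overlap)),
        **classify_direction(overlap),
    }


def _stage_go(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    dag = io_mod.read_obo(out / "terms.obo")
    go_mod.validate_dag(dag)
    direct = io_mod.read_gene_associations(out / "associations.tsv")
    annotations = go_mod.propagate_annotations(dag, direct)
    for tissue in cfg.tissues:
        de_genes = pd.read_csv(out / f"{tissue}_de_genes.tsv", sep="\t")
        detected = pd.read_csv(
            out / f"{tissue}_gene_detected.tsv", sep="\t", index_col=0
        )["detected"]
        background = set(detected[detected].index)
        frames = []
        for direction in ("up", "down"):
            changed = set(
                de_genes.loc[
                    de_genes["selected"] & (de_genes["direction"] == direction),
                    "gene_symbol",
                ]
            )
            res = go_mod.enrich_terms(
                changed, background, annotations, dag=dag,
                direction=direction, min_changed=cfg.min_changed,
            )
            res = go_mod.prune_hierarchy(res, dag)
            if not res.empty:
                res = go_mod.resampling_fdr(
                    res, background, annotations,
                    n_resamples=cfg.go_resamples, seed=cfg.seed + 13,
                )
            frames.append(res)
        result = pd.concat(frames, ignore_index=True)
        flat = result.assign(members=result["members"].map(lambda m: ";".join(m)))
        flat.to_csv(out / f"{tissue}_go_enrichment.tsv", sep="\t", index=False)
        manifest.setdefault("go", {})[tissue] = {
            "n_terms_tested": int(len(result)),
            "n_significant": int((result["p_value"] < 0.05).sum()),
        }


def _stage_gsea(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    gene_sets = io_mod.read_gmt(out / "gene_sets.gmt")
    for tissue in cfg.tissues:
        matrix = io_mod.read_matrix(out / f"{tissue}_gene_matrix.tsv")
        usable = {
            name: gs & set(matrix.values.index)
            for name, gs in gene_sets.items()
        }
        usable = {
            n: g
            for n, g in usable.items()
            if g and len(g) < len(matrix.values.index)
        }
        res = gsea_mod.permutation_significance(
            matrix, gene_sets=usable, weight_exponent=cfg.gsea_weight,
            seed=cfg.seed + 17,
        )
        flat = res.assign(
            hit_ranks=res["hit_ranks"].map(lambda h: ";".join(map(str, h)))
        )
        flat.to_csv(out / f"{tissue}_gsea.tsv", sep="\t", index=False)
        manifest.setdefault("gsea", {})[tissue] = {
            "n_sets": int(len(res)),
            "n_fdr_lt_05": int((res["fdr"] < 0.05).sum()),
        }


def _stage_pcr(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    tissue = cfg.tissues[0]
    matrix = io_mod.read_matrix(out / f"{tissue}_gene_matrix.tsv")
    truth = pd.read_csv(
        out / f"{tissue}_truth.tsv", sep="\t",
        keep_default_na=False, na_values=[""],  # 'null' is a direction label
    )
    de_genes = pd.read_csv(out / f"{tissue}_de_genes.tsv", sep="\t")
    chosen = (
        de_genes[de_genes["selected"]]
        .sort_values("p_value")["gene_symbol"]
        .head(cfg.pcr_genes)
        .tolist()
    )
    if not chosen:
        manifest["pcr"] = {"n_genes": 0}
        return
    from .simulate import GroundTruth

    gt = GroundTruth(genes=truth, probes=pd.DataFrame())
    panel_ct = generate_pcr_panel(
        gt, chosen, matrix.values, matrix.groups,
        ct_noise_sd=cfg.pcr_ct_noise_sd, seed=cfg.seed + 23,
    )
    io_mod.write_ct_table(panel_ct, out / f"{tissue}_ct.tsv")
    reference = panel_ct.loc[panel_ct["is_reference"], "gene"].iloc[0]
    panel = rtpcr_mod.analyze_panel(panel_ct, reference_gene=reference)
    panel = panel.merge(
        de_genes[["gene_symbol", "log2fc", "p_value"]].rename(
            columns={"log2fc": "array_log2fc", "p_value": "array_p"}
        ),
        on="gene_symbol",
    )
    verdicts, summary = rtpcr_mod.concordance(panel)
    verdicts.to_csv(out / f"{tissue}_pcr_panel.tsv", sep="\t", index=False)
    manifest["pcr"] = {
        "n_genes": summary.n_total,
        "n_confirmed": summary.n_confirmed,
        "confirmation_rate": summary.confirmation_rate,
        "pearson_r": summary.pearson_r,
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "de": _stage_de,
    "overlap": _stage_overlap,
    "go": _stage_go,
    "gsea": _stage_gsea,
    "pcr": _stage_pcr,
}


def run_pipeline(config: PipelineConfig, stages=None) -> dict:
    """Run the requested stages (default: all) and return the manifest."""
    stages = list(STAGES) if stages is None else list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest: dict = {}
    if manifest_path.exists():
        import json

        manifest = json.loads(manifest_path.read_text())
    manifest["config"] = asdict(config)
    manifest["config"]["tissues"] = list(config.tissues)
    for stage in STAGES:
        if stage not in stages:
            continue
        try:
            _STAGE_FUNCS[stage](config, out, manifest)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        io_mod.write_json(manifest, manifest_path)
    _write_summary(manifest, out / "summary.txt")
    return manifest


def _write_summary(manifest: dict, path: Path) -> None:
    lines = ["hibexpr pipeline summary", "========================"]
    for tissue, s in manifest.get("de", {}).items():
        lines.append(
            f"{tissue}: {s['n_selected']} DE genes"
            f" ({s.get('pct_selected', float('nan')):.1f}% of"
            f" {s.get('n_background', 0)} detected genes),"
            f" {s['pct_up']:.0f}% up, experiment FDR"
            f" {s.get('experiment_fdr', float('nan')):.3f}"
        )
    if "overlap" in manifest:
        o = manifest["overlap"]
        lines.append(
            f"shared DE genes: {o['n_shared']}"
            f" (up both {o['up_both']}, down both {o['down_both']},"
            f" opposite {o['opposite']})"
        )
    if "pcr" in manifest and manifest["pcr"].get("n_genes"):
        p = manifest["pcr"]
        lines.append(
            f"RT-PCR: {p['n_confirmed']}/{p['n_genes']} confirmed"
            f" ({100 * p['confirmation_rate']:.1f}%), r = {p['pearson_r']:.2f}"
        )
    path.write_text("\n".join(lines) + "\n")
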