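"""Synthetic spotted-array experiments with known ground truth.

The generator emulates the kind of two-condition radiolabelled cDNA array
experiment this pipeline analyses: a small unbalanced design (6 hibernating
vs 5 summer-active animals), a few thousand spotted probes per array,
log-normal spot intensities riding on an additive local background, a
fraction of flagged (unusable) spots, genes represented by more than one
probe, and a minority of genes with a real group effect.  Every random
choice flows through one :class:`numpy.random.Generator` seeded from the
design, so a design regenerates bit-identical tables.

Alongside the spot tables the generator emits the probe-to-gene mapping
(with alignment scores mimicking a BLAST-vs-RefSeq screen), a small GO-style
term DAG with designated enriched terms, and matched qPCR Ct tables with
dilution series — everything downstream stages consume, with full ground
truth for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SyntheticDesign",
    "GroundTruth",
    "AnnotationBundle",
    "generate_array_experiment",
    "generate_annotations",
    "generate_pcr_panel",
]

@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of one synthetic two-group array experiment.

    Defaults mirror the study design this pipeline targets: 6 hibernating vs
    5 summer animals on a 3,200-spot array, ~5% of genes truly changed with
    |log2FC| in [1, 3], per-spot multiplicative noise of 0.35 on the log2
    scale, local background around 10% of the median signal, 5% flagged
    spots and 10% of genes carried by two probes.
    """

    n_hibernating: int = 6
    n_summer: int = 5
    n_probes: int = 3200
    n_genes: int = 2500
    frac_de: float = 0.05
    effect_log2fc_range: tuple[float, float] = (1.0, 3.0)
    dispersion: float = 0.35
    background_scale: float = 0.10
    flag_rate: float = 0.05
    multiprobe_rate: float = 0.10
    abundance_log2_sd: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hibernating", "n_summer", "n_probes", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("frac_de", "flag_rate", "multiprobe_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.effect_log2fc_range
        if lo <= 0 or hi < lo:
            raise ValueError("effect_log2fc_range must satisfy 0 < lo <= hi")
        if self.n_genes > self.n_probes:
            raise ValueError("n_genes cannot exceed n_probes")
        if self.dispersion < 0 or self.background_scale < 0:
            raise ValueError("dispersion and background_scale must be >= 0")

    @property
    def samples(self) -> list[str]:
        return [f"hib{i+1}" for i in range(self.n_hibernating)] + [
            f"sum{i+1}" for i in range(self.n_summer)
        ]

    @property
    def groups(self) -> pd.Series:
        labels = ["hibernating"] * self.n_hibernating + ["summer"] * self.n_summer
        return pd.Series(labels, index=self.samples, name="group")


@dataclass
class GroundTruth:
    """True per-gene effects and probe layout of a synthetic experiment.

    ``genes`` has one row per gene (gene_symbol, true_log2fc, direction in
    {up, down, null}); ``probes`` maps every mapped probe to exactly one
    gene.  Term memberships are attached by :func:`generate_annotations`.
    """

    genes: pd.DataFrame
    probes: pd.DataFrame
    categories: dict[str, set[str]] = field(default_factory=dict)

    @property
    def de_genes(self) -> pd.DataFrame:
        return self.genes[self.genes["direction"] != "null"]


def _gene_symbols(n: int) -> list[str]:
    return [f"Bbg{i+1:04d}" for i in range(n)]


def generate_array_experiment(
    design: SyntheticDesign,
    tissue: str = "heart",
    true_log2fc: pd.Series | None = None,
):
    """Simulate one experiment: per-sample spot tables, probe map, truth.

    Returns ``(spots, probe_map, truth)`` where ``spots`` is a long-format
    table (array_id, sample, group, tissue, probe_id, signal_median,
    bg_median, flag), ``probe_map`` holds candidate probe→gene hits with
    alignment scores, and ``truth`` is the :class:`GroundTruth`.

    The intensity model: spot signal = local background + gene abundance ×
    per-array scale × 2^N(0, dispersion).  Hibernating samples of a DE gene
    carry abundance × 2^true_log2fc, so the group-mean ratio equals the
    planted fold change.  Array scale factors are log-uniform in [0.5, 2]
    so that median normalization is consequential; flags are assigned
    independently of intensity.

    ``true_log2fc`` (indexed by gene symbol) overrides the random effect
    draw — used to plant the same genes in two tissues.
    """
    rng = np.random.default_rng(design.seed)
    genes = _gene_symbols(design.n_genes)

    # --- true effects -----------------------------------------------------
    if true_log2fc is None:
        n_de = int(round(design.frac_de * design.n_genes))
        de_idx = rng.choice(design.n_genes, size=n_de, replace=False)
        lo, hi = design.effect_log2fc_range
        effects = np.zeros(design.n_genes)
        effects[de_idx] = rng.uniform(lo, hi, size=n_de) * rng.choice(
            [-1.0, 1.0], size=n_de
        )
    else:
        effects = true_log2fc.reindex(genes).fillna(0.0).to_numpy(float)
    direction = np.where(effects > 0, "up", np.where(effects < 0, "down", "null"))
    truth_genes = pd.DataFrame(
        {"gene_symbol": genes, "true_log2fc": effects, "direction": direction}
    )

    # --- probe layout -----------------------------------------------------
    n_multi = int(round(design.multiprobe_rate * design.n_genes))
    n_mapped_probes = design.n_genes + n_multi
    if n_mapped_probes > design.n_probes:
        raise ValueError(
            "design requires more mapped probes than spots: lower multiprobe_rate"
        )
    multi_genes = rng.choice(design.n_genes, size=n_multi, replace=False)
    probe_gene_idx = np.concatenate([np.arange(design.n_genes), multi_genes])
    probe_ids = [f"P{i+1:05d}" for i in range(design.n_probes)]
    truth_probes = pd.DataFrame(
        {
            "probe_id": [probe_ids[i] for i in range(n_mapped_probes)],
            "gene_symbol": [genes[g] for g in probe_gene_idx],
        }
    )

    # probe map: true hits score >= 120, plus occasional lower-scoring
    # secondary hits and sub-threshold decoy probes (score < 100).
    rows = {
        "probe_id": list(truth_probes["probe_id"]),
        "gene_symbol": list(truth_probes["gene_symbol"]),
        "align_score": list(rng.uniform(120.0, 500.0, size=n_mapped_probes)),
    }
    secondary = rng.random(n_mapped_probes) < 0.05
    for i in np.flatnonzero(secondary):
        other = genes[int(rng.integers(design.n_genes))]
        if other == rows["gene_symbol"][i]:
            continue
        rows["probe_id"].append(rows["probe_id"][i])
        rows["gene_symbol"].append(other)
        rows["align_score"].append(
            max(60.0, rows["align_score"][i] - float(rng.uniform(5.0, 50.0)))
        )
    for i in range(n_mapped_probes, design.n_probes):
        rows["probe_id"].append(probe_ids[i])
        rows["gene_symbol"].append(f"Dec{i:04d}")
        rows["align_score"].append(float(rng.uniform(20.0, 99.0)))
    probe_map = pd.DataFrame(rows)

    # --- abundances and spot intensities ---------------------------------
    base_abundance = 2.0 ** rng.normal(6.0, design.abundance_log2_sd, design.n_probes)
    affinity = 2.0 ** rng.normal(0.0, 0.5, design.n_probes)  # per-probe efficiency
    probe_effect = np.zeros(design.n_probes)
    probe_effect[:n_mapped_probes] = effects[probe_gene_idx]

    scale = np.exp(rng.uniform(np.log(0.5), np.log(2.0), len(design.samples)))
    groups = design.groups
    frames = []
    for j, sample in enumerate(design.samples):
        shift = probe_effect if groups[sample] == "hibernating" else 0.0
        mu = base_abundance * affinity * 2.0**shift
        noise = 2.0 ** rng.normal(0.0, design.dispersion, design.n_probes)
        level = design.background_scale * float(np.median(mu))
        bg = level * rng.uniform(0.5, 1.5, design.n_probes) * scale[j]
        signal = bg + mu * noise * scale[j]
        frames.append(
            pd.DataFrame(
                {
                    "array_id": f"{tissue}_{sample}",
                    "sample": sample,
                    "group": groups[sample],
                    "tissue": tissue,
                    "probe_id": probe_ids,
                    "signal_median": signal,
                    "bg_median": bg,
                    "flag": np.where(
                        rng.random(design.n_probes) < design.flag_rate, "flagged", "ok"
                    ),
                }
            )
        )
    spots = pd.concat(frames, ignore_index=True)
    return spots, probe_map, GroundTruth(genes=truth_genes, probes=truth_probes)


@dataclass
class AnnotationBundle:
    """GO-style annotation resources generated for one synthetic truth."""

    dag: nx.MultiDiGraph
    annotations: pd.DataFrame  # columns: gene_symbol, term (direct only)
    gene_sets: dict[str, set[str]]  # GMT-style, term name -> genes
    enriched: pd.DataFrame  # columns: term, direction


def generate_annotations(
    truth: GroundTruth,
    n_terms: int = 20,
    enriched_terms: int = 4,
    term_size: tuple[int, int] = (40, 80),
    enrich_frac: float = 0.3,
    namespace: str = "biological_process",
    seed: int = 0,
) -> AnnotationBundle:
    """Build a small term DAG whose designated terms are truly enriched.

    The DAG is three levels deep: a namespace root, parent terms, and
    ``n_terms`` leaf terms (two leaves per parent).  Direct annotations are
    placed on leaves only, so a parent's propagated membership is exactly
    the union of its children's.  The first ``enriched_terms`` leaves are
    preferentially filled (fraction ``enrich_frac``) with truly DE genes of
    alternating direction (up, down, up, ...); all other leaves draw genes
    uniformly, independent of DE status.
    """
    if enriched_terms > n_terms:
        raise ValueError("enriched_terms cannot exceed n_terms")
    rng = np.random.default_rng(seed)
    genes = truth.genes["gene_symbol"].to_numpy()
    up = truth.genes.loc[truth.genes["direction"] == "up", "gene_symbol"].to_numpy()
    down = truth.genes.loc[truth.genes["direction"] == "down", "gene_symbol"].to_numpy()
    null = truth.genes.loc[truth.genes["direction"] == "null", "gene_symbol"].to_numpy()

    dag = nx.MultiDiGraph()
    root = "GO:0000001"
    dag.add_node(root, name=f"{namespace} root", namespace=namespace)
    n_parents = (n_terms + 1) // 2
    parents = [f"GO:1{i:06d}" for i in range(n_parents)]
    leaves = [f"GO:2{i:06d}" for i in range(n_terms)]
    for i, p in enumerate(parents):
        dag.add_node(p, name=f"parent term {i}", namespace=namespace)
        dag.add_edge(p, root, key="is_a")
    for i, t in enumerate(leaves):
        dag.add_node(t, name=f"leaf term {i}", namespace=namespace)
        dag.add_edge(t, parents[i // 2], key="is_a")

    members: dict[str, set[str]] = {}
    enriched_rows = []
    for i, t in enumerate(leaves):
        size = int(rng.integers(term_size[0], term_size[1] + 1))
        if i < enriched_terms:
            direction = "up" if i % 2 == 0 else "down"
            pool = up if direction == "up" else down
            n_sig = min(len(pool), int(round(enrich_frac * size)))
            chosen = set(rng.choice(pool, size=n_sig, replace=False))
            fill = rng.choice(null, size=size - n_sig, replace=False)
            members[t] = chosen | set(fill)
            enriched_rows.append({"term": t, "direction": direction})
        else:
            members[t] = set(rng.choice(genes, size=min(size, len(genes)), replace=False))

    annotations = pd.DataFrame(
        [(g, t) for t, gs in members.items() for g in sorted(gs)],
        columns=["gene_symbol", "term"],
    )
    gene_sets = {t: set(gs) for t, gs in members.items()}
    for i, p in enumerate(parents):
        kids = leaves[2 * i : 2 * i + 2]
        gene_sets[p] = set().union(*(members[k] for k in kids))
    truth.categories = {t: set(gs) for t, gs in gene_sets.items()}
    enriched = pd.DataFrame(enriched_rows, columns=["term", "direction"])
    return AnnotationBundle(dag=dag, annotations=annotations, gene_sets=gene_sets, enriched=enriched)


def generate_pcr_panel(
    truth: GroundTruth,
    genes: list[str],
    expression: pd.DataFrame,
    groups: pd.Series,
    reference_gene: str | None = None,
    ct_noise_sd: float = 0.15,
    efficiency_range: tuple[float, float] = (1.85, 2.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Emit a long-format Ct table with matching 10-fold dilution series.

    ``expression`` is a genes × samples table of relative abundances (the
    normalized expression matrix works).  Ct follows the standard-curve
    model Ct = c0 − log_E(abundance) + N(0, ct_noise_sd); each primer set
    additionally yields a 4-point 10-fold dilution series (rows with
    ``dilution`` set and sample == "standard").  The reference gene, by
    construction a gene with zero true effect, is appended if absent.
    """
    rng = np.random.default_rng(seed)
    if reference_gene is None:
        nulls = truth.genes.loc[truth.genes["direction"] == "null", "gene_symbol"]
        candidates = [g for g in nulls if g in expression.index and g not in genes]
        if not candidates:
            raise ValueError("no null gene available as reference")
        reference_gene = candidates[0]
    panel_genes = list(genes)
    if reference_gene not in panel_genes:
        panel_genes.append(reference_gene)
    missing = [g for g in panel_genes if g not in expression.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")

    lo, hi = efficiency_range
    records = []
    for g in panel_genes:
        eff = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        c0 = float(rng.uniform(20.0, 28.0))
        x = expression.loc[g]
        for sample, value in x.items():
            if not np.isfinite(value) or value <= 0:
                continue
            ct = c0 - np.log(value) / np.log(eff) + rng.normal(0.0, ct_noise_sd)
            records.append(
                {
                    "sample": sample,
                    "group": groups[sample],
                    "gene": g,
                    "ct": ct,
                    "dilution": np.nan,
                    "efficiency_true": eff,
                    "is_reference": g == reference_gene,
                }
            )
        for d in (1.0, 0.1, 0.01, 0.001):
            ct = c0 - np.log(d) / np.log(eff) + rng.normal(0.0, ct_noise_sd)
            records.append(
                {
                    "sample": "standard",
                    "group": "standard",
                    "gene": g,
                    "ct": ct,
                    "dilution": d,
                    "efficiency_true": eff,
                    "is_reference": g == reference_gene,
                }
            )
    return pd.DataFrame.from_records(records)
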