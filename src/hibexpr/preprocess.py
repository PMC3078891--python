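"""Spot-table preprocessing: flags, background, detection, normalization.

Raw input is a long-format spot table with one row per (array, probe):
``array_id, sample, group, [tissue,] probe_id, signal_median, bg_median,
flag``.  The stages here mirror the classic analysis of radiolabelled
spotted arrays: drop flagged spots, subtract the local background median
from the signal median, call a spot detected when its signal exceeds twice
its local background, divide each array's background-corrected values by
their median (so every array's median normalized value is 1), map probes to
gene symbols through an alignment-score table, and collapse multi-probe
genes to their most significant probe.

Non-positive background-corrected values cannot participate in a
division-based normalization; they are carried as missing (NaN) and excluded
from the per-array median and from downstream testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "filter_flags",
    "background_correct",
    "detect_signal",
    "normalize_median",
    "map_probes",
    "collapse_genes",
    "gene_detection",
]


@dataclass
class ExpressionMatrix:
    """Normalized expression values with sample metadata.

    ``values``: rows are probes (or genes after mapping/collapsing),
    columns are samples; entries are median-normalized intensities, NaN
    where the spot was flagged or non-positive after background
    correction.  ``groups`` maps sample -> phenotype label.  ``detected``
    is the spot-level detection mask on the same axes.  ``probe_gene``
    (after :func:`map_probes`) maps each retained probe to its gene.
    """

    values: pd.DataFrame
    groups: pd.Series
    detected: pd.DataFrame | None = None
    probe_gene: pd.Series | None = None
    qc: dict = field(default_factory=dict)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(),
            groups=self.groups.copy(),
            detected=None if self.detected is None else self.detected.copy(),
            probe_gene=None if self.probe_gene is None else self.probe_gene.copy(),
            qc=dict(self.qc),
        )


def filter_flags(spots: pd.DataFrame) -> pd.DataFrame:
    """Keep only unflagged spots; raise if nothing survives."""
    out = spots[spots["flag"] == "ok"].copy()
    if out.empty:
        raise ValueError("all spots flagged: array unusable")
    out.attrs["n_flagged_removed"] = int(len(spots) - len(out))
    return out


def background_correct(spots: pd.DataFrame) -> pd.DataFrame:
    """Subtract the local background median from the signal median."""
    out = spots.copy()
    out["corrected"] = out["signal_median"] - out["bg_median"]
    return out


def detect_signal(spots: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call spots detected when signal exceeds two local backgrounds.

    The comparison is strict (signal > 2 × bg_median).  Returns the table
    with a boolean ``detected`` column and a per-array summary with columns
    ``n_spots, n_detected, detection_rate``.
    """
    out = spots.copy()
    out["detected"] = out["signal_median"] > 2.0 * out["bg_median"]
    rates = (
        out.groupby("array_id", sort=True)["detected"]
        .agg(n_detected="sum", n_spots="size")
        .assign(detection_rate=lambda d: d["n_detected"] / d["n_spots"])
        .reset_index()
    )
    return out, rates


def normalize_median(spots: pd.DataFrame) -> ExpressionMatrix:
    """Divide each array's corrected values by that array's median.

    Only positive background-corrected values enter the median and the
    output; everything else becomes NaN.  The per-array median of the
    included normalized values is 1 by construction.  A non-positive
    median marks a degenerate array and raises.
    """
    df = spots.copy()
    if "corrected" not in df.columns:
        raise ValueError("run background_correct first")
    if "detected" not in df.columns:
        df, _ = detect_signal(df)
    df["included"] = df["corrected"] > 0
    medians = {}
    for array_id, sub in df.groupby("array_id", sort=True):
        vals = sub.loc[sub["included"], "corrected"]
        if vals.empty:
            raise ValueError(f"array {array_id}: no positive corrected values")
        med = float(vals.median())
        if med <= 0:
            raise ValueError(f"array {array_id}: non-positive median {med}")
        medians[array_id] = med
    df["normalized"] = np.where(
        df["included"], df["corrected"] / df["array_id"].map(medians), np.nan
    )
    values = df.pivot(index="probe_id", columns="sample", values="normalized")
    detected = df.pivot(index="probe_id", columns="sample", values="detected")
    groups = df.drop_duplicates("sample").set_index("sample")["group"]
    values = values[groups.index]
    detected = detected[groups.index].eq(True)  # NaN (absent spot) -> False
    qc = {
        "array_medians": medians,
        "n_flagged_removed": spots.attrs.get("n_flagged_removed"),
    }
    return ExpressionMatrix(values=values, groups=groups, detected=detected, qc=qc)


def map_probes(
    matrix: ExpressionMatrix, probe_map: pd.DataFrame, min_score: float = 100.0
) -> ExpressionMatrix:
    """Assign each probe its best-scoring gene; drop sub-threshold probes.

    A probe with several candidate hits keeps the highest alignment score;
    score ties break lexicographically by gene symbol (with a warning).
    Probes whose best score falls below ``min_score`` are removed.
    """
    pm = probe_map[probe_map["probe_id"].isin(matrix.values.index)]
    best = (
        pm.sort_values(["probe_id", "align_score", "gene_symbol"],
                       ascending=[True, False, True])
        .drop_duplicates("probe_id", keep="first")
    )
    ties = (
        pm.merge(best[["probe_id", "align_score"]], on=["probe_id", "align_score"])
        .groupby("probe_id")["gene_symbol"]
        .nunique()
    )
    n_ties = int((ties > 1).sum())
    if n_ties:
        warnings.warn(
            f"{n_ties} probe(s) had tied best alignment scores; "
            "kept the lexicographically smaller gene symbol",
            stacklevel=2,
        )
    best = best[best["align_score"] >= min_score]
    kept = matrix.values.index.intersection(best["probe_id"])
    out = matrix.copy()
    out.values = matrix.values.loc[kept]
    out.detected = None if matrix.detected is None else matrix.detected.loc[kept]
    out.probe_gene = best.set_index("probe_id")["gene_symbol"].loc[kept]
    out.qc["n_probes_unmapped"] = int(len(matrix.values) - len(kept))
    return out


def collapse_genes(de_per_probe: pd.DataFrame, p_col: str = "p_value") -> pd.DataFrame:
    """Represent each gene by its smallest-p probe.

    Expects per-probe statistics (columns ``probe_id, gene_symbol`` plus
    ``p_col``); returns one row per gene — the minimum-p probe's row — with
    probe provenance retained in ``probe_id``.  NaN p-values lose to any
    finite p; genes with only NaN p keep their first probe.
    """
    if de_per_probe.empty:
        return de_per_probe.copy()
    key = de_per_probe[p_col].fillna(np.inf)
    order = de_per_probe.assign(_p=key).sort_values(
        ["gene_symbol", "_p", "probe_id"], kind="mergesort"
    )
    out = order.drop_duplicates("gene_symbol", keep="first").drop(columns="_p")
    return out.reset_index(drop=True)


def gene_detection(
    matrix: ExpressionMatrix, min_sample_fraction: float = 0.5
) -> pd.Series:
    """Gene-level detection: detected on >=1 probe in >= a fraction of samples.

    Requires :func:`map_probes` to have attached ``probe_gene``.  Returns a
    boolean Series indexed by gene symbol — the "genes with significant
    signal" universe used for selection percentages and as the enrichment
    background.
    """
    if matrix.probe_gene is None:
        raise ValueError("map probes to genes first")
    det = matrix.detected
    if det is None:
        raise ValueError("detection mask missing")
    by_gene = det.groupby(matrix.probe_gene).any()  # per gene × sample
    frac = by_gene.mean(axis=1)
    out = frac >= min_sample_fraction
    out.index.name = "gene_symbol"
    return out
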