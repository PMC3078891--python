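"""Cross-tissue concordance of differentially expressed genes.

Genes selected in both tissues are intersected by symbol and classified by
the signs of their two fold changes: up in both, down in both, or opposite.
Duplicate gene rows within one tissue's table (a typographical artifact in
published gene lists) collapse to a single record keeping the smaller p per
tissue, so counts refer to unique genes.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["intersect_de", "classify_direction"]

CLASSES = ("up_both", "down_both", "opposite")


def _dedupe(table: pd.DataFrame) -> pd.DataFrame:
    order = table.sort_values(["gene_symbol", "p_value"], kind="mergesort")
    return order.drop_duplicates("gene_symbol", keep="first")


def _classify(fc_a: float, fc_b: float) -> str:
    if fc_a == 0 or fc_b == 0:
        raise ValueError("zero log2FC cannot be direction-classified")
    if fc_a > 0 and fc_b > 0:
        return "up_both"
    if fc_a < 0 and fc_b < 0:
        return "down_both"
    return "opposite"


def intersect_de(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    names: tuple[str, str] = ("liver", "heart"),
) -> pd.DataFrame:
    """Overlap table of genes selected in both tissues.

    Inputs are gene-level DE tables with ``gene_symbol, p_value, log2fc``
    and (optionally) a ``selected`` flag — when present only selected rows
    participate.  Output columns: gene_symbol, log2fc_<a>, p_<a>,
    log2fc_<b>, p_<b>, class.
    """
    a, b = names
    ta, tb = de_a, de_b
    if "selected" in ta.columns:
        ta = ta[ta["selected"]]
    if "selected" in tb.columns:
        tb = tb[tb["selected"]]
    ta = _dedupe(ta)[["gene_symbol", "log2fc", "p_value"]]
    tb = _dedupe(tb)[["gene_symbol", "log2fc", "p_value"]]
    merged = ta.merge(tb, on="gene_symbol", suffixes=(f"_{a}", f"_{b}"))
    merged = merged.rename(
        columns={
            f"p_value_{a}": f"p_{a}",
            f"p_value_{b}": f"p_{b}",
        }
    )
    if merged.empty:
        merged["class"] = pd.Series(dtype=str)
        return merged.reset_index(drop=True)
    merged["class"] = [
        _classify(fa, fb)
        for fa, fb in zip(merged[f"log2fc_{a}"], merged[f"log2fc_{b}"])
    ]
    return merged.sort_values("gene_symbol").reset_index(drop=True)


def classify_direction(records: pd.DataFrame) -> dict[str, int]:
    """Counts per concordance class over an overlap table."""
    counts = records["class"].value_counts().to_dict()
    return {c: int(counts.get(c, 0)) for c in CLASSES}
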