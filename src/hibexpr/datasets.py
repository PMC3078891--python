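"""Bundled reference tables from the black-bear hibernation study.

Two small plain-text tables transcribed from the published study of heart
and liver gene expression in hibernating black bears (6 hibernating vs 5
summer-active animals; array data deposited as GEO series GSE27875):

* the RT-PCR validation panel — 32 genes tested by quantitative real-time
  PCR alongside their array results, and
* the list of differentially expressed genes shared between liver and
  heart, with the duplicated row present in the published table preserved
  as printed (deduplication is the analysis code's job).

P-values censored in print ("<0.001") are parsed to half the reporting
limit; only their position relative to the 0.05 confirmation gate matters.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["load_validation_panel", "load_shared_de_genes"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("hibexpr.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def _parse_p(s: pd.Series) -> pd.Series:
    def one(v: str) -> float:
        v = v.strip()
        if v.startswith("<"):
            return float(v[1:]) / 2.0
        return float(v)

    return s.map(one)


def load_validation_panel() -> pd.DataFrame:
    """RT-PCR vs array results for the 32-gene validation panel.

    Columns: gene_symbol, tissue, rtpcr_p, rtpcr_log2fc (NaN where the
    published value is n/a), array_p, array_log2fc.
    """
    df = _read("pcr_array_validation.tsv")
    out = pd.DataFrame(
        {
            "gene_symbol": df["gene_symbol"],
            "tissue": df["tissue"],
            "rtpcr_p": _parse_p(df["rtpcr_p"]),
            "rtpcr_log2fc": pd.to_numeric(
                df["rtpcr_log2fc"].replace("n/a", np.nan)
            ),
            "array_p": _parse_p(df["array_p"]),
            "array_log2fc": pd.to_numeric(df["array_log2fc"]),
        }
    )
    return out


def load_shared_de_genes() -> pd.DataFrame:
    """Genes differentially expressed in both liver and heart, as printed.

    Columns: category (fatty_acid_catabolism, protein_biosynthesis,
    amino_acid_catabolism, other), gene_symbol, p_liver, log2fc_liver,
    p_heart, log2fc_heart.  One gene appears twice, exactly as published.
    """
    df = _read("shared_de_genes.tsv")
    return pd.DataFrame(
        {
            "category": df["category"],
            "gene_symbol": df["gene_symbol"],
            "p_liver": _parse_p(df["p_liver"]),
            "log2fc_liver": pd.to_numeric(df["log2fc_liver"]),
            "p_heart": _parse_p(df["p_heart"]),
            "log2fc_heart": pd.to_numeric(df["log2fc_heart"]),
        }
    )
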