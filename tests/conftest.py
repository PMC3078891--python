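"""Shared fixtures: one small synthetic experiment reused across modules."""

import numpy as np
import pandas as pd
import pytest

import hibexpr as hx


@pytest.fixture(scope="session")
def small_design():
    return hx.SyntheticDesign(n_probes=500, n_genes=400, frac_de=0.1, seed=7)


@pytest.fixture(scope="session")
def small_experiment(small_design):
    spots, probe_map, truth = hx.generate_array_experiment(small_design)
    return spots, probe_map, truth


@pytest.fixture(scope="session")
def small_matrix(small_experiment):
    spots, probe_map, _ = small_experiment
    kept = hx.background_correct(hx.filter_flags(spots))
    kept, _ = hx.detect_signal(kept)
    matrix = hx.normalize_median(kept)
    return hx.map_probes(matrix, probe_map)


@pytest.fixture(scope="session")
def small_gene_level(small_matrix):
    """Gene-level DE table and gene-level value matrix."""
    table = hx.de_table(small_matrix)
    table["gene_symbol"] = table["probe_id"].map(small_matrix.probe_gene)
    gene_table = hx.collapse_genes(table)
    values = small_matrix.values.loc[gene_table["probe_id"]]
    values.index = pd.Index(gene_table["gene_symbol"], name="gene_symbol")
    return gene_table, values, small_matrix.groups


def make_spot_frame(signal, bg, flag=None, sample="s1", group="hibernating"):
    """Tiny single-array spot table for unit tests."""
    n = len(signal)
    return pd.DataFrame(
        {
            "array_id": f"a_{sample}",
            "sample": sample,
            "group": group,
            "probe_id": [f"P{i:03d}" for i in range(n)],
            "signal_median": np.asarray(signal, dtype=float),
            "bg_median": np.asarray(bg, dtype=float),
            "flag": ["ok"] * n if flag is None else flag,
        }
    )
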