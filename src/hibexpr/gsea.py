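"""Self-contained gene set enrichment analysis (running-sum statistic).

Genes are ranked by the signal-to-noise ratio between the two phenotype
classes, (mu_1 - mu_2) / (sigma_1 + sigma_2), each sigma optionally floored
at max(0.2*|mu|, 0.2) as in the reference implementation.  Walking the
ranked list, members of a gene set increment a running sum by
|metric|^p / N_R (N_R = sum of |metric|^p over members) and non-members
decrement it by 1/(N - N_hits); the enrichment score ES is the signed
maximum deviation from zero.  With p = 0 the walk telescopes back to 0 and
ES depends only on ranks.

Significance comes from phenotype permutations: for the 6-vs-5 design all
462 distinct relabellings are enumerated.  NES = ES / mean(|null ES| of the
same sign); the FDR for a set compares the fraction of null NES at least as
extreme (same sign) against the fraction of observed NES at least as
extreme, clipped to [0, 1].
"""

from __future__ import annotations

import warnings
from math import comb

import numpy as np
import pandas as pd

from .de import distinct_relabelings, _group_masks
from .preprocess import ExpressionMatrix

__all__ = [
    "signal_to_noise",
    "rank_genes",
    "enrichment_score",
    "permutation_significance",
    "plot_running_sum",
]


def signal_to_noise(
    values: pd.DataFrame,
    groups: pd.Series,
    sd_floor_policy: str = "gsea",
) -> pd.Series:
    """Per-gene signal-to-noise ratio (group 1 minus group 2).

    ``sd_floor_policy``: "gsea" floors each group's sd at
    max(0.2*|mean|, 0.2) (prevents division by zero and tames low-variance
    genes); "none" uses the raw sds.
    """
    if sd_floor_policy not in ("gsea", "none"):
        raise ValueError("sd_floor_policy must be 'gsea' or 'none'")
    m1, m2 = _group_masks(groups, values.columns)
    x = values.to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu1 = np.nanmean(x[:, m1], axis=1)
        mu2 = np.nanmean(x[:, m2], axis=1)
        s1 = np.nanstd(x[:, m1], axis=1, ddof=1)
        s2 = np.nanstd(x[:, m2], axis=1, ddof=1)
    if sd_floor_policy == "gsea":
        s1 = np.maximum(s1, np.maximum(0.2 * np.abs(mu1), 0.2))
        s2 = np.maximum(s2, np.maximum(0.2 * np.abs(mu2), 0.2))
    metric = (mu1 - mu2) / (s1 + s2)
    return pd.Series(metric, index=values.index, name="signal_to_noise")


def rank_genes(metric: pd.Series) -> pd.DataFrame:
    """Sort descending by metric, ties broken ascending by gene symbol."""
    df = metric.rename("metric").rename_axis("gene_symbol").reset_index()
    df = df.sort_values(
        ["metric", "gene_symbol"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def _es_from_arrays(
    metric_sorted: np.ndarray, is_hit: np.ndarray, weight: float
) -> tuple[float, np.ndarray]:
    n = len(metric_sorted)
    n_hits = int(is_hit.sum())
    if n_hits == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if n_hits == n:
        raise ValueError("gene set covers the whole ranked list (miss penalty undefined)")
    w = np.abs(metric_sorted) ** weight
    nr = w[is_hit].sum()
    if nr == 0:
        # all hit weights zero (possible when metric==0 and weight>0): fall
        # back to equal weights so the running sum remains defined
        w = np.ones(n)
        nr = float(n_hits)
    step = np.where(is_hit, w / nr, -1.0 / (n - n_hits))
    running = np.cumsum(step)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def enrichment_score(
    ranked: pd.DataFrame, gene_set: set[str], weight_exponent: float = 1.0
) -> tuple[float, np.ndarray]:
    """ES and the full running sum for one gene set on a ranked list.

    ``ranked`` is the output of :func:`rank_genes`.  ES is the running
    sum's signed maximum deviation from zero (first index on ties).
    """
    genes = ranked["gene_symbol"].to_numpy()
    metric = ranked["metric"].to_numpy(float)
    is_hit = np.isin(genes, list(gene_set))
    return _es_from_arrays(metric, is_hit, weight_exponent)


def permutation_significance(
    matrix: ExpressionMatrix | pd.DataFrame,
    groups: pd.Series | None = None,
    gene_sets: dict[str, set[str]] | None = None,
    weight_exponent: float = 1.0,
    sd_floor_policy: str = "gsea",
    max_exhaustive: int = 10_000,
    n_sample: int = 1_000,
    min_distinct: int = 50,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Per-set ES, NES and phenotype-permutation FDR.

    All distinct relabellings are enumerated when at most
    ``max_exhaustive`` (the 6-vs-5 design gives 462), otherwise sampled.
    If fewer than ``min_distinct`` distinct relabellings exist, FDR is
    unreliable: a warning is emitted and the exact permutation p-value is
    reported with FDR = NaN.
    """
    if isinstance(matrix, ExpressionMatrix):
        values, groups = matrix.values, matrix.groups
    else:
        values = matrix
        if groups is None:
            raise ValueError("groups required with a plain DataFrame")
    if not gene_sets:
        raise ValueError("at least one gene set required")
    keep = values.index[values.index.notna()]
    values = values.loc[keep]
    m1, _ = _group_masks(groups, values.columns)
    n_total, n_g1 = len(values.columns), int(m1.sum())
    genes = values.index.to_numpy()
    hit_masks = {name: np.isin(genes, list(gs)) for name, gs in gene_sets.items()}
    for name, mask in hit_masks.items():
        if mask.sum() == 0:
            raise ValueError(f"gene set {name!r} has no overlap with the matrix")

    def es_all(mask1: np.ndarray) -> dict[str, float]:
        met = _snr_array(values, mask1, sd_floor_policy)
        order = np.lexsort((genes, -met))
        met_sorted = met[order]
        out = {}
        for name, hmask in hit_masks.items():
            es, _ = _es_from_arrays(met_sorted, hmask[order], weight_exponent)
            out[name] = es
        return out

    observed = es_all(m1)

    n_distinct = comb(n_total, n_g1)
    perms: list[np.ndarray] = []
    if n_distinct <= max_exhaustive:
        for combo in distinct_relabelings(n_total, n_g1):
            mask = np.zeros(n_total, dtype=bool)
            mask[list(combo)] = True
            perms.append(mask)
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_sample):
            mask = np.zeros(n_total, dtype=bool)
            mask[rng.choice(n_total, size=n_g1, replace=False)] = True
            perms.append(mask)
    too_few = n_distinct < min_distinct
    if too_few:
        warnings.warn(
            f"only {n_distinct} distinct relabellings; reporting exact p, FDR undefined",
            stacklevel=2,
        )

    null = {name: np.empty(len(perms)) for name in gene_sets}
    for i, mask in enumerate(perms):
        for name, es in es_all(mask).items():
            null[name][i] = es

    # normalise: NES = ES / mean(|null ES| of matching sign)
    nes_obs, nes_null = {}, {}
    for name in gene_sets:
        ns = null[name]
        pos_mean = np.abs(ns[ns > 0]).mean() if (ns > 0).any() else np.nan
        neg_mean = np.abs(ns[ns < 0]).mean() if (ns < 0).any() else np.nan
        es = observed[name]
        denom = pos_mean if es >= 0 else neg_mean
        nes_obs[name] = es / denom if denom and np.isfinite(denom) else np.nan
        scale = np.where(ns >= 0, pos_mean, neg_mean)
        nes_null[name] = ns / scale

    all_null = np.concatenate([nes_null[name] for name in gene_sets])
    all_obs = np.array([nes_obs[name] for name in gene_sets])
    ranked_obs = rank_genes(signal_to_noise(values, groups, sd_floor_policy))
    ranked_genes = ranked_obs["gene_symbol"].to_numpy()
    rows = []
    for name, gs in gene_sets.items():
        es = observed[name]
        ns = null[name]
        nes = nes_obs[name]
        p_exact = float(np.mean(np.abs(ns) >= abs(es)))
        if too_few or not np.isfinite(nes):
            fdr = float("nan")
        elif nes >= 0:
            num = np.mean(all_null[np.isfinite(all_null)] >= nes) if np.isfinite(
                all_null
            ).any() else np.nan
            den = np.mean(all_obs[np.isfinite(all_obs)] >= nes)
            fdr = float(np.clip(num / den, 0.0, 1.0)) if den > 0 else float("nan")
        else:
            finite = all_null[np.isfinite(all_null)]
            num = np.mean(finite <= nes)
            den = np.mean(all_obs[np.isfinite(all_obs)] <= nes)
            fdr = float(np.clip(num / den, 0.0, 1.0)) if den > 0 else float("nan")
        hits = np.flatnonzero(np.isin(ranked_genes, list(gs))) + 1
        rows.append(
            {
                "gene_set": name,
                "size": int(hit_masks[name].sum()),
                "es": es,
                "nes": nes,
                "p_perm": p_exact,
                "fdr": fdr,
                "hit_ranks": tuple(int(h) for h in hits),
                "n_permutations": len(perms),
                "exhaustive": n_distinct <= max_exhaustive,
            }
        )
    return pd.DataFrame(rows).sort_values("p_perm", kind="mergesort").reset_index(drop=True)


def _snr_array(values: pd.DataFrame, mask1: np.ndarray, sd_floor_policy: str) -> np.ndarray:
    x = values.to_numpy(float)
    m2 = ~mask1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu1 = np.nanmean(x[:, mask1], axis=1)
        mu2 = np.nanmean(x[:, m2], axis=1)
        s1 = np.nanstd(x[:, mask1], axis=1, ddof=1)
        s2 = np.nanstd(x[:, m2], axis=1, ddof=1)
    if sd_floor_policy == "gsea":
        s1 = np.maximum(s1, np.maximum(0.2 * np.abs(mu1), 0.2))
        s2 = np.maximum(s2, np.maximum(0.2 * np.abs(mu2), 0.2))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        met = (mu1 - mu2) / (s1 + s2)
    return np.where(np.isfinite(met), met, 0.0)


def plot_running_sum(ranked: pd.DataFrame, gene_set: set[str], name: str,
                     weight_exponent: float = 1.0, path: str | None = None):
    """Running-sum plot for one gene set (enrichment profile + hit ticks)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    es, running = enrichment_score(ranked, gene_set, weight_exponent)
    hits = np.flatnonzero(ranked["gene_symbol"].isin(gene_set).to_numpy()) + 1
    fig, (ax1, ax2) = plt.subplots(
        2, 1, figsize=(7, 4), sharex=True, height_ratios=[3, 1]
    )
    ax1.plot(np.arange(1, len(running) + 1), running, color="tab:green")
    ax1.axhline(0.0, color="grey", lw=0.5)
    ax1.set_ylabel("running sum")
    ax1.set_title(f"{name}: ES = {es:.3f}")
    ax2.vlines(hits, 0, 1, color="black", lw=0.4)
    ax2.set_yticks([])
    ax2.set_xlabel("rank in ordered list")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
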