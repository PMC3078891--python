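"""Direction-stratified GO category enrichment with resampling FDR.

Selected genes of one direction (up or down) are tested per term against a
declared background (the genes with significant signal and at least one
annotation in the analysed namespace).  With N background genes of which K
changed, and a term covering n background genes of which k changed:

* enrichment ratio = (k/n) / (K/N) — observed over expected proportion,
* one-sided Fisher exact p = upper-tail hypergeometric P(X >= k),
* terms with fewer than ``min_changed`` changed genes are omitted,
* a parent whose changed-gene set equals a significant child's is pruned
  (the more specific child represents the signal), transitively up chains,
* per-term FDR comes from resampling K genes at random from the background
  and counting how often resampled terms reach each observed p (step-up
  over the observed p ranks, clipped to [0, 1], monotone in p).

Annotations obey the true-path rule: a gene annotated to a term is counted
in every ancestor, via :func:`propagate_annotations`.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "validate_dag",
    "term_ancestors",
    "propagate_annotations",
    "enrichment_ratio",
    "fisher_one_sided",
    "enrich_terms",
    "apply_filters",
    "prune_hierarchy",
    "resampling_fdr",
]


def validate_dag(dag: nx.MultiDiGraph | nx.DiGraph) -> None:
    """Check acyclicity and that every non-root term reaches a root."""
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("term graph contains a cycle")
    roots = {n for n in dag.nodes if dag.out_degree(n) == 0}
    if not roots:
        raise ValueError("term graph has no root")
    for n in dag.nodes:
        if n in roots:
            continue
        if not nx.descendants(dag, n) & roots:
            raise ValueError(f"term {n} does not reach a namespace root")


def term_ancestors(dag, term: str) -> set[str]:
    """All ancestors of ``term`` following child -> parent (is_a) edges."""
    return set(nx.descendants(dag, term))


def propagate_annotations(dag, direct: pd.DataFrame) -> dict[str, frozenset[str]]:
    """True-path propagation: annotate each gene to all ancestor terms.

    ``direct`` has columns ``gene_symbol, term``.  Unknown term ids raise
    with the offending ids listed.  Idempotent: propagating an already
    propagated table changes nothing.
    """
    unknown = sorted(set(direct["term"]) - set(dag.nodes))
    if unknown:
        raise KeyError(f"unknown term id(s): {unknown}")
    anc_cache = {t: term_ancestors(dag, t) | {t} for t in set(direct["term"])}
    out: dict[str, set[str]] = {}
    for gene, term in zip(direct["gene_symbol"], direct["term"]):
        out.setdefault(gene, set()).update(anc_cache[term])
    return {g: frozenset(ts) for g, ts in out.items()}


def enrichment_ratio(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N): changed fraction in the category over the background."""
    if n == 0 or K == 0 or N == 0:
        return float("nan")
    return (k / n) / (K / N)


def fisher_one_sided(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric P(X >= k) — one-sided Fisher exact test.

    Margins: N background genes, K changed, n in the category, k changed
    in the category.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K and n - k <= N - K):
        raise ValueError(f"impossible 2x2 margins: k={k} n={n} K={K} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_terms(
    changed_genes: set[str],
    background_genes: set[str],
    annotations: dict[str, frozenset[str]],
    dag=None,
    direction: str = "up",
    namespace: str | None = None,
    min_changed: int = 5,
) -> pd.DataFrame:
    """Per-term enrichment table for one direction of change.

    ``annotations`` maps gene -> propagated term set.  The background is
    restricted to genes with at least one annotation (in ``namespace`` if
    given); changed genes outside the background are ignored.  Terms with
    fewer than ``min_changed`` changed genes are omitted before testing.
    """

    def in_ns(term: str) -> bool:
        if namespace is None or dag is None:
            return True
        return dag.nodes[term].get("namespace") == namespace

    bg = {
        g
        for g in background_genes
        if g in annotations and any(in_ns(t) for t in annotations[g])
    }
    changed = changed_genes & bg
    N, K = len(bg), len(changed)
    term_members: dict[str, set[str]] = {}
    term_changed: dict[str, set[str]] = {}
    for g in bg:
        for t in annotations[g]:
            if not in_ns(t):
                continue
            term_members.setdefault(t, set()).add(g)
            if g in changed:
                term_changed.setdefault(t, set()).add(g)
    rows = []
    for t, members in sorted(term_members.items()):
        k = len(term_changed.get(t, ()))
        n = len(members)
        rows.append(
            {
                "term": t,
                "name": dag.nodes[t].get("name", t) if dag is not None else t,
                "direction": direction,
                "n_on_array": n,
                "k_changed": k,
                "enrichment": enrichment_ratio(k, n, K, N),
                "p_value": fisher_one_sided(k, n, K, N),
                "members": tuple(sorted(term_changed.get(t, ()))),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term", "name", "direction", "n_on_array", "k_changed",
            "enrichment", "p_value", "members",
        ],
    )
    out.attrs["N"] = N
    out.attrs["K"] = K
    out = apply_filters(out, min_changed=min_changed)
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def apply_filters(results: pd.DataFrame, min_changed: int = 5) -> pd.DataFrame:
    """Omit terms with fewer than ``min_changed`` changed genes (k < 5 by default)."""
    out = results[results["k_changed"] >= min_changed].copy()
    if out.empty and len(results):
        warnings.warn("all terms fell below the minimum changed-gene count", stacklevel=2)
    out.attrs.update(results.attrs)
    return out


def prune_hierarchy(
    results: pd.DataFrame, dag, alpha: float = 0.05, sig_col: str = "p_value"
) -> pd.DataFrame:
    """Drop significant parents whose member set equals a significant child's.

    When a parent and a more specific descendant are both significant with
    the identical changed-gene set, only the descendant is kept; chains of
    identical sets collapse to the deepest term.  Non-significant terms are
    untouched.
    """
    sig = results[results[sig_col] < alpha]
    members = dict(zip(sig["term"], sig["members"]))
    drop = set()
    for t in members:
        for anc in term_ancestors(dag, t):
            if anc in members and set(members[anc]) == set(members[t]):
                drop.add(anc)
    out = results[~results["term"].isin(drop)].copy()
    out.attrs.update(results.attrs)
    out.attrs["n_pruned"] = len(drop)
    return out


def resampling_fdr(
    results: pd.DataFrame,
    background_genes: set[str],
    annotations: dict[str, frozenset[str]],
    n_changed: int | None = None,
    n_resamples: int = 1000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Per-term FDR by resampling the changed-gene count from the background.

    Draws ``n_changed`` genes (default: the observed K) uniformly from the
    background ``n_resamples`` times, recomputes every tested term's Fisher
    p, and sets term i's FDR (terms ranked by observed p, rank r_i) to
    mean over resamples of #\\{terms with p <= p_i\\} / r_i, made monotone
    non-decreasing in p by a step-up pass and clipped to [0, 1].
    """
    if results.empty:
        out = results.copy()
        out["fdr"] = pd.Series(dtype=float)
        return out
    bg = sorted(g for g in background_genes if g in annotations)
    G = len(bg)
    terms = list(results["term"])
    # membership matrix over the tested terms only
    gene_idx = {g: i for i, g in enumerate(bg)}
    M = np.zeros((len(terms), G), dtype=bool)
    n_on_array = results["n_on_array"].to_numpy()
    for ti, t in enumerate(terms):
        for g in bg:
            if t in annotations[g]:
                M[ti, gene_idx[g]] = True
    K = int(n_changed if n_changed is not None else results.attrs.get("K", 0))
    if K <= 0:
        raise ValueError("number of changed genes to resample must be positive")
    rng = np.random.default_rng(seed)
    draws = np.zeros((n_resamples, G), dtype=bool)
    for r in range(n_resamples):
        draws[r, rng.choice(G, size=K, replace=False)] = True
    k_mat = draws.astype(np.int32) @ M.T.astype(np.int32)  # resamples × terms
    # vectorised one-sided Fisher p for every (resample, term)
    p_mat = stats.hypergeom.sf(k_mat - 1, G, K, n_on_array[None, :])
    obs_p = results["p_value"].to_numpy()
    order = np.argsort(obs_p, kind="mergesort")
    fdr = np.full(len(terms), np.nan)
    ranked_p = obs_p[order]
    # mean count of resampled term p-values at or below each observed p
    exceed = (p_mat[:, :, None] <= ranked_p[None, None, :]).sum(axis=1).mean(axis=0)
    raw = exceed / (np.arange(len(ranked_p)) + 1)
    stepped = np.minimum.accumulate(raw[::-1])[::-1]  # step-up: monotone in p
    fdr[order] = np.clip(stepped, 0.0, 1.0)
    out = results.copy()
    out["fdr"] = fdr
    out.attrs.update(results.attrs)
    return out
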