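"""Annotation propagation, Fisher enrichment, pruning and resampling FDR."""

from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import hibexpr as hx
from hibexpr import go as go_mod


def _chain_dag():
    dag = nx.MultiDiGraph()
    for t in ("root", "mid", "leaf"):
        dag.add_node(t, name=t, namespace="biological_process")
    dag.add_edge("mid", "root", key="is_a")
    dag.add_edge("leaf", "mid", key="is_a")
    return dag


class TestPropagation:
    def test_child_annotation_counts_in_parent(self):
        dag = _chain_dag()
        direct = pd.DataFrame({"gene_symbol": ["g1"], "term": ["leaf"]})
        prop = hx.propagate_annotations(dag, direct)
        assert prop["g1"] == {"leaf", "mid", "root"}

    def test_root_annotation_unchanged(self):
        dag = _chain_dag()
        direct = pd.DataFrame({"gene_symbol": ["g1"], "term": ["root"]})
        assert hx.propagate_annotations(dag, direct)["g1"] == {"root"}

    def test_unknown_term_raises_with_offenders(self):
        dag = _chain_dag()
        direct = pd.DataFrame({"gene_symbol": ["g1"], "term": ["nope"]})
        with pytest.raises(KeyError, match="nope"):
            hx.propagate_annotations(dag, direct)

    def test_matches_transitive_closure_on_random_dag(self):
        rng = np.random.default_rng(4)
        dag = nx.MultiDiGraph()
        terms = [f"T{i}" for i in range(15)]
        for t in terms:
            dag.add_node(t, name=t, namespace="biological_process")
        for i, t in enumerate(terms[1:], start=1):
            for parent in rng.choice(i, size=min(i, 2), replace=False):
                dag.add_edge(t, terms[parent], key="is_a")
        genes = [f"g{i}" for i in range(30)]
        direct = pd.DataFrame(
            {
                "gene_symbol": rng.choice(genes, 60),
                "term": rng.choice(terms, 60),
            }
        )
        prop = hx.propagate_annotations(dag, direct)
        closure = nx.transitive_closure(nx.DiGraph(dag))
        for gene, sub in direct.groupby("gene_symbol"):
            expected = set(sub["term"])
            for t in sub["term"]:
                expected |= set(closure.successors(t))
            assert prop[gene] == expected

    def test_propagation_idempotent(self):
        dag = _chain_dag()
        direct = pd.DataFrame({"gene_symbol": ["g1"], "term": ["leaf"]})
        once = hx.propagate_annotations(dag, direct)
        again_direct = pd.DataFrame(
            [(g, t) for g, ts in once.items() for t in ts],
            columns=["gene_symbol", "term"],
        )
        assert hx.propagate_annotations(dag, again_direct) == once


class TestFisherAndRatio:
    @pytest.mark.parametrize(
        "k,n,K,N,expected",
        [(5, 10, 100, 1000, 5.0), (1, 10, 100, 1000, 1.0), (4, 4, 10, 10, 1.0)],
    )
    def test_enrichment_ratio_arithmetic(self, k, n, K, N, expected):
        assert hx.enrichment_ratio(k, n, K, N) == pytest.approx(expected)

    def test_ratio_above_one_iff_proportion_exceeds_background(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            N = int(rng.integers(10, 60))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(max(0, n + K - N), min(n, K) + 1))
            assert (hx.enrichment_ratio(k, n, K, N) > 1) == (k / n > K / N)

    def test_fisher_exact_small_case(self):
        # all four sampled genes changed: p = C(5,4)/C(10,4) = 5/210
        assert hx.fisher_one_sided(4, 4, 5, 10) == pytest.approx(5 / 210, abs=1e-12)

    def test_fisher_k_zero_is_one(self):
        assert hx.fisher_one_sided(0, 4, 5, 10) == pytest.approx(1.0, abs=1e-12)

    def test_fisher_matches_enumeration_on_random_margins(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            N = int(rng.integers(2, 61))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(max(0, n + K - N), min(n, K) + 1))
            total = comb(N, n)
            tail = sum(
                comb(K, i) * comb(N - K, n - i)
                for i in range(k, min(n, K) + 1)
            )
            assert hx.fisher_one_sided(k, n, K, N) == pytest.approx(
                tail / total, abs=1e-12
            )

    def test_impossible_margins_raise(self):
        with pytest.raises(ValueError):
            hx.fisher_one_sided(6, 5, 10, 20)


class TestFilters:
    def _results(self, ks):
        return pd.DataFrame(
            {
                "term": [f"T{i}" for i in range(len(ks))],
                "k_changed": ks,
                "p_value": [0.001] * len(ks),
                "members": [tuple(f"g{j}" for j in range(k)) for k in ks],
            }
        )

    def test_fewer_than_five_omitted_five_retained(self):
        out = hx.apply_filters(self._results([4, 5, 6]))
        assert list(out["k_changed"]) == [5, 6]

    def test_all_below_threshold_warns_and_empties(self):
        with pytest.warns(UserWarning, match="minimum changed-gene"):
            out = hx.apply_filters(self._results([1, 2]))
        assert out.empty


class TestPruning:
    def _results(self, rows):
        return pd.DataFrame(
            rows, columns=["term", "p_value", "members"]
        ).assign(k_changed=lambda d: d["members"].map(len))

    def test_parent_with_identical_member_set_removed(self):
        dag = _chain_dag()
        res = self._results(
            [("mid", 0.001, ("g1", "g2")), ("leaf", 0.001, ("g1", "g2"))]
        )
        out = hx.prune_hierarchy(res, dag)
        assert list(out["term"]) == ["leaf"]

    def test_parent_with_larger_member_set_retained(self):
        dag = _chain_dag()
        res = self._results(
            [("mid", 0.001, ("g1", "g2", "g3")), ("leaf", 0.001, ("g1", "g2"))]
        )
        out = hx.prune_hierarchy(res, dag)
        assert set(out["term"]) == {"mid", "leaf"}

    def test_chain_of_identical_sets_keeps_only_leaf(self):
        dag = _chain_dag()
        res = self._results(
            [
                ("root", 0.001, ("g1",)),
                ("mid", 0.001, ("g1",)),
                ("leaf", 0.001, ("g1",)),
            ]
        )
        out = hx.prune_hierarchy(res, dag)
        assert list(out["term"]) == ["leaf"]

    def test_non_significant_parent_untouched(self):
        dag = _chain_dag()
        res = self._results(
            [("mid", 0.5, ("g1",)), ("leaf", 0.001, ("g1",))]
        )
        out = hx.prune_hierarchy(res, dag)
        assert set(out["term"]) == {"mid", "leaf"}


@pytest.fixture(scope="module")
def synthetic_enrichment():
    d = hx.SyntheticDesign(n_probes=900, n_genes=800, frac_de=0.12, seed=9)
    _, _, truth = hx.generate_array_experiment(d)
    ann = hx.generate_annotations(truth, n_terms=10, enriched_terms=2, seed=10)
    prop = hx.propagate_annotations(ann.dag, ann.annotations)
    background = set(truth.genes["gene_symbol"]) & set(prop)
    up = set(truth.genes.loc[truth.genes.direction == "up", "gene_symbol"])
    res = hx.enrich_terms(
        up & background, background, prop, dag=ann.dag, direction="up"
    )
    res = hx.resampling_fdr(res, background, prop, n_resamples=400, seed=3)
    return ann, res


class TestResamplingFdr:

    def test_planted_term_has_low_fdr(self, synthetic_enrichment):
        ann, res = synthetic_enrichment
        planted_up = ann.enriched.loc[ann.enriched.direction == "up", "term"]
        table = res.set_index("term")
        assert (table.loc[planted_up, "fdr"] < 0.05).all()

    def test_fdr_monotone_in_observed_p(self, synthetic_enrichment):
        _, res = synthetic_enrichment
        ordered = res.sort_values("p_value")
        assert (ordered["fdr"].diff().dropna() >= -1e-12).all()

    def test_unstructured_selection_is_calibrated(self):
        """Random 'changed' sets produce no small FDR values."""
        d = hx.SyntheticDesign(n_probes=700, n_genes=600, frac_de=0.0, seed=12)
        _, _, truth = hx.generate_array_experiment(d)
        ann = hx.generate_annotations(truth, n_terms=10, enriched_terms=0, seed=13)
        prop = hx.propagate_annotations(ann.dag, ann.annotations)
        background = set(truth.genes["gene_symbol"]) & set(prop)
        rng = np.random.default_rng(14)
        mins = []
        for rep in range(5):
            changed = set(rng.choice(sorted(background), size=40, replace=False))
            res = hx.enrich_terms(
                changed, background, prop, dag=ann.dag, direction="up",
                min_changed=1,
            )
            res = hx.resampling_fdr(res, background, prop, n_resamples=300,
                                    seed=20 + rep)
            mins.append(res["fdr"].min())
        assert np.median(mins) > 0.05


def test_direction_stratified_runs_partition_changed_genes(small_experiment):
    _, _, truth = hx.generate_array_experiment(
        hx.SyntheticDesign(n_probes=500, n_genes=400, frac_de=0.15, seed=21)
    )
    ann = hx.generate_annotations(truth, n_terms=8, enriched_terms=2, seed=22)
    prop = hx.propagate_annotations(ann.dag, ann.annotations)
    background = set(truth.genes["gene_symbol"]) & set(prop)
    up = set(truth.genes.loc[truth.genes.direction == "up", "gene_symbol"]) & background
    down = set(truth.genes.loc[truth.genes.direction == "down", "gene_symbol"]) & background
    res_up = hx.enrich_terms(up, background, prop, dag=ann.dag, direction="up",
                             min_changed=1)
    res_down = hx.enrich_terms(down, background, prop, dag=ann.dag,
                               direction="down", min_changed=1)
    for t in set(res_up["term"]) & set(res_down["term"]):
        mu = set(res_up.set_index("term").loc[t, "members"])
        md = set(res_down.set_index("term").loc[t, "members"])
        assert not (mu & md)
        if mu and md:
            assert mu != md


def test_obo_round_trip(tmp_path, small_experiment):
    from hibexpr import io as io_mod

    _, _, truth = small_experiment
    ann = hx.generate_annotations(truth, n_terms=6, enriched_terms=1, seed=1)
    path = tmp_path / "terms.obo"
    io_mod.write_obo(ann.dag, path)
    back = io_mod.read_obo(path)
    assert set(back.nodes) == set(ann.dag.nodes)
    go_mod.validate_dag(back)
    assert go_mod.term_ancestors(back, "GO:2000000") == go_mod.term_ancestors(
        ann.dag, "GO:2000000"
    )


from hypothesis import given, settings, strategies as st


@st.composite
def _margins(draw):
    N = draw(st.integers(2, 60))
    K = draw(st.integers(0, N))
    n = draw(st.integers(0, N))
    k = draw(st.integers(max(0, n + K - N), min(n, K)))
    return k, n, K, N


@given(_margins())
@settings(max_examples=200, deadline=None, derandomize=True)
def test_fisher_tail_property(margins):
    """P(X >= k) from the implementation equals the exact integer tail sum."""
    k, n, K, N = margins
    total = comb(N, n)
    tail = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    assert hx.fisher_one_sided(k, n, K, N) == pytest.approx(tail / total, abs=1e-12)
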