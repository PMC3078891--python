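"""Signal-to-noise ranking, running-sum enrichment score, permutation nulls."""

import numpy as np
import pandas as pd
import pytest

import hibexpr as hx
from hibexpr import gsea as gsea_mod


def _matrix(data, n_hib, n_sum):
    samples = [f"h{i}" for i in range(n_hib)] + [f"s{i}" for i in range(n_sum)]
    values = pd.DataFrame(
        data, columns=samples,
        index=pd.Index([f"g{i}" for i in range(len(data))], name="gene_symbol"),
    )
    groups = pd.Series(["hibernating"] * n_hib + ["summer"] * n_sum, index=samples)
    return values, groups


def brute_force_es(metrics, genes, gene_set, p):
    """Independent step-by-step walk of the running sum."""
    order = sorted(range(len(genes)), key=lambda i: (-metrics[i], genes[i]))
    hits = [i for i in order if genes[i] in gene_set]
    nr = sum(abs(metrics[i]) ** p for i in hits)
    n, nh = len(genes), len(hits)
    running, best, s = [], 0.0, 0.0
    for i in order:
        if genes[i] in gene_set:
            s += (abs(metrics[i]) ** p) / nr if nr else 1.0 / nh
        else:
            s -= 1.0 / (n - nh)
        running.append(s)
        if abs(s) > abs(best):
            best = s
    return best, running


class TestSignalToNoise:
    def test_equal_means_give_zero(self):
        values, groups = _matrix([[1, 1, 1, 1, 1, 1]], 3, 3)
        assert hx.signal_to_noise(values, groups).iloc[0] == 0.0

    def test_unfloored_arithmetic_example(self):
        rngless = [[3.5, 2.5, 3.0, 1.5, 0.5, 1.0]]  # means 3,1; sds 0.5,0.5
        values, groups = _matrix(rngless, 3, 3)
        snr = hx.signal_to_noise(values, groups, sd_floor_policy="none")
        assert snr.iloc[0] == pytest.approx(2.0)

    def test_floor_policy_caps_low_variance(self):
        values, groups = _matrix([[3.0, 3.0, 3.001, 1.0, 1.0, 1.001]], 3, 3)
        floored = hx.signal_to_noise(values, groups).iloc[0]
        assert floored == pytest.approx((3.0 - 1.0) / (0.6 + 0.2), rel=1e-2)

    def test_swapping_labels_negates_metric(self):
        rng = np.random.default_rng(1)
        values, groups = _matrix(rng.uniform(1, 5, (10, 6)), 3, 3)
        flipped = groups.map(
            {"hibernating": "summer", "summer": "hibernating"}
        )
        a = hx.signal_to_noise(values, groups)
        b = hx.signal_to_noise(values, flipped)
        assert np.allclose(a, -b)


class TestRanking:
    def test_ranks_are_a_permutation_and_tie_break_deterministic(self):
        metric = pd.Series(
            {"b": 1.0, "a": 1.0, "c": 2.0}, name="metric"
        ).rename_axis("gene_symbol")
        ranked = hx.rank_genes(metric)
        assert list(ranked["gene_symbol"]) == ["c", "a", "b"]
        assert list(ranked["rank"]) == [1, 2, 3]


class TestEnrichmentScore:
    def test_single_member_at_top_unweighted(self):
        ranked = pd.DataFrame(
            {
                "gene_symbol": ["g1", "g2", "g3", "g4"],
                "metric": [3.0, 2.0, 1.0, 0.5],
            }
        )
        es, running = hx.enrichment_score(ranked, {"g1"}, weight_exponent=0.0)
        assert es == pytest.approx(1.0)
        assert running[-1] == pytest.approx(0.0, abs=1e-12)

    def test_complement_of_bottom_gene_unweighted(self):
        """All genes but the bottom one: the walk climbs to its closed-form
        maximum (N−1 equal hit increments summing to 1) then falls to 0."""
        genes = [f"g{i}" for i in range(10)]
        metrics = list(np.linspace(5, 1, 10))
        ranked = pd.DataFrame({"gene_symbol": genes, "metric": metrics})
        es, running = hx.enrichment_score(ranked, set(genes[:-1]), weight_exponent=0.0)
        oracle_es, oracle_running = brute_force_es(
            metrics, genes, set(genes[:-1]), 0.0
        )
        assert es == pytest.approx(oracle_es, abs=1e-12)
        assert es == pytest.approx(1.0, abs=1e-12)  # closed form: (N−1)·1/(N−1)

    def test_matches_brute_force_walk_on_random_lists(self):
        rng = np.random.default_rng(7)
        for trial in range(50):
            n = 50
            genes = [f"g{i}" for i in range(n)]
            metrics = rng.normal(size=n)
            size = int(rng.integers(3, 20))
            gene_set = set(rng.choice(genes, size=size, replace=False))
            p = float(rng.choice([0.0, 1.0, 1.5]))
            ranked = hx.rank_genes(
                pd.Series(metrics, index=genes).rename_axis("gene_symbol")
            )
            es, running = hx.enrichment_score(ranked, gene_set, weight_exponent=p)
            oracle_es, oracle_running = brute_force_es(
                metrics, genes, gene_set, p
            )
            assert es == pytest.approx(oracle_es, abs=1e-12)
            assert np.allclose(running, oracle_running, atol=1e-12)

    def test_running_sum_telescopes_to_zero_unweighted(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(40)]
        ranked = hx.rank_genes(
            pd.Series(rng.normal(size=40), index=genes).rename_axis("gene_symbol")
        )
        _, running = hx.enrichment_score(
            ranked, set(rng.choice(genes, 10, replace=False)), weight_exponent=0.0
        )
        assert abs(running[-1]) < 1e-12

    def test_unweighted_es_invariant_to_monotone_metric_transform(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(30)]
        metric = pd.Series(rng.uniform(1, 2, 30), index=genes).rename_axis(
            "gene_symbol"
        )
        gene_set = set(rng.choice(genes, 8, replace=False))
        es1, _ = hx.enrichment_score(hx.rank_genes(metric), gene_set, 0.0)
        es2, _ = hx.enrichment_score(hx.rank_genes(metric**3), gene_set, 0.0)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_empty_intersection_rejected(self):
        ranked = pd.DataFrame({"gene_symbol": ["g1"], "metric": [1.0]})
        with pytest.raises(ValueError, match="overlap"):
            hx.enrichment_score(ranked, {"zz"})

    def test_full_universe_set_rejected(self):
        ranked = pd.DataFrame(
            {"gene_symbol": ["g1", "g2"], "metric": [1.0, 0.5]}
        )
        with pytest.raises(ValueError, match="whole ranked list"):
            hx.enrichment_score(ranked, {"g1", "g2"})


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(11)
    n_genes = 300
    values, groups = _matrix(2.0 ** rng.normal(0, 0.4, (n_genes, 11)), 6, 5)
    # plant 25 strongly up genes and make a set of them
    up = [f"g{i}" for i in range(25)]
    values.loc[up, groups == "hibernating"] *= 2 ** 1.5
    sets = {
        "planted_up": set(up),
        "random_a": set(rng.choice(values.index, 25, replace=False)),
        "random_b": set(rng.choice(values.index, 25, replace=False)),
    }
    return hx.permutation_significance(
        values, groups, gene_sets=sets, seed=0
    ).set_index("gene_set")


class TestPermutationSignificance:

    def test_exhaustive_enumeration_of_six_vs_five(self, planted):
        assert (planted["n_permutations"] == 462).all()
        assert planted["exhaustive"].all()

    def test_planted_top_de_set_is_significant(self, planted):
        row = planted.loc["planted_up"]
        assert row["es"] > 0
        assert row["fdr"] < 0.05

    def test_es_bounds_and_hit_ranks(self, planted):
        assert (planted["es"].abs() <= 1.0).all()
        for _, row in planted.iterrows():
            assert all(1 <= r <= 300 for r in row["hit_ranks"])
            assert len(row["hit_ranks"]) == row["size"]

    def test_too_few_permutations_warns_and_reports_exact_p(self):
        rng = np.random.default_rng(12)
        values, groups = _matrix(rng.uniform(1, 3, (30, 7)), 4, 3)
        with pytest.warns(UserWarning, match="distinct relabellings"):
            res = hx.permutation_significance(
                values, groups, gene_sets={"s": set(values.index[:6])}, seed=0
            )
        assert res["fdr"].isna().all()
        assert ((res["p_perm"] >= 0) & (res["p_perm"] <= 1)).all()


def test_label_independent_data_is_calibrated():
    """On null data no set reaches small exact permutation p in most seeds."""
    flags = 0
    for seed in range(6):
        rng = np.random.default_rng(100 + seed)
        samples = [f"h{i}" for i in range(6)] + [f"s{i}" for i in range(5)]
        values = pd.DataFrame(
            2.0 ** rng.normal(0, 0.5, (200, 11)),
            index=pd.Index([f"g{i}" for i in range(200)], name="gene_symbol"),
            columns=samples,
        )
        groups = pd.Series(["hibernating"] * 6 + ["summer"] * 5, index=samples)
        sets = {
            f"s{j}": set(rng.choice(values.index, 30, replace=False))
            for j in range(5)
        }
        res = hx.permutation_significance(values, groups, gene_sets=sets, seed=seed)
        flags += int((res["fdr"] < 0.05).any())
    assert flags <= 1
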