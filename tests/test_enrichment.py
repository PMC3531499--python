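"""Hypergeometric tests, BH, preranked GSEA and the enrichment map."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import regutarget as rt
from regutarget.enrichment import _es_from_positions, _hypergeom_sf_exact


# ------------------------------------------------------------- hypergeometric

def test_hypergeom_worked_case():
    universe = [f"g{i}" for i in range(20)]
    set_a, set_b = universe[:5], universe[:3] + universe[5:7]  # overlap 3
    res = rt.hypergeom_overlap(set_a, set_b, universe)
    assert (res.k, res.K, res.n, res.N) == (3, 5, 5, 20)
    assert res.p_upper == pytest.approx(1126 / 15504, rel=1e-12)
    assert res.odds_ratio == pytest.approx((3 * 13) / (2 * 2))


def test_hypergeom_closed_form_case():
    universe = [f"g{i}" for i in range(10)]
    res = rt.hypergeom_overlap(universe[:2], universe[:2], universe)
    assert res.p_upper == pytest.approx(1 / 45, rel=1e-12)


def test_hypergeom_zero_overlap_p_is_one():
    universe = [f"g{i}" for i in range(10)]
    res = rt.hypergeom_overlap(universe[:3], universe[3:6], universe)
    assert res.p_upper == 1.0
    assert res.haldane  # a = 0 cell triggers the continuity correction


def test_hypergeom_membership_validation():
    with pytest.raises(ValueError, match="outside the universe"):
        rt.hypergeom_overlap(["z"], ["a"], ["a", "b"])


def test_hypergeom_matches_draw_enumeration_oracle():
    """p_upper equals brute-force enumeration over every possible draw."""
    universe = list(range(10))
    for K in (2, 4, 7):
        set_a = [f"g{i}" for i in universe[:K]]
        for n in (1, 3, 5):
            hits = 0
            total = 0
            k_obs = None
            for draw in itertools.combinations(universe, n):
                total += 1
            for k in range(max(0, K + n - 10), min(K, n) + 1):
                count = sum(
                    1
                    for draw in itertools.combinations(universe, n)
                    if len(set(draw) & set(universe[:K])) >= k
                )
                set_b = [f"g{i}" for i in universe[:k]] + [
                    f"g{i}" for i in universe[K : K + n - k]
                ]
                res = rt.hypergeom_overlap(set_a, set_b, [f"g{i}" for i in universe])
                assert res.p_upper == pytest.approx(count / total, rel=1e-12)


def test_hypergeom_log_precision_small_universes():
    """Exact log-p agreement with an independently coded factorial oracle."""

    def oracle(k, K, n, N):
        total = math.factorial(N) // (math.factorial(n) * math.factorial(N - n))
        acc = 0
        for j in range(k, min(K, n) + 1):
            a = math.factorial(K) // (math.factorial(j) * math.factorial(K - j))
            b = math.factorial(N - K) // (
                math.factorial(n - j) * math.factorial(N - K - n + j)
            )
            acc += a * b
        return acc / total

    rng = np.random.default_rng(3)
    for _ in range(300):
        N = int(rng.integers(2, 26))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(0, N + 1))
        k = int(rng.integers(max(0, K + n - N), min(K, n) + 1))
        p = float(_hypergeom_sf_exact(k, K, n, N))
        assert abs(math.log(p) - math.log(oracle(k, K, n, N))) < 1e-12


def test_hypergeom_agrees_with_scipy():
    rng = np.random.default_rng(4)
    for _ in range(100):
        N = int(rng.integers(50, 5_000))
        K = int(rng.integers(1, N))
        n = int(rng.integers(1, N))
        k = int(rng.integers(max(0, K + n - N), min(K, n) + 1))
        p = float(_hypergeom_sf_exact(k, K, n, N))
        assert p == pytest.approx(stats.hypergeom.sf(k - 1, N, K, n), rel=1e-8)


# ------------------------------------------------------------------------- BH

def test_bh_step_up_by_hand():
    assert np.allclose(rt.adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert rt.adjust_bh([1.0]) == pytest.approx([1.0])


def test_bh_dominates_input_and_validates():
    rng = np.random.default_rng(5)
    p = rng.random(200)
    q = rt.adjust_bh(p)
    assert (q >= p - 1e-15).all() and (q <= 1.0).all()
    with pytest.raises(ValueError):
        rt.adjust_bh([0.5, 1.5])


# ---------------------------------------------------------------------- GSEA

def ranked_series(scores, prefix="g"):
    return pd.Series(scores, index=[f"{prefix}{i}" for i in range(len(scores))])


def brute_force_es(ranked: pd.Series, gene_set, weight=1.0):
    """Plain running-sum recomputation (the oracle)."""
    genes = list(ranked.index)
    scores = ranked.to_numpy()
    hits = [g in set(gene_set) for g in genes]
    n, n_h = len(genes), sum(hits)
    n_r = sum(abs(s) ** weight for s, h in zip(scores, hits) if h)
    run, best = 0.0, 0.0
    for s, h in zip(scores, hits):
        # zero-weight hits (all hit scores exactly 0) contribute no gain
        run += ((abs(s) ** weight / n_r) if n_r > 0 else 0.0) if h else -1.0 / (n - n_h)
        if abs(run) > abs(best):
            best = run
    return best


def test_gsea_es_set_equals_universe():
    r = ranked_series([3.0, 2.0, 1.0])
    es, le = rt.gsea_es(r, ["g0", "g1", "g2"])
    assert es == 1.0


def test_gsea_es_worked_example():
    r = ranked_series([3.0, 2.0, 1.0, 0.5])
    es, le = rt.gsea_es(r, ["g0", "g2"])
    assert es == pytest.approx(0.75)
    assert le == ["g0"]


def test_gsea_es_bottom_gene_negative():
    r = ranked_series([3.0, 2.0, 1.0])
    es, le = rt.gsea_es(r, ["g2"])
    assert es == pytest.approx(-1.0)
    assert le == ["g2"]


def test_gsea_es_empty_intersection_errors():
    with pytest.raises(ValueError, match="no members"):
        rt.gsea_es(ranked_series([1.0, 0.5]), ["zzz"])


def test_gsea_es_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(6)
    for _ in range(500):
        n = int(rng.integers(3, 200))
        scores = np.sort(rng.normal(size=n))[::-1]
        r = ranked_series(scores)
        m = int(rng.integers(1, n))
        members = list(rng.choice(r.index, size=m, replace=False))
        es, _ = rt.gsea_es(r, members)
        assert es == pytest.approx(brute_force_es(r, members), abs=1e-12)


def test_gsea_es_invariant_to_positive_rescaling():
    rng = np.random.default_rng(7)
    scores = np.sort(rng.normal(size=50))[::-1]
    members = [f"g{i}" for i in range(0, 50, 7)]
    es1, _ = rt.gsea_es(ranked_series(scores), members)
    es2, _ = rt.gsea_es(ranked_series(scores * 13.7), members)
    assert es1 == pytest.approx(es2, rel=1e-12)


def test_fast_null_es_matches_running_sum():
    """The O(set) extremum-at-hits shortcut equals the full running sum."""
    rng = np.random.default_rng(8)
    for _ in range(300):
        n = int(rng.integers(4, 120))
        scores = np.sort(rng.normal(size=n))[::-1]
        m = int(rng.integers(1, n))
        pos = np.sort(rng.choice(n, size=m, replace=False))
        r = ranked_series(scores)
        members = [f"g{i}" for i in pos]
        fast = _es_from_positions(pos, np.abs(scores[pos]), n)
        assert fast == pytest.approx(brute_force_es(r, members), abs=1e-12)


def test_gsea_preranked_null_calibration():
    """Random sets on random scores reject at the nominal rate."""
    rng = np.random.default_rng(2)
    scores = np.sort(rng.normal(size=1_000))[::-1]
    r = ranked_series(scores)
    collection = {
        f"s{i}": list(rng.choice(r.index, size=20, replace=False)) for i in range(200)
    }
    res = rt.gsea_preranked(r, collection, n_perm=500, seed=2)
    frac = (res["p_perm"] < 0.05).mean()
    lo, hi = stats.binom(200, 0.05).ppf([0.005, 0.995]) / 200
    assert lo <= frac <= hi


def test_gsea_preranked_detects_planted_set():
    rng = np.random.default_rng(9)
    scores = np.sort(rng.normal(size=1_000))[::-1]
    r = ranked_series(scores)
    collection = {"top": [f"g{i}" for i in range(20)]}
    collection.update(
        {f"s{i}": list(rng.choice(r.index, size=20, replace=False)) for i in range(30)}
    )
    res = rt.gsea_preranked(r, collection, n_perm=1000, seed=3)
    assert res.loc["top", "nes"] > 0
    assert res.loc["top", "fdr_q"] < 0.25
    assert res.loc["top", "p_perm"] < 0.01


def test_gsea_preranked_seed_determinism():
    rng = np.random.default_rng(10)
    scores = np.sort(rng.normal(size=300))[::-1]
    r = ranked_series(scores)
    coll = {f"s{i}": list(rng.choice(r.index, size=15, replace=False)) for i in range(10)}
    a = rt.gsea_preranked(r, coll, n_perm=200, seed=4)
    b = rt.gsea_preranked(r, coll, n_perm=200, seed=4)
    pd.testing.assert_frame_equal(a, b)


def test_gsea_preranked_filters_small_sets_and_validates():
    r = ranked_series(np.linspace(3, 0.1, 50))
    with pytest.raises(ValueError, match="no gene sets"):
        rt.gsea_preranked(r, {"tiny": ["g0", "g1"]}, n_perm=100, seed=1)
    with pytest.raises(ValueError, match="n_perm"):
        rt.gsea_preranked(r, {"s": [f"g{i}" for i in range(10)]}, n_perm=10)


def test_gsea_leading_edge_subset_of_set():
    rng = np.random.default_rng(11)
    scores = np.sort(rng.normal(size=200))[::-1]
    r = ranked_series(scores)
    members = list(rng.choice(r.index, size=25, replace=False))
    res = rt.gsea_preranked(r, {"s": members}, n_perm=100, seed=5)
    assert set(res.loc["s", "leading_edge"]) <= set(members)
    assert res.loc["s", "p_perm"] >= 1 / 101


# ------------------------------------------------------------- enrichment map

def _results_frame(rows):
    return pd.DataFrame(
        rows, columns=["name", "size", "nes", "fdr_q"]
    ).set_index("name")


def test_enrichment_map_identical_sets_full_weight():
    res = _results_frame([("A", 3, 2.0, 0.01), ("B", 3, 1.5, 0.01)])
    members = {"A": {"x", "y", "z"}, "B": {"x", "y", "z"}}
    g = rt.build_enrichment_map(res, members)
    assert g["A"]["B"]["weight"] == 1.0


def test_enrichment_map_disjoint_no_edge_and_fdr_filter():
    res = _results_frame([("A", 2, 2.0, 0.01), ("B", 2, 1.5, 0.01), ("C", 2, 1.2, 0.9)])
    members = {"A": {"x", "y"}, "B": {"u", "v"}, "C": {"x", "y"}}
    g = rt.build_enrichment_map(res, members)
    assert set(g.nodes) == {"A", "B"}
    assert g.number_of_edges() == 0


def test_enrichment_map_edge_exactly_at_cutoff_kept():
    res = _results_frame([("A", 10, 2.0, 0.01), ("B", 20, 1.5, 0.01)])
    a = {f"x{i}" for i in range(10)}
    b = set(list(a)[:5]) | {f"y{i}" for i in range(15)}
    g = rt.build_enrichment_map(res, {"A": a, "B": b})
    assert g["A"]["B"]["weight"] == pytest.approx(0.5)


def test_enrichment_map_order_invariant():
    rng = np.random.default_rng(12)
    names = [f"S{i}" for i in range(8)]
    members = {nm: set(rng.choice(100, size=12, replace=False).tolist()) for nm in names}
    rows = [(nm, 12, float(rng.normal()), float(rng.random() * 0.2)) for nm in names]
    g1 = rt.build_enrichment_map(_results_frame(rows), members, sim_cutoff=0.1)
    g2 = rt.build_enrichment_map(_results_frame(rows[::-1]), members, sim_cutoff=0.1)
    assert nx.utils.graphs_equal(g1, g2)


def test_gmt_roundtrip(tmp_path):
    sets = {"A": ["g1", "g2"], "B": ["g3", "g4", "g5"]}
    path = tmp_path / "sets.gmt"
    rt.write_gmt(sets, path)
    assert rt.read_gmt(path) == sets
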