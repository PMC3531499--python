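"""Gene-set enrichment: hypergeometric overlaps, preranked GSEA, enrichment maps.

Two complementary enrichment routes are provided.

* :func:`hypergeom_overlap` tests the overlap of two gene sets within an
  explicit finite universe.  The upper-tail p-value is computed with exact
  integer arithmetic (no gamma-function approximation), because published
  overlaps of large sets reach p ~ 1e-80 where float tail sums degrade.
  The universe is the single most influential — and most often unstated —
  parameter of such tests; it is therefore a required argument and echoed
  in every result.

* :func:`gsea_preranked` scores gene sets against a ranked list with the
  weighted Kolmogorov–Smirnov-like running-sum statistic (enrichment score,
  ES), a gene-sampling permutation null, sign-matched normalisation (NES)
  and the ratio-of-tails FDR.

Significant sets can be assembled into an *enrichment map*: a graph whose
nodes are enriched sets and whose edges connect sets with high membership
similarity, so that redundant sets cluster into functional themes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OverlapTestResult",
    "EnrichmentResult",
    "hypergeom_overlap",
    "adjust_bh",
    "gsea_es",
    "gsea_preranked",
    "build_enrichment_map",
    "read_gmt",
    "write_gmt",
]


# ---------------------------------------------------------------------------
# hypergeometric overlap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapTestResult:
    """2x2 overlap test of two gene sets within a universe of size N.

    Table: a = k (in both), b = K - k (A only), c = n - k (B only),
    d = N - K - n + k (neither).  ``haldane`` flags the +0.5 continuity
    correction applied to the odds ratio when any cell is zero.
    """

    k: int
    K: int
    n: int
    N: int
    p_upper: float
    odds_ratio: float
    haldane: bool = False


def _hypergeom_sf_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N, K, n), exact rational arithmetic."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return Fraction(acc, total)


def hypergeom_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> OverlapTestResult:
    """Upper-tail hypergeometric test of |A ∩ B| given a finite universe.

    Both sets must be subsets of the (deduplicated) universe.  The odds
    ratio is (a·d)/(b·c) with a Haldane–Anscombe +0.5 on every cell when
    any cell is zero (flagged in the result).
    """
    uni = set(universe)
    a_set, b_set = set(set_a), set(set_b)
    for label, s in (("set_a", a_set), ("set_b", b_set)):
        extra = s - uni
        if extra:
            raise ValueError(f"{label} contains genes outside the universe: {sorted(extra)[:5]}")
    N, K, n = len(uni), len(a_set), len(b_set)
    k = len(a_set & b_set)
    p_upper = float(_hypergeom_sf_exact(k, K, n, N))
    a, b, c, d = k, K - k, n - k, N - K - n + k
    haldane = 0 in (a, b, c, d)
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return OverlapTestResult(k, K, n, N, p_upper, (a * d) / (b * c), haldane)


def adjust_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    size: int  # set size after restriction to the ranked universe
    es: float
    nes: float
    p_perm: float
    fdr_q: float
    leading_edge: tuple[str, ...]


def _as_ranked(ranked) -> tuple[list[str], np.ndarray]:
    if isinstance(ranked, pd.Series):
        genes, scores = list(ranked.index), ranked.to_numpy(dtype=float)
    else:
        genes = [g for g, _ in ranked]
        scores = np.array([s for _, s in ranked], dtype=float)
    if len(set(genes)) != len(genes):
        raise ValueError("ranked list contains duplicate genes")
    if np.any(np.diff(scores) > 0):
        order = np.argsort(-scores, kind="stable")
        genes = [genes[i] for i in order]
        scores = scores[order]
    return genes, scores


def gsea_es(ranked, gene_set: Iterable[str], weight: float = 1.0) -> tuple[float, list[str]]:
    """Enrichment score and leading edge of one gene set.

    ``ranked``: pandas Series (index = gene, value = score) or sequence of
    (gene, score) pairs; sorted descending internally if needed.  The
    running sum gains |score|^weight / N_R at members ("hits") and loses
    1/(N - N_H) at non-members; ES is the extremum of largest magnitude.
    The leading edge comprises the hits at or before the extremum for
    positive ES, and at or after it for negative ES.
    """
    genes, scores = _as_ranked(ranked)
    gs = set(gene_set)
    hit = np.fromiter((g in gs for g in genes), dtype=bool, count=len(genes))
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set has no members in the ranked list")
    n = len(genes)
    w = np.abs(scores) ** weight
    n_r = w[hit].sum()
    steps = np.where(hit, (w / n_r) if n_r > 0 else 0.0, 0.0)
    if n > n_hit:
        steps = steps - (~hit) / (n - n_hit)
        running = np.cumsum(steps)
        i_max = int(np.argmax(np.abs(running)))
        es = float(running[i_max])
    else:
        running = np.cumsum(steps)
        i_max = n - 1
        es = 1.0  # set == universe: pure gain, ES = 1 by convention
    if es >= 0:
        leading = [g for j, g in enumerate(genes) if hit[j] and j <= i_max]
    else:
        leading = [g for j, g in enumerate(genes) if hit[j] and j >= i_max]
    return es, leading


def _es_from_positions(pos: np.ndarray, w: np.ndarray, n: int) -> float:
    """ES from sorted hit positions only (O(set size)).

    ``pos``: sorted 0-based ranks of the hits; ``w``: |score|^weight at
    those ranks.  Between hits the running sum decays linearly, so the
    extremal values occur right after each hit (local maxima candidates)
    and right before each hit / at the end (local minima candidates).
    """
    m = pos.size
    if m == n:
        return 1.0
    dec = 1.0 / (n - m)
    n_r = w.sum()
    gain = (w / n_r) if n_r > 0 else np.zeros_like(w)
    cum_gain = np.cumsum(gain)
    misses_before = pos - np.arange(m)  # misses strictly before each hit
    at_hit = cum_gain - misses_before * dec  # value right after each hit
    before_hit = at_hit - gain  # value right before each hit
    j_hi = int(np.argmax(at_hit))
    hi, idx_hi = float(at_hit[j_hi]), int(pos[j_hi])
    j_lo = int(np.argmin(before_hit))
    lo, idx_lo = float(before_hit[j_lo]), int(pos[j_lo]) - 1
    if lo > 0.0:  # running sum ends at 0, which is then the minimum
        lo, idx_lo = 0.0, n - 1
    # |ES| ties resolve to the earlier extremum, matching the running sum
    if hi > -lo or (hi == -lo and idx_hi < idx_lo):
        return hi
    return lo


def _null_es_matrix(
    rng: np.random.Generator, w_all: np.ndarray, n: int, m: int, n_perm: int
) -> np.ndarray:
    """ES of ``n_perm`` random size-``m`` draws from an ``n``-gene universe.

    Vectorised version of :func:`_es_from_positions` over all draws.
    """
    if m >= n:
        return np.ones(n_perm)
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, m, axis=1)[:, :m]
    idx.sort(axis=1)
    gains_raw = w_all[idx]
    n_r = gains_raw.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        gain = np.where(n_r > 0, gains_raw / n_r, 0.0)
    cum_gain = np.cumsum(gain, axis=1)
    dec = 1.0 / (n - m)
    misses_before = idx - np.arange(m)
    at_hit = cum_gain - misses_before * dec
    before_hit = at_hit - gain
    j_hi = np.argmax(at_hit, axis=1)
    rows = np.arange(n_perm)
    hi = at_hit[rows, j_hi]
    idx_hi = idx[rows, j_hi]
    j_lo = np.argmin(before_hit, axis=1)
    lo = before_hit[rows, j_lo]
    idx_lo = idx[rows, j_lo] - 1
    end_min = lo > 0.0  # running sum ends at 0
    lo = np.where(end_min, 0.0, lo)
    idx_lo = np.where(end_min, n - 1, idx_lo)
    take_hi = (hi > -lo) | ((hi == -lo) & (idx_hi < idx_lo))
    return np.where(take_hi, hi, lo)


def gsea_preranked(
    ranked,
    collection: Mapping[str, Iterable[str]],
    n_perm: int = 1000,
    seed: int | None = None,
    min_size: int = 5,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Preranked GSEA over a gene-set collection with a gene-sampling null.

    For each set the null distribution is the ES of ``n_perm`` random
    same-size draws from the ranked universe.  NES = ES / mean |null ES| of
    matching sign; p_perm uses the +1 pseudo-count convention over
    same-sign nulls; FDR q is the GSEA ratio-of-tails statistic over the
    pooled observed and null NES values, clipped to [0, 1].

    Returns a DataFrame indexed by set name with columns
    ``size, es, nes, p_perm, fdr_q, leading_edge``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes, scores = _as_ranked(ranked)
    if isinstance(ranked, pd.Series):
        ranked = pd.Series(scores, index=genes)
    else:
        ranked = pd.Series(scores, index=genes)
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    w_all = np.abs(scores) ** weight

    kept: list[tuple[str, list[str]]] = []
    for name, members in collection.items():
        inside = sorted({g for g in members if g in gene_pos})
        if len(inside) >= min_size:
            kept.append((name, inside))
    if not kept:
        raise ValueError("no gene sets remain after restriction to the ranked universe")

    rng = np.random.default_rng(seed)
    rows = []
    null_nes_pool: list[np.ndarray] = []
    for name, members in kept:
        es, leading = gsea_es(ranked, members, weight=weight)
        m = len(members)
        null_es = _null_es_matrix(rng, w_all, n, m, n_perm)
        same = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        if same.size == 0:
            p_perm, nes = 1.0 / (n_perm + 1), math.copysign(np.inf, es)
        else:
            p_perm = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + same.size)
            nes = es / np.abs(same).mean()
        pos_null = null_es[null_es > 0]
        neg_null = null_es[null_es < 0]
        nes_null = np.concatenate(
            [
                pos_null / pos_null.mean() if pos_null.size else pos_null,
                neg_null / np.abs(neg_null).mean() if neg_null.size else neg_null,
            ]
        )
        null_nes_pool.append(nes_null)
        rows.append((name, m, es, nes, p_perm, leading))

    pooled_null = np.concatenate(null_nes_pool)
    obs_nes = np.array([r[3] for r in rows])
    fdr = np.empty(len(rows))
    for i, (_, _, es, nes, _, _) in enumerate(rows):
        if nes >= 0:
            tail_null = (pooled_null >= nes).sum() / max((pooled_null >= 0).sum(), 1)
            tail_obs = (obs_nes >= nes).sum() / max((obs_nes >= 0).sum(), 1)
        else:
            tail_null = (pooled_null <= nes).sum() / max((pooled_null < 0).sum(), 1)
            tail_obs = (obs_nes <= nes).sum() / max((obs_nes < 0).sum(), 1)
        fdr[i] = min(1.0, tail_null / tail_obs) if tail_obs > 0 else 1.0

    df = pd.DataFrame(
        {
            "size": [r[1] for r in rows],
            "es": [r[2] for r in rows],
            "nes": [r[3] for r in rows],
            "p_perm": [r[4] for r in rows],
            "fdr_q": fdr,
            "leading_edge": [tuple(r[5]) for r in rows],
        },
        index=pd.Index([r[0] for r in rows], name="name"),
    )
    return df


# ---------------------------------------------------------------------------
# enrichment map
# ---------------------------------------------------------------------------

def _similarity(a: set, b: set, metric: str) -> float:
    inter = len(a & b)
    if inter == 0:
        return 0.0
    if metric == "overlap":
        return inter / min(len(a), len(b))
    if metric == "jaccard":
        return inter / len(a | b)
    raise ValueError(f"unknown similarity metric {metric!r}")


def build_enrichment_map(
    results: pd.DataFrame,
    memberships: Mapping[str, Iterable[str]],
    fdr_cutoff: float = 0.25,
    similarity: str = "overlap",
    sim_cutoff: float = 0.5,
) -> nx.Graph:
    """Graph of significant gene sets with similarity-weighted edges.

    Nodes are rows of ``results`` with ``fdr_q <= fdr_cutoff`` (attributes
    ``nes``, ``size``, ``fdr_q``); an edge joins two nodes when their
    membership similarity (overlap coefficient by default, Jaccard by
    ``similarity='jaccard'``) is >= ``sim_cutoff``; edge weight = similarity.
    """
    graph = nx.Graph()
    names = sorted(results.index[results["fdr_q"] <= fdr_cutoff])
    sets = {}
    for name in names:
        members = set(memberships[name])
        sets[name] = members
        row = results.loc[name]
        graph.add_node(name, nes=float(row["nes"]), size=int(row["size"]), fdr_q=float(row["fdr_q"]))
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            sim = _similarity(sets[a], sets[b], similarity)
            if sim >= sim_cutoff and sim > 0:
                graph.add_edge(a, b, weight=sim)
    return graph


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(
    sets: Mapping[str, Iterable[str]], path: str | Path, descriptions: Mapping[str, str] | None = None
) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")
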