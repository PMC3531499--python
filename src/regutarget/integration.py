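"""Binding-to-expression integration.

Two questions connect a ChIP peak set to a perturbation expression screen:

1. Does binding near a TSS predict expression change?  The
   *distance-response curve* bins peaks by |distance to nearest TSS| and
   plots the mean |log2 fold change| of the nearest genes per bin, against
   a permutation null band obtained by randomly re-assigning the
   expression table to genes.  An observed curve escaping the band at
   short distances is the hallmark of genuine proximal regulation.

2. Which genes are *direct targets*?  A gene is called bound when a
   consensus peak center lies within ``D_max`` of its TSS, and regulated
   when additionally its absolute fold change exceeds ``fc_min`` (linear
   scale) at FDR <= ``q_max``.  The regulated gene list is the direct
   transcriptional signature carried into enrichment and classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, _GeneIndex
from .enrichment import OverlapTestResult, hypergeom_overlap
from .peaks import ConsensusPeak

__all__ = [
    "DistanceCurve",
    "distance_response_curve",
    "call_direct_targets",
    "intersect_with_set",
    "default_distance_bins",
]


def default_distance_bins(lo: float = 100.0, hi: float = 1e6, n: int = 12) -> np.ndarray:
    """Log-spaced |distance| bin edges in bp (first edge forced to 0)."""
    edges = np.geomspace(lo, hi, n)
    return np.concatenate([[0.0], edges])


@dataclass(frozen=True)
class DistanceCurve:
    """Observed distance-response curve with its permutation envelope."""

    table: pd.DataFrame  # bin_lo, bin_hi, n_peaks, observed, null_lo, null_hi
    n_perm: int
    band: tuple[float, float]
    seed: int | None

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _check_de(de: pd.DataFrame) -> pd.DataFrame:
    required = {"gene_id", "log2fc", "fdr"}
    missing = required - set(de.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if de["gene_id"].duplicated().any():
        raise ValueError("DE table contains duplicate gene ids")
    return de


def distance_response_curve(
    peaks: Sequence[ConsensusPeak],
    genes: Sequence[GeneModel],
    de: pd.DataFrame,
    bins: np.ndarray | None = None,
    n_perm: int = 1000,
    band: tuple[float, float] = (2.5, 97.5),
    seed: int | None = None,
    signed: bool = False,
) -> DistanceCurve:
    """Mean |log2FC| of nearest genes per |TSS distance| bin, with null band.

    Each peak contributes once through its nearest-TSS gene.  The null re-
    assigns expression values to genes uniformly at random ``n_perm`` times
    and records pointwise percentiles of the per-bin means.  With
    ``signed=True`` the raw (signed) log2FC is averaged instead of its
    magnitude.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    de = _check_de(de)
    if bins is None:
        bins = default_distance_bins()
    bins = np.asarray(bins, dtype=float)
    if np.any(np.diff(bins) <= 0):
        raise ValueError("bin edges must be strictly increasing")

    index = _GeneIndex(genes)
    nearest = [index.nearest(p.chrom, p.center) for p in peaks]
    gene_ids = [g.gene_id for g, _ in nearest]
    absdist = np.array([abs(d) for _, d in nearest], dtype=float)

    lfc_by_gene = de.set_index("gene_id")["log2fc"]
    missing = sorted(set(gene_ids) - set(lfc_by_gene.index))
    if missing:
        raise ValueError(f"nearest genes missing from DE table: {missing[:10]}")

    values_all = lfc_by_gene.to_numpy(dtype=float)
    gene_order = {g: i for i, g in enumerate(lfc_by_gene.index)}
    peak_gene_idx = np.array([gene_order[g] for g in gene_ids])

    which = np.digitize(absdist, bins) - 1  # bin index per peak; -1/out-of-range dropped
    in_range = (which >= 0) & (which < len(bins) - 1)
    nb = len(bins) - 1
    counts = np.bincount(which[in_range], minlength=nb)

    def per_bin_means(vals: np.ndarray) -> np.ndarray:
        v = vals[peak_gene_idx]
        if not signed:
            v = np.abs(v)
        sums = np.bincount(which[in_range], weights=v[in_range], minlength=nb)
        with np.errstate(invalid="ignore"):
            return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    observed = per_bin_means(values_all)

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, nb))
    for i in range(n_perm):
        null[i] = per_bin_means(rng.permutation(values_all))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty bins are all-NaN
        lo = np.nanpercentile(null, band[0], axis=0)
        hi = np.nanpercentile(null, band[1], axis=0)

    table = pd.DataFrame(
        {
            "bin_lo": bins[:-1],
            "bin_hi": bins[1:],
            "n_peaks": counts,
            "observed": observed,
            "null_lo": np.where(counts > 0, lo, np.nan),
            "null_hi": np.where(counts > 0, hi, np.nan),
        }
    )
    return DistanceCurve(table, n_perm, band, seed)


def call_direct_targets(
    peaks: Sequence[ConsensusPeak],
    genes: Sequence[GeneModel],
    de: pd.DataFrame,
    d_max: int = 10_000,
    fc_min: float = 1.5,
    q_max: float = 0.25,
) -> tuple[pd.DataFrame, list[str]]:
    """Call bound and regulated (direct-target) genes.

    Per gene: the nearest consensus peak center to its TSS (signed distance
    in gene orientation).  ``is_bound`` when |distance| <= d_max;
    ``is_regulated`` when additionally 2**|log2fc| >= fc_min and
    fdr <= q_max.  Returns the per-gene table and the regulated gene list
    (the direct transcriptional signature), sorted by gene id.
    """
    if d_max <= 0 or q_max <= 0:
        raise ValueError("thresholds must be positive")
    if fc_min < 1:
        raise ValueError("fc_min must be >= 1 (linear fold change)")
    de = _check_de(de).set_index("gene_id")

    centers: dict[str, list[tuple[int, str]]] = {}
    for p in peaks:
        centers.setdefault(p.chrom, []).append((p.center, p.id))
    sorted_centers = {
        c: (np.array([x for x, _ in sorted(v)]), [pid for _, pid in sorted(v)])
        for c, v in centers.items()
    }

    rows = []
    for g in sorted(genes, key=lambda g: g.gene_id):
        entry = sorted_centers.get(g.chrom)
        if entry is None:
            rows.append((g.gene_id, np.nan, None, False))
            continue
        arr, ids = entry
        i = int(np.searchsorted(arr, g.tss))
        best_d, best_id = None, None
        for j in (i - 1, i):
            if 0 <= j < len(arr):
                d = int(arr[j]) - g.tss
                if best_d is None or abs(d) < abs(best_d):
                    best_d, best_id = d, ids[j]
        signed = best_d if g.strand == "+" else -best_d
        rows.append((g.gene_id, signed, best_id, abs(best_d) <= d_max))

    table = pd.DataFrame(rows, columns=["gene_id", "distance", "peak_id", "is_bound"])
    joined = table.join(de, on="gene_id")
    absfc = np.power(2.0, np.abs(joined["log2fc"]))
    table["is_regulated"] = (
        table["is_bound"] & (absfc >= fc_min) & (joined["fdr"] <= q_max)
    ).fillna(False)
    table["direction"] = np.where(
        table["is_regulated"], np.where(joined["log2fc"] > 0, "up", "down"), ""
    )
    regulated = sorted(table.loc[table["is_regulated"], "gene_id"])
    return table, regulated


def intersect_with_set(
    regulated: Iterable[str], reference: Iterable[str], universe: Iterable[str]
) -> tuple[list[str], OverlapTestResult]:
    """Intersect a called-target list with a reference set; test the overlap.

    Both sets must lie inside the universe; the hypergeometric upper-tail
    test (and odds ratio) is delegated to
    :func:`regutarget.enrichment.hypergeom_overlap`.
    """
    reg, ref = set(regulated), set(reference)
    result = hypergeom_overlap(reg, ref, universe)
    return sorted(reg & ref), result
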