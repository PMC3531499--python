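"""Gene models, nearest-TSS distances and genomic categorisation of peaks.

A peak is reduced to its center point.  The signed distance to the nearest
transcription start site is reported in gene orientation: positive values
lie 3' (downstream) of the TSS, negative values 5' (upstream).  Each peak
receives exactly one genomic category, decided by the first matching class
in a fixed precedence order::

    promoter<=1kb > 5'UTR > 3'UTR > exon(CDS) > intron
                  > promoter 1-10kb > downstream<=10kb > distal intergenic

Promoter and downstream windows are strand-aware.  The precedence order is
a convention (region classes overlap in the genome); promoter outranks UTR
so that TSS-proximal binding is accounted as promoter binding.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .peaks import ConsensusPeak

__all__ = [
    "GeneModel",
    "PeakAnnotation",
    "CATEGORIES",
    "read_gene_models",
    "write_gene_models",
    "nearest_tss",
    "categorize_peak",
    "annotate_peaks",
    "category_proportions",
]

CATEGORIES: tuple[str, ...] = (
    "promoter<=1kb",
    "5'UTR",
    "3'UTR",
    "exon_cds",
    "intron",
    "promoter_1-10kb",
    "downstream<=10kb",
    "distal_intergenic",
)


@dataclass(frozen=True)
class GeneModel:
    """One transcript model per gene (BED12-style).

    ``cds_start``/``cds_end`` delimit the coding span; when absent
    (``cds_start == cds_end``) the transcript is treated as non-coding and
    its exons carry no UTR/CDS sub-classification.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.tx_start >= self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start >= tx_end")
        prev_end = self.tx_start
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene must have >=1 exon")
        for s, e in self.exons:
            if s >= e or s < prev_end or e > self.tx_end:
                raise ValueError(f"{self.gene_id}: bad exon structure {self.exons}")
            prev_end = e
        if self.exons[0][0] != self.tx_start or self.exons[-1][1] != self.tx_end:
            raise ValueError(f"{self.gene_id}: exons must span transcript bounds")

    @property
    def tss(self) -> int:
        """5' end of the transcript: tx_start on '+', tx_end on '-'."""
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tes(self) -> int:
        """3' end of the transcript."""
        return self.tx_end if self.strand == "+" else self.tx_start

    def oriented_offset(self, pos: int) -> int:
        """Signed offset of ``pos`` from the TSS in gene orientation."""
        return pos - self.tss if self.strand == "+" else self.tss - pos


@dataclass(frozen=True)
class PeakAnnotation:
    peak_id: str
    category: str
    nearest_gene: str
    distance: int  # signed bp, gene orientation, positive downstream of TSS


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 (thickStart/thickEnd = CDS)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED12 columns, got {len(f)}")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            cds_start = thick_start if thick_start != thick_end else None
            cds_end = thick_end if thick_start != thick_end else None
            genes.append(GeneModel(name, chrom, strand, start, end, exons, cds_start, cds_end))
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.tx_start) for s, e in g.exons)
            cs = g.cds_start if g.cds_start is not None else g.tx_start
            ce = g.cds_end if g.cds_end is not None else g.tx_start
            fh.write(
                f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{cs}\t{ce}\t0\t{len(g.exons)}\t{sizes},\t{offsets},\n"
            )


class _GeneIndex:
    """Per-chromosome sorted TSS arrays for fast nearest-TSS queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.by_chrom: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
        tmp: dict[str, list[GeneModel]] = {}
        for g in genes:
            tmp.setdefault(g.chrom, []).append(g)
        for chrom, gs in tmp.items():
            # sort by (tss, gene_id) so equal-distance ties resolve to the
            # lexicographically smaller gene id deterministically
            gs_sorted = sorted(gs, key=lambda g: (g.tss, g.gene_id))
            self.by_chrom[chrom] = (np.array([g.tss for g in gs_sorted]), gs_sorted)

    def nearest(self, chrom: str, pos: int) -> tuple[GeneModel, int]:
        if chrom not in self.by_chrom:
            raise ValueError(f"no reference genes on chromosome {chrom!r}")
        tss_arr, gs = self.by_chrom[chrom]
        i = int(np.searchsorted(tss_arr, pos))
        best: GeneModel | None = None
        best_abs = None
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(gs):
                cand = gs[j]
                d = abs(pos - cand.tss)
                if best is None or d < best_abs or (d == best_abs and cand.gene_id < best.gene_id):
                    best, best_abs = cand, d
        assert best is not None
        return best, best.oriented_offset(pos)


def nearest_tss(
    peak_center: int, genes: Sequence[GeneModel] | _GeneIndex, chrom: str
) -> tuple[str, int]:
    """Gene with the TSS nearest ``peak_center`` and the signed distance.

    Ties in |distance| go to the lexicographically smaller gene id.
    Raises ``ValueError`` when the chromosome has no genes.
    """
    index = genes if isinstance(genes, _GeneIndex) else _GeneIndex(genes)
    g, d = index.nearest(chrom, peak_center)
    return g.gene_id, d


def _in_exon(g: GeneModel, pos: int) -> bool:
    starts = [s for s, _ in g.exons]
    i = bisect.bisect_right(starts, pos) - 1
    return i >= 0 and g.exons[i][0] <= pos < g.exons[i][1]


def _gene_category(g: GeneModel, pos: int, promoter_bp: int, far_bp: int) -> str | None:
    """Category of a point with respect to one gene, or None if unrelated.

    Returns the highest-precedence class this gene supports at ``pos``.
    """
    off = g.oriented_offset(pos)
    if -promoter_bp <= off <= 0:  # the TSS base itself counts as promoter
        return "promoter<=1kb"
    if g.tx_start <= pos < g.tx_end:
        if _in_exon(g, pos):
            if g.cds_start is not None:
                if g.strand == "+":
                    five_hi, three_lo = g.cds_start, g.cds_end
                    if pos < five_hi:
                        return "5'UTR"
                    if pos >= three_lo:
                        return "3'UTR"
                else:
                    if pos >= g.cds_end:
                        return "5'UTR"
                    if pos < g.cds_start:
                        return "3'UTR"
                return "exon_cds"
            return "exon_cds"
        return "intron"
    if -far_bp <= off < -promoter_bp:
        return "promoter_1-10kb"
    tes_off = (pos - g.tes) if g.strand == "+" else (g.tes - pos)
    if 0 <= tes_off <= far_bp:
        return "downstream<=10kb"
    return None


def categorize_peak(
    peak: ConsensusPeak | int,
    genes: Sequence[GeneModel],
    chrom: str | None = None,
    peak_id: str = "",
    promoter_bp: int = 1_000,
    far_bp: int = 10_000,
    _index: "_AnnotationIndex | None" = None,
) -> PeakAnnotation:
    """Assign one genomic category plus nearest gene / signed TSS distance.

    ``peak`` may be a :class:`~regutarget.peaks.ConsensusPeak` (its center is
    used) or a raw center coordinate with ``chrom`` given explicitly.
    """
    if isinstance(peak, ConsensusPeak):
        pos, chrom_, pid = peak.center, peak.chrom, peak.id
    else:
        if chrom is None:
            raise ValueError("chrom required when passing a raw center position")
        pos, chrom_, pid = int(peak), chrom, peak_id
    index = _index if _index is not None else _AnnotationIndex(genes)
    g, dist = index.gene_index.nearest(chrom_, pos)
    best_rank = len(CATEGORIES) - 1  # distal_intergenic
    for cand in index.candidates(chrom_, pos, far_bp):
        cat = _gene_category(cand, pos, promoter_bp, far_bp)
        if cat is not None:
            rank = CATEGORIES.index(cat)
            if rank < best_rank:
                best_rank = rank
    return PeakAnnotation(pid, CATEGORIES[best_rank], g.gene_id, dist)


class _AnnotationIndex:
    """Gene index plus per-chromosome interval lookup for category queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.gene_index = _GeneIndex(genes)
        self._spans: dict[str, tuple[np.ndarray, np.ndarray, list[GeneModel]]] = {}
        tmp: dict[str, list[GeneModel]] = {}
        for g in genes:
            tmp.setdefault(g.chrom, []).append(g)
        for chrom, gs in tmp.items():
            gs_sorted = sorted(gs, key=lambda g: g.tx_start)
            self._spans[chrom] = (
                np.array([g.tx_start for g in gs_sorted]),
                np.array([g.tx_end for g in gs_sorted]),
                gs_sorted,
            )

    def candidates(self, chrom: str, pos: int, far_bp: int) -> list[GeneModel]:
        """Genes whose extended span [tx_start-far, tx_end+far] covers pos."""
        if chrom not in self._spans:
            return []
        starts, ends, gs = self._spans[chrom]
        lo = int(np.searchsorted(ends + far_bp, pos, side="left"))
        hi = int(np.searchsorted(starts - far_bp, pos, side="right"))
        return gs[lo:hi]


def annotate_peaks(
    peaks: Sequence[ConsensusPeak],
    genes: Sequence[GeneModel],
    promoter_bp: int = 1_000,
    far_bp: int = 10_000,
) -> pd.DataFrame:
    """Annotate every peak; returns a DataFrame indexed by peak id.

    Columns: ``category``, ``nearest_gene``, ``distance`` (signed bp).
    """
    index = _AnnotationIndex(genes)
    rows = [
        categorize_peak(p, genes, promoter_bp=promoter_bp, far_bp=far_bp, _index=index)
        for p in peaks
    ]
    return pd.DataFrame(
        {
            "peak_id": [r.peak_id for r in rows],
            "category": [r.category for r in rows],
            "nearest_gene": [r.nearest_gene for r in rows],
            "distance": [r.distance for r in rows],
        }
    ).set_index("peak_id")


def category_proportions(annotations: pd.DataFrame | Sequence[PeakAnnotation]) -> pd.DataFrame:
    """Counts and fractions per genomic category (fractions sum to 1)."""
    if not isinstance(annotations, pd.DataFrame):
        annotations = pd.DataFrame({"category": [a.category for a in annotations]})
    if len(annotations) == 0:
        raise ValueError("no annotations supplied")
    counts = annotations["category"].value_counts().reindex(CATEGORIES, fill_value=0)
    return pd.DataFrame({"count": counts, "fraction": counts / counts.sum()})
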