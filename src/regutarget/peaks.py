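"""Peak intervals and the dual-caller consensus peak set.

ChIP-seq peak callers disagree at the margins; restricting analysis to the
genomic intervals supported by two independent callers is a conservative way
to define high-confidence binding sites.  A consensus peak here is the
merged union of pairwise interval intersections between the two call sets,
so consensus peaks are pairwise disjoint and every consensus base pair is
covered by at least one peak from *each* caller.

Coordinates are 0-based half-open throughout (BED native).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

__all__ = [
    "Peak",
    "ConsensusPeak",
    "PeakParseError",
    "read_peaks",
    "write_peaks",
    "write_consensus_peaks",
    "intersect_peak_sets",
]


class PeakParseError(ValueError):
    """Raised for malformed BED lines; carries the 1-based line number."""


@dataclass(frozen=True)
class Peak:
    """A single caller's peak interval."""

    chrom: str
    start: int
    end: int
    id: str = ""
    enrichment: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"peak {self.id or '<unnamed>'}: start {self.start} >= end {self.end}"
            )
        if self.enrichment < 0:
            raise ValueError(f"peak {self.id}: negative enrichment {self.enrichment}")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class ConsensusPeak:
    """Disjoint interval supported by both callers.

    ``support`` lists the (caller-A id, caller-B id) pairs whose pairwise
    intersections were merged into this interval.  ``enrichment`` is the
    minimum enrichment among all contributing source peaks.
    """

    chrom: str
    start: int
    end: int
    id: str = ""
    enrichment: float = 0.0
    support: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"consensus {self.id}: start >= end")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def read_peaks(path: str | Path, source_label: str = "") -> list[Peak]:
    """Read peaks from a BED3+ file (optional name and score columns).

    Malformed lines (non-numeric coordinates, start >= end) raise
    :class:`PeakParseError` naming the offending 1-based line number.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise PeakParseError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise PeakParseError(
                    f"{path}:{lineno}: non-numeric coordinates {fields[1]!r}, {fields[2]!r}"
                ) from exc
            name = fields[3] if len(fields) > 3 else f"{source_label or 'peak'}_{lineno}"
            try:
                score = float(fields[4]) if len(fields) > 4 else 0.0
            except ValueError as exc:
                raise PeakParseError(f"{path}:{lineno}: non-numeric score {fields[4]!r}") from exc
            try:
                peaks.append(Peak(chrom, start, end, name, score, source_label))
            except ValueError as exc:
                raise PeakParseError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as BED6 (name = peak id, score = enrichment)."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\t{p.enrichment:g}\t.\n")


def write_consensus_peaks(peaks: Iterable[ConsensusPeak], path: str | Path) -> None:
    """Write consensus peaks as BED6 (score = min source enrichment)."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\t{p.enrichment:g}\t.\n")


def _validate_chroms(
    peaks: Sequence[Peak], genome: Mapping[str, int], label: str
) -> None:
    bad = sorted({p.chrom for p in peaks} - set(genome))
    if bad:
        raise ValueError(f"{label}: unknown chromosome names {bad}")
    for p in peaks:
        if p.end > genome[p.chrom]:
            raise ValueError(f"{label}: peak {p.id} exceeds {p.chrom} length {genome[p.chrom]}")


def intersect_peak_sets(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    min_overlap_bp: int = 1,
    genome: Mapping[str, int] | None = None,
) -> list[ConsensusPeak]:
    """Consensus peaks: merged pairwise intersections of two call sets.

    Every A x B pair overlapping by at least ``min_overlap_bp`` contributes
    its intersection span; candidate spans sharing any base pair are merged
    (union of intersections), so the result is pairwise disjoint, sorted by
    (chrom, start).  If ``genome`` (chrom -> length) is given, all peaks are
    validated against it first.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    if genome is not None:
        _validate_chroms(peaks_a, genome, "peaks_a")
        _validate_chroms(peaks_b, genome, "peaks_b")

    by_chrom_b: dict[str, IntervalTree] = {}
    for p in peaks_b:
        by_chrom_b.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)

    # candidate spans per chromosome: (start, end, a_peak, b_peak)
    candidates: dict[str, list[tuple[int, int, Peak, Peak]]] = {}
    for a in peaks_a:
        tree = by_chrom_b.get(a.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(a.start, a.end):
            b: Peak = iv.data
            lo, hi = max(a.start, b.start), min(a.end, b.end)
            if hi - lo >= min_overlap_bp:
                candidates.setdefault(a.chrom, []).append((lo, hi, a, b))

    consensus: list[ConsensusPeak] = []
    for chrom in sorted(candidates):
        spans = sorted(candidates[chrom], key=lambda t: (t[0], t[1]))
        cur_lo, cur_hi, cur_support, cur_enr = None, None, [], float("inf")
        for lo, hi, a, b in spans:
            if cur_lo is None or lo >= cur_hi:  # disjoint -> flush
                if cur_lo is not None:
                    consensus.append(
                        ConsensusPeak(chrom, cur_lo, cur_hi, "", cur_enr, tuple(cur_support))
                    )
                cur_lo, cur_hi, cur_support, cur_enr = lo, hi, [], float("inf")
            cur_hi = max(cur_hi, hi)
            cur_support.append((a.id, b.id))
            cur_enr = min(cur_enr, a.enrichment, b.enrichment)
        if cur_lo is not None:
            consensus.append(ConsensusPeak(chrom, cur_lo, cur_hi, "", cur_enr, tuple(cur_support)))

    width = max(4, len(str(len(consensus))))
    return [
        ConsensusPeak(c.chrom, c.start, c.end, f"consensus_{i:0{width}d}", c.enrichment, c.support)
        for i, c in enumerate(consensus, start=1)
    ]
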