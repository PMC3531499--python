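"""Synthetic data with planted ground truth for the full pipeline.

The generator emulates the observable structure of a transcription-factor
perturbation study: a gene annotation, two noisy caller views of one
underlying ChIP peak set in which a fraction of peaks are planted near the
TSS of "true target" genes, a differential-expression table whose effect
sizes decay exponentially with peak-to-TSS distance, gene-set collections
with one set enriched for the true targets, and a multi-subtype expression
cohort in which a signature separates the subtypes.

Every generator is a deterministic function of its seed, and the planted
truth (:class:`SimulationTruth`) is serialisable so downstream tests never
re-derive it.

Default parameters define the reference simulation conditions used
throughout the test-suite: 10 % of genes are targets; planted regulatory
peaks sit Laplace(0, 300 bp) around the TSS (direct-target binding is
promoter-proximal, while background peaks supply the distal binding mass);
effect size beta = 2 log2 units decays with scale lambda_e = 2 kb;
residual sd sigma = 0.5 with n_rep = 3 replicates per arm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel
from .enrichment import adjust_bh
from .peaks import Peak

__all__ = [
    "SimulationTruth",
    "simulate_genome",
    "simulate_chip_peaks",
    "simulate_de_table",
    "simulate_gene_sets",
    "simulate_cohort",
]

_MIN_GENE_LEN = 2_000
_MAX_GENE_LEN = 20_000
_MIN_GAP = 1_000


@dataclass(frozen=True)
class SimulationTruth:
    """Planted ground truth behind one simulated dataset."""

    target_genes: frozenset[str]
    peak_gene_map: dict[str, tuple[str, int]]  # peak id -> (gene id, signed planted d)
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "target_genes": sorted(self.target_genes),
            "peak_gene_map": {k: list(v) for k, v in self.peak_gene_map.items()},
            "params": self.params,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            frozenset(payload["target_genes"]),
            {k: (v[0], int(v[1])) for k, v in payload["peak_gene_map"].items()},
            payload["params"],
        )


def simulate_genome(
    n_genes: int, chrom_lengths: Sequence[int], seed: int
) -> list[GeneModel]:
    """Place ``n_genes`` non-overlapping genes on the given chromosomes.

    Gene lengths are uniform in [2, 20] kb with >=1 kb inter-gene gaps;
    strands are random; each gene gets 1-6 exons and a CDS occupying the
    central portion of the transcript (so 5'/3' UTRs exist).  Raises a
    capacity error when the genome cannot hold the requested gene count.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    for L in chrom_lengths:
        if L < 100_000:
            raise ValueError("every chromosome must be >= 100 kb")
    rng = np.random.default_rng(seed)
    total = sum(chrom_lengths)
    if n_genes * (_MIN_GENE_LEN + _MIN_GAP) > total:
        raise ValueError(
            f"insufficient genome space: {n_genes} genes need >= "
            f"{n_genes * (_MIN_GENE_LEN + _MIN_GAP)} bp, genome has {total} bp"
        )

    # apportion genes to chromosomes proportionally to length (largest remainder)
    shares = np.array(chrom_lengths, dtype=float) / total * n_genes
    counts = np.floor(shares).astype(int)
    rem = n_genes - counts.sum()
    for i in np.argsort(-(shares - counts))[:rem]:
        counts[i] += 1
    # repair any chromosome over capacity
    caps = np.array([L // (_MIN_GENE_LEN + _MIN_GAP) for L in chrom_lengths])
    while np.any(counts > caps):
        over = int(np.argmax(counts - caps))
        spare = np.where(counts < caps)[0]
        if spare.size == 0:
            raise ValueError("insufficient genome space for requested gene count")
        counts[over] -= 1
        counts[int(spare[np.argmax(caps[spare] - counts[spare])])] += 1

    width = max(4, len(str(n_genes)))
    genes: list[GeneModel] = []
    gid = 0
    for ci, (L, k) in enumerate(zip(chrom_lengths, counts)):
        if k == 0:
            continue
        chrom = f"chr{ci + 1}"
        max_len = min(_MAX_GENE_LEN, (L - (k + 1) * _MIN_GAP) // k)
        lengths = rng.integers(_MIN_GENE_LEN, max(max_len, _MIN_GENE_LEN) + 1, size=k)
        free = L - int(lengths.sum()) - (k + 1) * _MIN_GAP
        # distribute the free space as random extra gaps (k+1 slots)
        extra = rng.multinomial(free, np.full(k + 1, 1.0 / (k + 1))) if free > 0 else np.zeros(k + 1, int)
        pos = 0
        for j in range(k):
            pos += _MIN_GAP + int(extra[j])
            start, end = pos, pos + int(lengths[j])
            pos = end
            gid += 1
            genes.append(
                _make_gene(f"gene_{gid:0{width}d}", chrom, start, end, rng)
            )
    return genes


def _make_gene(gene_id: str, chrom: str, start: int, end: int, rng: np.random.Generator) -> GeneModel:
    strand = "+" if rng.random() < 0.5 else "-"
    length = end - start
    n_exons = int(rng.integers(1, 7))
    if n_exons == 1:
        exons = ((start, end),)
    else:
        # 2*(n_exons-1) distinct internal breakpoints -> alternating exon/intron
        cuts = np.sort(rng.choice(np.arange(start + 1, end), size=2 * (n_exons - 1), replace=False))
        bounds = [start, *cuts.tolist(), end]
        exons = tuple((bounds[2 * i], bounds[2 * i + 1]) for i in range(n_exons))
    # CDS spans the central ~60-80% of the transcript, clipped inside bounds
    frac_lo = rng.uniform(0.05, 0.2)
    frac_hi = rng.uniform(0.8, 0.95)
    cds_start = start + int(frac_lo * length)
    cds_end = start + int(frac_hi * length)
    if cds_start >= cds_end:
        cds_start, cds_end = None, None
    return GeneModel(gene_id, chrom, strand, start, end, exons, cds_start, cds_end)


def simulate_chip_peaks(
    genes: Sequence[GeneModel],
    chrom_lengths: Mapping[str, int],
    f_target: float = 0.1,
    lambda_d: float = 300.0,
    n_background: int = 200,
    caller_jitter: int = 0,
    p_miss: float = 0.0,
    peak_width: int = 200,
    seed: int = 0,
) -> tuple[list[Peak], list[Peak], SimulationTruth]:
    """Two caller views of one underlying peak set with planted targets.

    round(f_target * n_genes) genes become targets; each gets one true peak
    centered at TSS + d with d ~ Laplace(0, lambda_d) (signed in gene
    orientation, truncated to the chromosome).  ``n_background`` additional
    peaks fall uniformly over the genome.  Each caller view independently
    shifts both peak edges by Uniform(-caller_jitter, +caller_jitter) and
    drops each peak with probability ``p_miss``.
    """
    if not (0 < f_target <= 1):
        raise ValueError("f_target must be in (0, 1]")
    if lambda_d <= 0:
        raise ValueError("lambda_d must be > 0")
    rng = np.random.default_rng(seed)
    n_targets = round(f_target * len(genes))
    order = rng.permutation(len(genes))
    targets = [genes[i] for i in order[:n_targets]]

    half = peak_width // 2
    true_peaks: list[Peak] = []
    peak_gene_map: dict[str, tuple[str, int]] = {}
    width = max(4, len(str(n_targets + n_background)))
    for i, g in enumerate(sorted(targets, key=lambda g: g.gene_id), start=1):
        d = int(round(rng.laplace(0.0, lambda_d)))
        center = g.tss + d if g.strand == "+" else g.tss - d
        L = chrom_lengths[g.chrom]
        center = min(max(center, half), L - half - 1)
        d_real = g.oriented_offset(center)  # truncation can shrink |d|
        pid = f"true_{i:0{width}d}"
        enr = float(5.0 + rng.exponential(5.0))
        true_peaks.append(Peak(g.chrom, center - half, center + half, pid, enr, "truth"))
        peak_gene_map[pid] = (g.gene_id, int(d_real))

    chroms = sorted(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()
    bg_chroms = rng.choice(len(chroms), size=n_background, p=probs)
    for i in range(n_background):
        c = chroms[int(bg_chroms[i])]
        center = int(rng.integers(half, chrom_lengths[c] - half))
        enr = float(1.0 + rng.exponential(2.0))
        true_peaks.append(
            Peak(c, center - half, center + half, f"bg_{i + 1:0{width}d}", enr, "truth")
        )

    def caller_view(label: str) -> list[Peak]:
        out = []
        for p in true_peaks:
            if rng.random() < p_miss:
                continue
            if caller_jitter > 0:
                ds = int(rng.integers(-caller_jitter, caller_jitter + 1))
                de = int(rng.integers(-caller_jitter, caller_jitter + 1))
            else:
                ds = de = 0
            s, e = p.start + ds, p.end + de
            if s >= e:
                s, e = p.start, p.end  # degenerate jitter: keep original span
            s = max(s, 0)
            out.append(Peak(p.chrom, s, e, f"{label}_{p.id}", p.enrichment, label))
        return out

    peaks_a, peaks_b = caller_view("A"), caller_view("B")
    truth = SimulationTruth(
        frozenset(g.gene_id for g in targets),
        peak_gene_map,
        {
            "f_target": f_target,
            "lambda_d": lambda_d,
            "n_background": n_background,
            "caller_jitter": caller_jitter,
            "p_miss": p_miss,
            "peak_width": peak_width,
            "seed": seed,
        },
    )
    return peaks_a, peaks_b, truth


def simulate_de_table(
    genes: Sequence[GeneModel],
    truth: SimulationTruth,
    beta: float = 2.0,
    lambda_e: float = 2_000.0,
    sigma: float = 0.5,
    n_rep: int = 3,
    frac_negative: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Differential-expression table with distance-decaying planted effects.

    A target gene with a planted peak at signed distance d has true log2
    fold change s * beta * exp(-|d| / lambda_e) with per-gene sign s
    (``frac_negative`` of targets are repressed); non-targets have 0.  The
    observed log2FC adds Normal(0, se) noise with the two-arm standard
    error se = sigma * sqrt(2 / n_rep); the reported statistic is the
    standardised effect log2FC / se, whose null distribution is exactly
    standard normal because the generator's residual sd is known — so the
    two-sided p-values are uniform under beta = 0 by construction.  FDR is
    Benjamini-Hochberg over all genes.

    Returns a DataFrame with columns ``gene_id, log2fc, t, p, fdr``.
    """
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    gene_ids = [g.gene_id for g in genes]
    known = set(gene_ids)
    missing = [g for g, _ in truth.peak_gene_map.values() if g not in known]
    if missing:
        raise ValueError(f"truth references genes absent from the gene table: {missing[:5]}")

    rng = np.random.default_rng(seed)
    true_lfc = {}
    dist_by_gene: dict[str, int] = {}
    for _, (gid, d) in sorted(truth.peak_gene_map.items()):
        if gid in truth.target_genes:
            if gid not in dist_by_gene or abs(d) < abs(dist_by_gene[gid]):
                dist_by_gene[gid] = d
    for gid in sorted(truth.target_genes):
        d = dist_by_gene.get(gid, 0)
        s = -1.0 if rng.random() < frac_negative else 1.0
        true_lfc[gid] = s * beta * np.exp(-abs(d) / lambda_e)

    n = len(gene_ids)
    mu = np.array([true_lfc.get(g, 0.0) for g in gene_ids])
    se = sigma * np.sqrt(2.0 / n_rep)
    lfc = mu + rng.normal(0.0, se, size=n)
    t = lfc / se
    p = 2.0 * stats.norm.sf(np.abs(t))
    fdr = adjust_bh(p)
    return pd.DataFrame({"gene_id": gene_ids, "log2fc": lfc, "t": t, "p": p, "fdr": fdr})


def simulate_gene_sets(
    genes: Sequence[GeneModel],
    truth: SimulationTruth,
    n_sets: int = 50,
    set_size: int = 50,
    enrichment: float = 0.7,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Gene-set collection with one set enriched for the true targets.

    The first set ("PLANTED_TARGETS") draws round(enrichment * set_size)
    members from the target genes and the remainder uniformly from the
    rest; the other ``n_sets - 1`` sets are uniform draws.  No set contains
    duplicate genes.
    """
    gene_ids = sorted(g.gene_id for g in genes)
    if set_size > len(gene_ids):
        raise ValueError("set_size exceeds the number of genes")
    n_enriched = round(enrichment * set_size)
    targets = sorted(truth.target_genes)
    if n_enriched > len(targets):
        raise ValueError(
            f"enrichment * set_size = {n_enriched} exceeds the {len(targets)} target genes"
        )
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    planted = list(rng.choice(targets, size=n_enriched, replace=False))
    rest_pool = sorted(set(gene_ids) - set(planted))
    planted += list(rng.choice(rest_pool, size=set_size - n_enriched, replace=False))
    sets["PLANTED_TARGETS"] = planted
    for i in range(1, n_sets):
        sets[f"RANDOM_SET_{i:03d}"] = list(rng.choice(gene_ids, size=set_size, replace=False))
    return sets


def simulate_cohort(
    signature: Sequence[str],
    n_other: int = 500,
    subtype_sizes: Sequence[int] = (20, 20, 20),
    delta: float = 10.0,
    sigma: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Subtype-structured expression cohort (samples x genes).

    Each subtype has a centroid over the signature genes drawn as
    delta * sigma / sqrt(2) * N(0, 1) per gene, so the root-mean-square
    per-gene separation between any two subtype centroids is delta * sigma.
    Non-signature genes ("other_0001", ...) are Normal(0, sigma) for every
    sample.  Returns (matrix, labels) with labels "subtype_1", ...
    """
    if len(subtype_sizes) < 2:
        raise ValueError("need >= 2 subtypes")
    if any(s < 2 for s in subtype_sizes):
        raise ValueError("every subtype needs >= 2 samples")
    rng = np.random.default_rng(seed)
    sig = list(signature)
    n_sub = len(subtype_sizes)
    centroids = rng.normal(0.0, delta * sigma / np.sqrt(2.0), size=(n_sub, len(sig)))
    rows, labels = [], []
    sample_ids = []
    si = 0
    for c, size in enumerate(subtype_sizes):
        for _ in range(size):
            si += 1
            sample_ids.append(f"sample_{si:04d}")
            labels.append(f"subtype_{c + 1}")
            rows.append(rng.normal(centroids[c], sigma))
    other = rng.normal(0.0, sigma, size=(len(labels), n_other))
    mat = np.hstack([np.asarray(rows), other]) if n_other else np.asarray(rows)
    cols = sig + [f"other_{i + 1:04d}" for i in range(n_other)]
    matrix = pd.DataFrame(mat, index=sample_ids, columns=cols)
    return matrix, pd.Series(labels, index=sample_ids, name="subtype")
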