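"""Shared fixtures: small synthetic genomes and the reference simulation.

Everything is generated at test time from fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

import regutarget as rt

REFERENCE_SEED = 20_120_407


@pytest.fixture(scope="session")
def small_genome():
    """200 genes on one 20 Mb chromosome."""
    genes = rt.simulate_genome(200, [20_000_000], seed=11)
    return genes, {"chr1": 20_000_000}


@pytest.fixture(scope="session")
def reference_sim():
    """The reference study conditions: 2,000 genes, generator defaults.

    Returns (genes, chrom_lengths, peaks_a, peaks_b, truth, de).
    """
    chrom_lengths = {"chr1": 200_000_000}
    genes = rt.simulate_genome(2_000, [200_000_000], seed=REFERENCE_SEED)
    peaks_a, peaks_b, truth = rt.simulate_chip_peaks(
        genes, chrom_lengths, n_background=200, seed=REFERENCE_SEED + 1
    )
    de = rt.simulate_de_table(genes, truth, seed=REFERENCE_SEED + 2)
    return genes, chrom_lengths, peaks_a, peaks_b, truth, de


@pytest.fixture(scope="session")
def reference_consensus(reference_sim):
    _, _, peaks_a, peaks_b, _, _ = reference_sim
    return rt.intersect_peak_sets(peaks_a, peaks_b)


def random_peaks(rng: np.random.Generator, n: int, span: int = 1000, chroms=("chr1",)):
    """Random small peak instances for oracle comparisons."""
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span - 2))
        end = int(rng.integers(start + 1, span))
        out.append(rt.Peak(chrom, start, end, f"p{i}", float(rng.random()), "x"))
    return out
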