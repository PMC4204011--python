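"""Shared fixtures and brute-force oracles.

The oracle functions here deliberately re-derive every quantity with the
most naive possible loop so they stay independent of the library code
they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from cpgkit.composition import NucleotideSequence


def brute_force_cpg_count(bases: str) -> int:
    """Count CpGs by explicit inspection of every adjacent pair."""
    return sum(
        1
        for i in range(len(bases) - 1)
        if bases[i] == "C" and bases[i + 1] == "G"
    )


def brute_force_window_stats(bases: str, start: int, end: int) -> tuple[float, int]:
    """(gc_fraction, cpg_count) of one window by explicit loops.

    The CpG whose C is the window's last base counts for this window.
    """
    gc = sum(1 for b in bases[start:end] if b in "GC")
    n_cpg = sum(
        1
        for i in range(start, min(end, len(bases) - 1))
        if bases[i] == "C" and bases[i + 1] == "G"
    )
    return gc / (end - start), n_cpg


def brute_force_blocks(
    bases_by_chrom: dict[str, str],
    window_size: int,
    passes,
    min_block_length: int,
) -> list[tuple[str, int, int]]:
    """(chrom, start, end) of maximal passing runs, by explicit scanning.

    ``passes(gc_fraction, cpg_count, has_n) -> bool`` decides each window.
    """
    out = []
    for chrom, bases in bases_by_chrom.items():
        flags = []
        for start in range(0, len(bases) - window_size + 1, window_size):
            end = start + window_size
            gc, n_cpg = brute_force_window_stats(bases, start, end)
            flags.append((start, end, passes(gc, n_cpg, "N" in bases[start:end])))
        i = 0
        while i < len(flags):
            if not flags[i][2]:
                i += 1
                continue
            j = i
            while j + 1 < len(flags) and flags[j + 1][2]:
                j += 1
            start, end = flags[i][0], flags[j][1]
            if end - start >= min_block_length:
                out.append((chrom, start, end))
            i = j + 1
    return out


def brute_force_overlap_hits(query_rows, subject_rows) -> int:
    """All-pairs count of query intervals overlapping ≥1 subject interval."""
    hits = 0
    for qc, qs, qe in query_rows:
        if any(qc == sc and qs < se and ss < qe for sc, ss, se in subject_rows):
            hits += 1
    return hits


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


@pytest.fixture
def random_sequence(rng) -> NucleotideSequence:
    return NucleotideSequence("rand", random_dna(rng, 500))
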