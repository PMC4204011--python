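"""Constrained random DNA sequence design.

Generates random sequences that satisfy *exact* joint constraints on
length, G+C base count and CpG dinucleotide count — the building block for
synthetic CpG-island-like elements. An island "like a typical CGI" is,
e.g., 1000 bp at 65% G+C with one CpG per ~10 bp; moving the G+C target
down to 40% while keeping the CpG density gives an A+T-rich, CpG-rich
sequence that does not occur naturally in mammalian genomes.

Design targets are met exactly: the output contains exactly the requested
number of CpGs (and no accidental extras) and exactly
``round(gc_target × length)`` G+C bases. The G+C fraction is therefore
satisfied to the nearest whole base; the rounding residue is reported in
the :class:`DesignReport`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cpgkit.composition import (
    CompositionStats,
    NucleotideSequence,
    composition_stats,
    count_cpg,
)

__all__ = [
    "DesignSpec",
    "DesignReport",
    "InfeasibleSpecError",
    "GenerationError",
    "design_sequence",
    "design_report",
    "embed_with_flanks",
]


class InfeasibleSpecError(ValueError):
    """The joint (length, GC, CpG) constraints cannot all hold."""


class GenerationError(RuntimeError):
    """Sequence generation failed to satisfy the constraints.

    With the current fill rule this is unreachable in practice; it guards
    the bounded-restart contract.
    """


@dataclass(frozen=True)
class DesignSpec:
    """Joint constraints defining one synthetic island.

    Parameters
    ----------
    length : int
        Total sequence length in bases.
    gc_target : float
        Target G+C fraction in [0, 1]; realised as
        ``round(gc_target * length)`` G+C bases.
    cpg_per_100bp : float
        Target CpG density; realised as ``round(length * cpg_per_100bp / 100)``
        CpG dinucleotides, exactly.
    seed : int
        Seed for the pseudo-random generator; required (no global state).
    label : str
        Sequence identifier for the output.
    """

    length: int
    gc_target: float
    cpg_per_100bp: float
    seed: int
    label: str = "design"

    @property
    def cpg_count(self) -> int:
        return round(self.length * self.cpg_per_100bp / 100.0)

    @property
    def gc_bases(self) -> int:
        return round(self.gc_target * self.length)

    def validate(self) -> None:
        """Raise :class:`InfeasibleSpecError` naming the violated inequality."""
        if self.length <= 0:
            raise InfeasibleSpecError(f"length must be positive, got {self.length}")
        if not 0.0 <= self.gc_target <= 1.0:
            raise InfeasibleSpecError(
                f"gc_target must lie in [0, 1], got {self.gc_target}"
            )
        if self.cpg_per_100bp < 0:
            raise InfeasibleSpecError(
                f"cpg_per_100bp must be non-negative, got {self.cpg_per_100bp}"
            )
        k, s, n = self.cpg_count, self.gc_bases, self.length
        if 2 * k > n:
            raise InfeasibleSpecError(
                f"2 × cpg_count ≤ length violated: {k} CpGs need {2 * k} bases "
                f"but length is {n}"
            )
        if s < 2 * k:
            raise InfeasibleSpecError(
                f"round(gc_target × length) ≥ 2 × cpg_count violated: {k} CpGs "
                f"consume {2 * k} G/C bases but the GC target allows only {s}"
            )
        if s > n:
            raise InfeasibleSpecError(
                f"round(gc_target × length) ≤ length violated: {s} > {n}"
            )


@dataclass(frozen=True)
class DesignReport:
    """Achieved composition of a design and signed deviations from spec.

    ``gc_fraction_deviation`` is the achieved minus the requested fraction;
    it is bounded by the half-base rounding residue, |dev| ≤ 0.5/length.
    """

    spec: DesignSpec
    achieved: CompositionStats
    length_deviation: int
    cpg_deviation: int
    gc_bases_deviation: int
    gc_fraction_deviation: float


def _place_cpg_starts(rng: np.random.Generator, length: int, k: int) -> np.ndarray:
    """Uniform non-overlapping placement of k CG dimers in `length` bases.

    Standard combinatorial bijection: choose k of length−k slots, then
    shift the i-th chosen slot by i. Start positions are sorted and differ
    by ≥ 2, so placed dimers never overlap.
    """
    if k == 0:
        return np.empty(0, dtype=np.int64)
    slots = np.sort(rng.choice(length - k, size=k, replace=False))
    return slots + np.arange(k)


def _fill_letters(
    rng: np.random.Generator, length: int, cpg_starts: np.ndarray, n_strong_fill: int
) -> str | None:
    """Write CG dimers, then assign free positions strong (G/C) or weak (A/T).

    Letters are chosen left to right; a G is never written immediately
    after a C outside the placed dimers, so the placed CpGs are the only
    CpGs in the output. Returns None on (theoretical) failure so the caller
    can restart with a fresh random stream.
    """
    seq = np.empty(length, dtype="<U1")
    occupied = np.zeros(length, dtype=bool)
    for s in cpg_starts:
        seq[s] = "C"
        seq[s + 1] = "G"
        occupied[s] = occupied[s + 1] = True

    free = np.flatnonzero(~occupied)
    strong_mask = np.zeros(length, dtype=bool)
    if n_strong_fill:
        strong_at = rng.choice(free, size=n_strong_fill, replace=False)
        strong_mask[strong_at] = True

    # Pre-draw the random letter choices for the free positions.
    strong_draw = rng.random(length)
    weak_draw = rng.random(length)
    for i in free:
        if strong_mask[i]:
            # Placing G after a C would create a new CpG: force C there.
            if i > 0 and seq[i - 1] == "C":
                seq[i] = "C"
            else:
                seq[i] = "G" if strong_draw[i] < 0.5 else "C"
        else:
            seq[i] = "A" if weak_draw[i] < 0.5 else "T"
    return "".join(seq)


def design_sequence(spec: DesignSpec, max_restarts: int = 10) -> NucleotideSequence:
    """Generate a random sequence meeting the spec's constraints exactly.

    The output has exactly ``spec.length`` bases, exactly ``spec.cpg_count``
    CpG dinucleotides (none besides the placed ones) and exactly
    ``spec.gc_bases`` G+C bases. Identical spec and seed reproduce the
    identical sequence.

    Procedure: (1) draw the CpG start positions uniformly among all
    non-overlapping placements; (2) write CG at each; (3) distribute the
    remaining strong bases over free positions and assign letters left to
    right such that no new CpG can arise; (4) verify every constraint and
    restart with the next random stream on failure, up to ``max_restarts``.
    """
    spec.validate()
    n_strong_fill = spec.gc_bases - 2 * spec.cpg_count
    seed_seq = np.random.SeedSequence(spec.seed)
    for child in seed_seq.spawn(max_restarts):
        rng = np.random.default_rng(child)
        starts = _place_cpg_starts(rng, spec.length, spec.cpg_count)
        bases = _fill_letters(rng, spec.length, starts, n_strong_fill)
        if bases is None:
            continue
        if (
            len(bases) == spec.length
            and count_cpg(bases) == spec.cpg_count
            and bases.count("G") + bases.count("C") == spec.gc_bases
        ):
            return NucleotideSequence(spec.label, bases)
    raise GenerationError(
        f"failed to satisfy constraints after {max_restarts} restarts "
        f"(spec: {spec})"
    )


def design_tiled_sequence(
    spec: DesignSpec, tile: int, max_tile_retries: int = 64
) -> NucleotideSequence:
    """Design a sequence as a concatenation of per-tile exact designs.

    Every ``tile``-bp segment individually carries round(tile × density/100)
    CpGs and round(gc_target × tile) G+C bases, so any scan window aligned
    to the tiling sees the target composition exactly — a plain
    :func:`design_sequence` guarantees only the sequence-wide totals, and
    its uniform CpG placement lets individual windows fluctuate. Tiles are
    redrawn when the junction with the previous tile would create an extra
    CpG, so the per-tile CpG count is exact under boundary-straddling
    window counting too.

    ``spec.length`` must be a multiple of ``tile``.
    """
    spec.validate()
    if spec.length % tile:
        raise InfeasibleSpecError(
            f"length {spec.length} is not a multiple of tile {tile}"
        )
    n_tiles = spec.length // tile
    tile_density = spec.cpg_per_100bp
    parts: list[str] = []
    for i, child in enumerate(np.random.SeedSequence(spec.seed).spawn(n_tiles)):
        for attempt, grandchild in enumerate(child.spawn(max_tile_retries)):
            tile_spec = DesignSpec(
                length=tile,
                gc_target=spec.gc_target,
                cpg_per_100bp=tile_density,
                seed=int(grandchild.generate_state(1)[0] % 2**31),
                label=f"{spec.label}_tile{i}",
            )
            candidate = design_sequence(tile_spec)
            if not (parts and parts[-1][-1] == "C" and candidate.bases[0] == "G"):
                parts.append(candidate.bases)
                break
        else:
            raise GenerationError(
                f"could not draw tile {i} without a junction CpG after "
                f"{max_tile_retries} attempts"
            )
    return NucleotideSequence(spec.label, "".join(parts))


def design_report(seq: NucleotideSequence, spec: DesignSpec) -> DesignReport:
    """Recompute achieved composition and tabulate deviations from spec."""
    achieved = composition_stats(seq)
    gc_bases = round(achieved.gc_fraction * achieved.effective_length)
    return DesignReport(
        spec=spec,
        achieved=achieved,
        length_deviation=len(seq) - spec.length,
        cpg_deviation=achieved.n_cpg - spec.cpg_count,
        gc_bases_deviation=gc_bases - spec.gc_bases,
        gc_fraction_deviation=achieved.gc_fraction - spec.gc_target,
    )


def embed_with_flanks(
    island: NucleotideSequence,
    left: NucleotideSequence,
    right: NucleotideSequence,
    id: str | None = None,
) -> tuple[NucleotideSequence, list[int]]:
    """Concatenate left + island + right, reporting junction CpGs.

    A CpG straddling either junction (left ends in C and island starts
    with G, or island ends in C and right starts with G) is reported by
    the 0-based position of its C in the concatenated sequence; junction
    CpGs are reported, not forbidden.
    """
    for part, name in ((left, "left"), (island, "island"), (right, "right")):
        if len(part) == 0:
            raise ValueError(f"{name} sequence is empty")
    joined = left.bases + island.bases + right.bases
    junctions = []
    if left.bases[-1] == "C" and island.bases[0] == "G":
        junctions.append(len(left) - 1)
    if island.bases[-1] == "C" and right.bases[0] == "G":
        junctions.append(len(left) + len(island) - 1)
    out_id = id if id is not None else f"{left.id}+{island.id}+{right.id}"
    return NucleotideSequence(out_id, joined), junctions
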