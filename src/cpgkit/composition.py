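"""Base-composition metrics for DNA sequences.

All coordinates are 0-based, half-open. CpG dinucleotides are counted on
the plus strand only: the CpG site is self-complementary as a duplex, so
counting both strands would double every site. ``N`` bases are excluded
from the effective length and never match C or G.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Literal

__all__ = [
    "NucleotideSequence",
    "CompositionStats",
    "ProfileRecord",
    "CompositionProfile",
    "UndefinedCompositionError",
    "gc_fraction",
    "count_cpg",
    "cpg_per_100bp",
    "cpg_obs_exp",
    "composition_stats",
    "sliding_profile",
    "classify_cgi",
    "reverse_complement",
]

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class UndefinedCompositionError(ValueError):
    """Raised when a composition metric is undefined for the input.

    Examples: GC fraction of an empty or all-N sequence, or the
    observed/expected CpG ratio of a sequence with no C or no G.
    """


@dataclass(frozen=True)
class NucleotideSequence:
    """An identified DNA string over the alphabet {A, C, G, T, N}.

    Input is normalised to upper case; any character outside the alphabet
    raises ``ValueError``.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        normalized = self.bases.upper()
        invalid = set(normalized) - _ALPHABET
        if invalid:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters: "
                f"{sorted(invalid)}; allowed alphabet is A/C/G/T/N"
            )
        object.__setattr__(self, "bases", normalized)

    def __len__(self) -> int:
        return len(self.bases)

    def __iter__(self) -> Iterator[str]:
        return iter(self.bases)

    @property
    def effective_length(self) -> int:
        """Number of non-N bases."""
        return len(self.bases) - self.bases.count("N")

    def reverse_complement(self, id: str | None = None) -> "NucleotideSequence":
        return NucleotideSequence(
            id if id is not None else f"{self.id}_rc",
            self.bases.translate(_COMPLEMENT)[::-1],
        )


def reverse_complement(bases: str) -> str:
    """Reverse complement of a raw base string (N maps to N)."""
    return bases.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CompositionStats:
    """Summary composition of one sequence.

    ``cpg_obs_exp`` is ``None`` when undefined (no C or no G present).
    """

    gc_fraction: float
    n_cpg: int
    cpg_per_100bp: float
    cpg_obs_exp: float | None
    effective_length: int


def _coerce(seq: NucleotideSequence | str) -> str:
    if isinstance(seq, NucleotideSequence):
        return seq.bases
    return seq.upper()


def gc_fraction(seq: NucleotideSequence | str) -> float:
    """Fraction of non-N bases that are G or C.

    Raises
    ------
    UndefinedCompositionError
        If the sequence is empty or entirely N.
    """
    bases = _coerce(seq)
    eff = len(bases) - bases.count("N")
    if eff == 0:
        raise UndefinedCompositionError(
            "GC fraction undefined: sequence is empty or all N"
        )
    return (bases.count("G") + bases.count("C")) / eff


def count_cpg(seq: NucleotideSequence | str) -> int:
    """Number of CpG (5'-CG-3') dinucleotides on the plus strand.

    ``CG`` cannot overlap itself, so a plain substring count is exact.
    A sequence shorter than 2 bases has zero CpGs.
    """
    return _coerce(seq).count("CG")


def cpg_per_100bp(seq: NucleotideSequence | str) -> float:
    """CpG density per 100 bp of effective (non-N) length."""
    bases = _coerce(seq)
    eff = len(bases) - bases.count("N")
    if eff == 0:
        raise UndefinedCompositionError(
            "CpG density undefined: sequence is empty or all N"
        )
    return 100.0 * bases.count("CG") / eff


def cpg_obs_exp(seq: NucleotideSequence | str) -> float:
    """Observed/expected CpG ratio, Gardiner-Garden & Frommer convention.

    o/e = n_CpG × L / (n_C × n_G) with L the effective (non-N) length.
    The ratio corrects raw CpG density for overall base composition: a
    sequence whose CpGs occur exactly as often as its mononucleotide
    frequencies predict scores ~1.

    Raises
    ------
    UndefinedCompositionError
        If the sequence contains no C or no G.
    """
    bases = _coerce(seq)
    n_c = bases.count("C")
    n_g = bases.count("G")
    if n_c == 0 or n_g == 0:
        raise UndefinedCompositionError(
            "o/e CpG ratio undefined: sequence lacks C or G"
        )
    eff = len(bases) - bases.count("N")
    return bases.count("CG") * eff / (n_c * n_g)


def composition_stats(seq: NucleotideSequence | str) -> CompositionStats:
    """Full composition summary; o/e is None where undefined."""
    bases = _coerce(seq)
    eff = len(bases) - bases.count("N")
    if eff == 0:
        raise UndefinedCompositionError(
            "composition undefined: sequence is empty or all N"
        )
    n_cpg = bases.count("CG")
    n_c = bases.count("C")
    n_g = bases.count("G")
    oe = n_cpg * eff / (n_c * n_g) if n_c and n_g else None
    return CompositionStats(
        gc_fraction=(n_c + n_g) / eff,
        n_cpg=n_cpg,
        cpg_per_100bp=100.0 * n_cpg / eff,
        cpg_obs_exp=oe,
        effective_length=eff,
    )


@dataclass(frozen=True)
class ProfileRecord:
    """One window of a composition profile (0-based half-open)."""

    start: int
    end: int
    gc_percent: float
    cpg_count: int


@dataclass
class CompositionProfile:
    """Sliding-window composition profile of one sequence.

    ``records`` are sorted by start; each complete window spans exactly
    ``window_size`` bases. A CpG whose C sits on the last base of a window
    is assigned to that window (the window containing the C).
    """

    seq_id: str
    window_size: int
    step: int
    records: list[ProfileRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProfileRecord]:
        return iter(self.records)

    def to_rows(self) -> list[tuple[str, int, int, float, int]]:
        """Rows (seq_id, start, end, gc_percent, cpg_count) for TSV output."""
        return [
            (self.seq_id, r.start, r.end, r.gc_percent, r.cpg_count)
            for r in self.records
        ]


def _window_cpg_count(bases: str, start: int, end: int) -> int:
    # CpG belongs to the window containing its C: include the pair whose C
    # is at end-1 (G falls in the next window / beyond the slice).
    n = bases.count("CG", start, end)
    if end < len(bases) and bases[end - 1] == "C" and bases[end] == "G":
        n += 1
    return n


def sliding_profile(
    seq: NucleotideSequence, window_size: int, step: int
) -> CompositionProfile:
    """Windowed GC% and CpG-count profile along a sequence.

    Windows start at 0, step, 2·step, … and only complete windows
    (start + window_size ≤ length) are emitted. GC% is computed over the
    non-N bases of each window; an all-N window records ``nan``.

    A window longer than the sequence yields an empty profile with a
    warning rather than an error.
    """
    if window_size < 2:
        raise ValueError("window_size must be ≥ 2")
    if step < 1:
        raise ValueError("step must be ≥ 1")
    bases = seq.bases
    profile = CompositionProfile(seq.id, window_size, step)
    if window_size > len(bases):
        warnings.warn(
            f"window_size {window_size} exceeds sequence length {len(bases)}; "
            "profile is empty",
            stacklevel=2,
        )
        return profile
    for start in range(0, len(bases) - window_size + 1, step):
        end = start + window_size
        win = bases[start:end]
        eff = window_size - win.count("N")
        gc = (
            100.0 * (win.count("G") + win.count("C")) / eff
            if eff
            else float("nan")
        )
        profile.records.append(
            ProfileRecord(start, end, gc, _window_cpg_count(bases, start, end))
        )
    return profile


def classify_cgi(
    seq: NucleotideSequence,
    min_length: int = 200,
    min_gc: float = 0.50,
    min_oe: float = 0.6,
) -> bool:
    """Threshold CpG-island call: length, GC fraction and o/e all at or
    above their minima (defaults 200 bp / 0.50 / 0.6, the classical rule).

    An undefined o/e (no C or no G) classifies as non-CGI with a warning.
    """
    if min_length <= 0 or min_gc <= 0 or min_oe <= 0:
        raise ValueError("classification thresholds must be positive")
    if len(seq) < min_length:
        return False
    try:
        if gc_fraction(seq) < min_gc:
            return False
        return cpg_obs_exp(seq) >= min_oe
    except UndefinedCompositionError:
        warnings.warn(
            f"sequence {seq.id!r}: o/e undefined, classified as non-CGI",
            stacklevel=2,
        )
        return False
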