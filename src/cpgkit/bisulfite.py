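"""Bisulfite clone methylation calling.

Bisulfite treatment deaminates unmethylated cytosine to uracil (read as T
after PCR) while 5-methylcytosine resists conversion. Sanger-sequenced
clones of a converted amplicon therefore report methylation base by base:
at a CpG cytosine, C means methylated and T unmethylated. Cytosines
outside CpG context are essentially never methylated in mammalian somatic
and embryonic stem cells, so the fraction of non-CpG C positions read as
T measures the chemical conversion efficiency of each clone and serves as
quality control.

Clones are treated as top-strand reads spanning the full amplicon;
alignment is gapless with up to 5 bases of end-trimming slack. Clones
with conversion rate below 0.95 are excluded from summaries (reported,
not silently dropped).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cpgkit.composition import NucleotideSequence

__all__ = [
    "BisulfiteAmplicon",
    "CloneCall",
    "MethylationMatrix",
    "AlignmentError",
    "locate_sites",
    "call_clone",
    "call_clones",
    "summarize",
    "gc_vs_methylation",
    "DEFAULT_CONVERSION_THRESHOLD",
    "MAX_END_TRIM",
]

DEFAULT_CONVERSION_THRESHOLD = 0.95
MAX_END_TRIM = 5

METHYLATED = "M"
UNMETHYLATED = "U"
AMBIGUOUS = "X"


class AlignmentError(ValueError):
    """Clone could not be aligned to the amplicon reference."""


@dataclass(frozen=True)
class BisulfiteAmplicon:
    """An amplicon reference with its cytosine position sets.

    ``cpg_positions`` holds the 0-based positions of CpG cytosines on the
    plus strand; ``non_cpg_c_positions`` all remaining cytosines. The two
    sets are disjoint and every listed position carries a C.
    """

    reference: NucleotideSequence
    cpg_positions: tuple[int, ...]
    non_cpg_c_positions: tuple[int, ...]

    @property
    def n_sites(self) -> int:
        return len(self.cpg_positions)


def locate_sites(reference: NucleotideSequence) -> BisulfiteAmplicon:
    """Locate CpG and non-CpG cytosines on the plus strand of a reference."""
    if len(reference) == 0:
        raise ValueError("reference is empty")
    bases = reference.bases
    cpg, other = [], []
    for i, b in enumerate(bases):
        if b != "C":
            continue
        if i + 1 < len(bases) and bases[i + 1] == "G":
            cpg.append(i)
        else:
            other.append(i)
    return BisulfiteAmplicon(reference, tuple(cpg), tuple(other))


@dataclass(frozen=True)
class CloneCall:
    """Per-site calls and conversion QC for one clone.

    ``conversion_rate`` is None when the amplicon has no non-CpG C (QC is
    then impossible and the clone is flagged).
    """

    clone_id: str
    calls: tuple[str, ...]  # one of M/U/X per CpG site
    conversion_rate: float | None
    offset: int  # reference position where the clone alignment starts

    @property
    def qc_flag(self) -> bool:
        return self.conversion_rate is None


def _best_offset(ref: str, clone: str) -> int:
    """Best gapless placement of the clone along the reference.

    Scores bisulfite-aware identity (reference C may legitimately read as
    T) over every offset compatible with ≤ MAX_END_TRIM end-trimming.
    """
    span = len(ref) - len(clone)
    best, best_score = 0, -1
    for off in range(0, span + 1):
        score = sum(
            1
            for r, c in zip(ref[off : off + len(clone)], clone)
            if c == r or (r == "C" and c == "T")
        )
        if score > best_score:
            best, best_score = off, score
    return best


def call_clone(
    amplicon: BisulfiteAmplicon, clone: NucleotideSequence
) -> CloneCall:
    """Call methylation at every CpG site of one clone.

    At a CpG cytosine position: C → methylated, T → unmethylated, anything
    else (or a position outside the clone's aligned span) → ambiguous.
    The conversion rate is the fraction of covered non-CpG C positions
    read as T.

    Raises
    ------
    AlignmentError
        If the clone length differs from the reference by more than the
        end-trimming tolerance (5 bases).
    """
    ref = amplicon.reference.bases
    diff = len(ref) - len(clone)
    if diff < 0 or diff > MAX_END_TRIM:
        raise AlignmentError(
            f"clone {clone.id!r} length {len(clone)} vs reference {len(ref)}: "
            f"gapless alignment requires 0 ≤ reference − clone ≤ {MAX_END_TRIM}"
        )
    offset = 0 if diff == 0 else _best_offset(ref, clone.bases)
    covered = range(offset, offset + len(clone))

    def base_at(pos: int) -> str | None:
        return clone.bases[pos - offset] if pos in covered else None

    calls = []
    for pos in amplicon.cpg_positions:
        b = base_at(pos)
        if b == "C":
            calls.append(METHYLATED)
        elif b == "T":
            calls.append(UNMETHYLATED)
        else:
            calls.append(AMBIGUOUS)

    converted = unconverted = 0
    for pos in amplicon.non_cpg_c_positions:
        b = base_at(pos)
        if b == "T":
            converted += 1
        elif b == "C":
            unconverted += 1
    total = converted + unconverted
    rate = converted / total if total else None
    return CloneCall(clone.id, tuple(calls), rate, offset)


@dataclass
class MethylationMatrix:
    """Clones × CpG-sites call grid with conversion QC.

    ``calls`` is a DataFrame (rows clone_ids, columns CpG positions,
    values M/U/X). Clones failing conversion QC are kept in
    ``excluded`` and absent from ``calls``.
    """

    amplicon: BisulfiteAmplicon
    calls: pd.DataFrame
    conversion_rates: pd.Series
    excluded: list[CloneCall] = field(default_factory=list)

    @property
    def clone_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def site_percent_methylation(self) -> pd.Series:
        """Per-site % methylation, ambiguous calls excluded."""
        meth = (self.calls == METHYLATED).sum(axis=0)
        unmeth = (self.calls == UNMETHYLATED).sum(axis=0)
        denom = meth + unmeth
        return 100.0 * meth / denom.where(denom > 0)

    @property
    def clone_percent_methylation(self) -> pd.Series:
        meth = (self.calls == METHYLATED).sum(axis=1)
        unmeth = (self.calls == UNMETHYLATED).sum(axis=1)
        denom = meth + unmeth
        return 100.0 * meth / denom.where(denom > 0)

    @property
    def overall_percent(self) -> float:
        """Overall % methylation: methylated / (methylated + unmethylated)."""
        meth = int((self.calls == METHYLATED).sum().sum())
        unmeth = int((self.calls == UNMETHYLATED).sum().sum())
        if meth + unmeth == 0:
            return float("nan")
        return 100.0 * meth / (meth + unmeth)


def call_clones(
    amplicon: BisulfiteAmplicon,
    clones: Iterable[NucleotideSequence],
    conversion_threshold: float = DEFAULT_CONVERSION_THRESHOLD,
) -> MethylationMatrix:
    """Call every clone and assemble the QC-filtered methylation matrix.

    Clones whose conversion rate is defined and below the threshold are
    excluded from the matrix and listed in ``excluded``. Clones with an
    undefined rate (no non-CpG C in the amplicon) are retained but their
    QC flag is visible via a NaN conversion rate.
    """
    kept_rows: dict[str, tuple[str, ...]] = {}
    rates: dict[str, float] = {}
    excluded: list[CloneCall] = []
    for clone in clones:
        cc = call_clone(amplicon, clone)
        if cc.conversion_rate is not None and cc.conversion_rate < conversion_threshold:
            excluded.append(cc)
            continue
        kept_rows[cc.clone_id] = cc.calls
        rates[cc.clone_id] = (
            cc.conversion_rate if cc.conversion_rate is not None else float("nan")
        )
    calls = pd.DataFrame.from_dict(
        kept_rows, orient="index", columns=list(amplicon.cpg_positions)
    )
    return MethylationMatrix(
        amplicon=amplicon,
        calls=calls,
        conversion_rates=pd.Series(rates, dtype=float),
        excluded=excluded,
    )


def summarize(matrix: MethylationMatrix) -> pd.DataFrame:
    """Per-site summary table plus overall statistics.

    Returns a DataFrame with one row per CpG site (position,
    n_methylated, n_unmethylated, n_ambiguous, percent_methylation) and
    attrs ``overall_percent``, ``n_clones``, ``n_excluded``. An empty
    matrix (all clones failed QC) yields an empty table with a warning.
    """
    if matrix.calls.empty:
        warnings.warn("no clones passed conversion QC; summary is empty", stacklevel=2)
        out = pd.DataFrame(
            columns=[
                "position",
                "n_methylated",
                "n_unmethylated",
                "n_ambiguous",
                "percent_methylation",
            ]
        )
        out.attrs.update(
            overall_percent=float("nan"),
            n_clones=0,
            n_excluded=len(matrix.excluded),
        )
        return out
    meth = (matrix.calls == METHYLATED).sum(axis=0)
    unmeth = (matrix.calls == UNMETHYLATED).sum(axis=0)
    ambig = (matrix.calls == AMBIGUOUS).sum(axis=0)
    out = pd.DataFrame(
        {
            "position": matrix.calls.columns,
            "n_methylated": meth.values,
            "n_unmethylated": unmeth.values,
            "n_ambiguous": ambig.values,
            "percent_methylation": matrix.site_percent_methylation.values,
        }
    )
    out.attrs.update(
        overall_percent=matrix.overall_percent,
        n_clones=len(matrix.calls),
        n_excluded=len(matrix.excluded),
    )
    return out


def gc_vs_methylation(
    construct_summaries: Sequence[tuple[float, float]],
) -> tuple[pd.DataFrame, float]:
    """Relate construct G+C content to overall methylation.

    Input: (gc_percent, overall_percent_methylation) pairs, one per
    construct. Returns the table sorted by GC together with the midpoint
    of the largest methylation *drop* between adjacent GC values — an
    operational estimate of the base-composition threshold at which de
    novo DNA methylation switches off.
    """
    if len(construct_summaries) < 2:
        raise ValueError("need at least 2 constructs to locate a transition")
    table = (
        pd.DataFrame(construct_summaries, columns=["gc_percent", "percent_methylation"])
        .sort_values("gc_percent", kind="stable")
        .reset_index(drop=True)
    )
    drops = table["percent_methylation"].to_numpy()[:-1] - table[
        "percent_methylation"
    ].to_numpy()[1:]
    i = int(np.argmax(drops))
    midpoint = float(
        (table["gc_percent"].iloc[i] + table["gc_percent"].iloc[i + 1]) / 2.0
    )
    return table, midpoint
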