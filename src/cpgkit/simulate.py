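"""Seeded generators of synthetic test data with known ground truth.

Three generators:

* synthetic genomes — a background of controlled composition (built with
  the constrained designer, so background G+C and CpG counts are exact)
  with composition blocks planted at declared coordinates, plus a truth
  table of the plants in BED-style 0-based half-open coordinates;
* bisulfite clone sets — clones drawn from per-site methylation
  probabilities and a conversion efficiency, plus the per-draw truth;
* feature/signal interval sets with tunable rank dependence between a
  feature and the signal.

Every generator is fully determined by its seed: identical spec and seed
reproduce byte-identical output. Child streams are spawned from the seed
so plants, chromosomes and clones draw from independent substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cpgkit.bisulfite import BisulfiteAmplicon
from cpgkit.composition import NucleotideSequence
from cpgkit.design import DesignSpec, design_sequence, design_tiled_sequence

__all__ = [
    "GenomePlantSpec",
    "CloneSimSpec",
    "synth_genome",
    "synth_clones",
    "synth_signal_intervals",
]


@dataclass(frozen=True)
class GenomePlantSpec:
    """A synthetic genome: background composition plus planted blocks.

    ``plants`` maps each planted block to (chrom, start, DesignSpec);
    plants must fit their chromosome and must not overlap one another.
    The background is generated with the constrained designer at
    ``background_gc`` / ``background_cpg_per_100bp``, so its composition
    is exact rather than merely expected.
    """

    chromosome_lengths: dict[str, int]
    background_gc: float = 0.40
    background_cpg_per_100bp: float = 1.0
    plants: tuple[tuple[str, int, DesignSpec], ...] = ()
    seed: int = 0
    tile_plants: int | None = None  # build plants per-tile exact (e.g. 100)

    def validate(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, spec in self.plants:
            if chrom not in self.chromosome_lengths:
                raise ValueError(f"plant on unknown chromosome {chrom!r}")
            end = start + spec.length
            if start < 0 or end > self.chromosome_lengths[chrom]:
                raise ValueError(
                    f"plant [{start}, {end}) out of range on {chrom!r} "
                    f"(length {self.chromosome_lengths[chrom]})"
                )
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, spans in by_chrom.items():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping plants on {chrom!r}: [{s1},{e1}) and [{s2},{e2})"
                    )


def synth_genome(
    spec: GenomePlantSpec,
) -> tuple[dict[str, NucleotideSequence], pd.DataFrame]:
    """Generate the genome and its truth table of planted blocks.

    Returns (chrom → sequence, truth DataFrame with columns chrom, start,
    end, label). Plants are spliced over the background at their declared
    coordinates. A CpG arising at a splice junction would perturb the
    composition of the adjacent window, so the background base on the
    non-plant side of any would-be junction CpG is flipped to A; the
    background composition is exact up to these single-base repairs.

    With ``tile_plants`` set, each plant is built from per-tile exact
    designs (see :func:`cpgkit.design.design_tiled_sequence`) so that
    every scan window of that size inside the plant carries the plant's
    target composition exactly — the construction plant-and-recover
    scanner tests rely on.
    """
    spec.validate()
    seed_seq = np.random.SeedSequence(spec.seed)
    chrom_seeds = seed_seq.spawn(len(spec.chromosome_lengths))

    genome: dict[str, NucleotideSequence] = {}
    for (chrom, length), child in zip(
        spec.chromosome_lengths.items(), chrom_seeds
    ):
        bg_spec = DesignSpec(
            length=length,
            gc_target=spec.background_gc,
            cpg_per_100bp=spec.background_cpg_per_100bp,
            seed=int(child.generate_state(1)[0] % 2**31),
            label=chrom,
        )
        genome[chrom] = design_sequence(bg_spec)

    truth_rows = []
    for chrom, start, plant_spec in spec.plants:
        if spec.tile_plants is not None:
            plant = design_tiled_sequence(plant_spec, spec.tile_plants)
        else:
            plant = design_sequence(plant_spec)
        bg = list(genome[chrom].bases)
        end = start + plant_spec.length
        # repair would-be junction CpGs on the background side
        if start > 0 and bg[start - 1] == "C" and plant.bases[0] == "G":
            bg[start - 1] = "A"
        if end < len(bg) and plant.bases[-1] == "C" and bg[end] == "G":
            bg[end] = "A"
        genome[chrom] = NucleotideSequence(
            chrom, "".join(bg[:start]) + plant.bases + "".join(bg[end:])
        )
        truth_rows.append(
            {"chrom": chrom, "start": start, "end": end, "label": plant_spec.label}
        )
    truth = pd.DataFrame(truth_rows, columns=["chrom", "start", "end", "label"])
    return genome, truth


@dataclass(frozen=True)
class CloneSimSpec:
    """Simulation of bisulfite clone reads from known parameters.

    ``site_methylation_probs`` gives the Bernoulli methylation probability
    of each CpG site of the amplicon (one value per site, in order);
    ``conversion_efficiency`` is the probability that any unmethylated
    cytosine (CpG or not) is converted to T.
    """

    amplicon: BisulfiteAmplicon
    site_methylation_probs: tuple[float, ...]
    conversion_efficiency: float = 0.99
    n_clones: int = 20
    seed: int = 0

    def validate(self) -> None:
        if len(self.site_methylation_probs) != self.amplicon.n_sites:
            raise ValueError(
                f"{len(self.site_methylation_probs)} probabilities for "
                f"{self.amplicon.n_sites} CpG sites"
            )
        if not all(0.0 <= p <= 1.0 for p in self.site_methylation_probs):
            raise ValueError("methylation probabilities must lie in [0, 1]")
        if not 0.0 <= self.conversion_efficiency <= 1.0:
            raise ValueError("conversion_efficiency must lie in [0, 1]")


def synth_clones(
    spec: CloneSimSpec,
) -> tuple[list[NucleotideSequence], pd.DataFrame]:
    """Simulate clone reads and return them with the per-draw truth table.

    For each clone and CpG site, methylation is drawn Bernoulli(p_site).
    Unmethylated CpG cytosines and all non-CpG cytosines convert to T
    with probability ``conversion_efficiency``; methylated cytosines never
    convert. The truth table records every methylation draw (columns
    clone_id, position, methylated).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ref = spec.amplicon.reference.bases
    probs = np.asarray(spec.site_methylation_probs)
    clones: list[NucleotideSequence] = []
    truth_rows = []
    for c in range(spec.n_clones):
        clone_id = f"clone_{c:03d}"
        read = list(ref)
        methylated = rng.random(len(probs)) < probs
        for pos, meth in zip(spec.amplicon.cpg_positions, methylated):
            truth_rows.append(
                {"clone_id": clone_id, "position": pos, "methylated": bool(meth)}
            )
            if not meth and rng.random() < spec.conversion_efficiency:
                read[pos] = "T"
        for pos in spec.amplicon.non_cpg_c_positions:
            if rng.random() < spec.conversion_efficiency:
                read[pos] = "T"
        clones.append(NucleotideSequence(clone_id, "".join(read)))
    truth = pd.DataFrame(truth_rows, columns=["clone_id", "position", "methylated"])
    return clones, truth


def synth_signal_intervals(
    n: int,
    dependence_strength: float,
    seed: int,
    feature: str = "cpg_density",
) -> pd.DataFrame:
    """Interval set with tunable feature → signal dependence.

    Lengths are log-normal around CGI scale (~200–2000 bp), CpG densities
    uniform on [2, 12] per 100 bp. The signal is
    ``exp(dependence_strength · z(feature) + ε)`` with standard-normal ε,
    so it is positive, monotone in the feature, and its rank correlation
    with the feature rises from ~0 (dependence 0) towards 1 as the
    dependence grows.
    """
    if n < 4:
        raise ValueError("need n ≥ 4 intervals")
    rng = np.random.default_rng(seed)
    lengths = np.clip(rng.lognormal(mean=6.3, sigma=0.6, size=n), 200, 5000).astype(
        np.int64
    )
    density = rng.uniform(2.0, 12.0, size=n)
    starts = rng.integers(0, 10_000_000, size=n)
    chosen = density if feature == "cpg_density" else lengths.astype(float)
    z = (chosen - chosen.mean()) / (chosen.std() or 1.0)
    signal = np.exp(dependence_strength * z + rng.standard_normal(n))
    return pd.DataFrame(
        {
            "chrom": ["chrS"] * n,
            "start": starts,
            "end": starts + lengths,
            "cpg_density": density,
            "signal": signal,
        }
    )
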