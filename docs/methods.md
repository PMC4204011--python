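# Methods

## Background and scope

CpG islands (CGIs) are short genomic stretches (~200–2000 bp) that combine
elevated G+C content (~65% against a bulk-genome ~40%) with a high density
of the CpG dinucleotide, which is otherwise depleted ~5-fold in vertebrate
genomes. Because length, G+C content and CpG density are entangled in
natural sequences, dissecting which of them drives CGI chromatin biology
requires *synthetic* sequences in which each property can be set
independently. cpgkit provides the computational side of that programme:
exact-composition sequence design, composition metrics and profiles,
windowed genome scans for naturally occurring atypical-composition
domains, bisulfite clone methylation calling, and interval statistics that
relate composition features to chromatin signal.

## Composition metrics

* **G+C fraction** — (G+C)/effective length, where the effective length
  excludes N bases. N never counts as C or G.
* **CpG count** — occurrences of 5'-CG-3' on the plus strand. The CpG
  site is self-complementary as a duplex, so plus-strand counting covers
  both strands; counting both would double every site. `CG` cannot
  overlap itself, so a substring count is exact.
* **Observed/expected CpG ratio** — the Gardiner-Garden & Frommer form
  o/e = n_CpG · L / (n_C · n_G). This normalises CpG density by the count
  expected from mononucleotide frequencies; uniform-random DNA scores ~1
  regardless of GC (verified by simulation in the test suite). The
  alternative convention (windowed Takai–Jones-style evaluation) differs
  only at whole-sequence scale by the window scheme; we compute o/e on
  the full sequence handed in.
* **CGI classifier** — length ≥ 200 bp, GC ≥ 0.50, o/e ≥ 0.6 (the
  classical thresholds), all configurable.
* **Coordinates** are 0-based half-open everywhere, including BED output.
* **Window boundary rule** — a CpG belongs to the window containing its C.
  This keeps window CpG counts additive across a tiling (each CpG counted
  exactly once) at the cost of letting a window's count depend on one base
  beyond its right edge.

Degenerate inputs: empty or all-N sequences have undefined composition
and raise `UndefinedCompositionError`; a sequence lacking C or G has an
undefined o/e (raised from `cpg_obs_exp`, classified non-CGI with a
warning in `classify_cgi`).

## Constrained design

`design_sequence` meets its three constraints *exactly*: the emitted
sequence has exactly `length` bases, exactly `round(length·density/100)`
CpGs (and no accidental extras) and exactly `round(gc_target·length)`
G+C bases. Exactness is a deliberate choice: a "~1 per 10 bp" target is
resolved to a hard count so that every downstream assertion (tests,
scans, reports) can be sharp; the residual GC rounding (≤ half a base) is
reported in the `DesignReport`.

Algorithm: (1) the CpG start positions are drawn uniformly over all
placements of k non-overlapping CG dimers in n bases, via the standard
bijection with k-subsets of n−k slots (minimum spacing 2 = non-overlap;
any clustering beyond that is left to chance); (2) the remaining strong
bases are assigned to uniformly chosen free positions; (3) letters are
written left to right, with one constraint: a strong fill position whose
left neighbour is C is written as C, never G. Since a CpG requires G
immediately after C, and weak fills are A/T, this rule makes new CpGs
impossible by construction — the repair/restart loop demanded by the
generation contract is retained as a verification safety net but is
unreachable. The slight excess of C-runs this induces is accepted; base
*counts* are unaffected. All randomness flows from the spec's seed
through `numpy.random.SeedSequence` (no global state); identical spec and
seed reproduce the identical sequence.

`design_tiled_sequence` builds a sequence as a concatenation of per-tile
exact designs (tiles redrawn if a junction would create a CpG). A plain
design guarantees only sequence-wide totals — with 100 CpGs placed
uniformly in 1 kb, an individual 100-bp window fluctuates around 10 and
falls below 5 with probability ~3% — so planted blocks for scanner
plant-and-recover tests are built tiled, making every aligned scan window
carry the target composition exactly.

Infeasible specs (2·cpg_count > length, GC budget below 2·cpg_count,
GC budget above length) raise `InfeasibleSpecError` naming the violated
inequality.

## Genome scanning

The genome is tiled into non-overlapping windows (default 100 bp) from
coordinate 0 of each chromosome; trailing partial windows are dropped,
and windows containing any N are flagged, never pass, and break block
runs (conservative). Blocks are maximal runs of adjoining passing windows
with total length ≥ `min_block_length`. Two presets mirror the searches
for endogenous atypical domains:

* **A+T-rich, CpG-rich** — pass iff GC < 0.50 and ≥ 5 CpGs per window
  (equivalently, windows with ≥50% GC or <5 CpGs are subtracted);
* **G+C-rich, CpG-poor** — pass iff GC ≥ 0.61 and ≤ 1 CpG per window.

`min_block_length` defaults to 500 bp (the relaxed setting); 1000 bp is
the CGI-dimension setting. Both presets use the same 100-bp tiling
machinery. Genome-scale counts of such blocks depend on assembly version
and window phase, so published counts are treated as indicative; the
scanner recomputes them for any FASTA supplied.

`random_fragments` samples equal-sized fragments uniformly over valid
start positions, weighting chromosomes by their number of valid starts —
the background cloud for a GC-vs-CpG-density scatter.

## Bisulfite calling

Bisulfite converts unmethylated C to T (via U); 5-methyl-C resists. At
each CpG cytosine of the amplicon reference: C → methylated,
T → unmethylated, anything else → ambiguous (excluded from every
denominator). Non-CpG cytosines are essentially unmethylated in the cell
types of interest, so the fraction of them read as T estimates per-clone
conversion efficiency; clones below 0.95 are excluded from summaries
(threshold a conventional choice, configurable). Clones are top-strand
gapless reads; up to 5 bases of end-trimming slack is absorbed by sliding
the clone along the reference to the best bisulfite-aware match (matching
C→T as identity). Amplicons with no non-CpG C cannot be QC'd; such
clones are retained with a NaN conversion rate rather than dropped.

`gc_vs_methylation` sorts construct-level (GC%, methylation%) pairs by GC
and reports the midpoint of the largest methylation drop between adjacent
GC values — an operationalisation of the sharp methylation transition
observed between ~50 and ~60% G+C. With only two constructs it reduces to
their midpoint.

## Interval statistics

* **Quartile binning** — intervals ranked by length or CpG density
  (stable sort; ties keep input order, lower ranks fill lower bins) and
  split into four equal-count bins (sizes differ by ≤1), reporting mean
  and median signal per bin. Equal-count, not equal-width: quartiles of
  the ranked list.
* **Overlap fraction** — fraction of query intervals sharing ≥ 1 bp with
  any subject interval ("coincide" operationalised as ≥1 bp overlap,
  half-open coordinates, so touching intervals do not overlap). Subject
  intervals are merged per chromosome and queries resolved by binary
  search; an all-pairs oracle cross-checks it in the tests.
* **Rank correlation** — Spearman's ρ via `scipy.stats.spearmanr`;
  undefined (raised) at zero variance or n < 3.

## Synthetic data generators

The generators produce the study conditions, not tunable benchmarks:

* **Genomes** — background at 40% G+C and 1 CpG/100 bp (bulk-genome-like
  composition), built with the constrained designer so background
  composition is exact rather than merely expected, with designed blocks
  planted at declared coordinates and a truth BED. Junction CpGs at
  splice boundaries would perturb the adjacent window, so the background
  base on the non-plant side is flipped to A (at most one base per
  junction). Plants for scanner tests use 100-bp tiled designs (above).
* **Clones** — per-site Bernoulli methylation, conversion applied to all
  unmethylated cytosines with the given efficiency (default 0.99,
  realistic for a good bisulfite experiment; 20 clones per construct),
  truth table of every draw.
* **Intervals** — CGI-scale log-normal lengths (~200–2000 bp), uniform
  CpG densities 2–12 per 100 bp, signal = exp(strength·z(feature) + ε)
  with standard-normal ε: positive, monotone in the feature, rank
  dependence rising from 0 with the strength parameter.

Every generator is a pure function of its seed (byte-identical reruns;
substreams spawned via `SeedSequence` so components are independent).

What the synthetic data does *not* model: repeat structure, isochores,
SNPs, sequencing error in clones (beyond conversion failure), PCR bias
between clones, and indels — so passing tests demonstrate algorithmic
correctness on composition-faithful inputs, not robustness to real-data
artefacts like clonal PCR duplicates or alignment gaps.

## Problem sizes and verification

The test suite verifies the designer on 1,000 random feasible specs
(lengths 100–2000 bp, GC 0.30–0.70, 0–12 CpG/100 bp), the scanner against
a brute-force window-and-run oracle on 100 random genomes (0.4–4 kb, 1–2
chromosomes each) plus 25 plant-and-recover genomes of 8 kb, bisulfite
recovery on 20 clones × ~30 sites against exact binomial 95% intervals,
and interval overlap against an all-pairs oracle on 1,000 random query
intervals. The whole suite runs in a few seconds. `scripts/acceptance.py`
regenerates the three construct classes at 1000 bp and recounts their
composition from the emitted bases.

## Known limitations

* The designer's fill rule slightly enriches C-runs relative to a
  uniform-among-valid-sequences sampler; dinucleotide frequencies other
  than CpG are not controlled.
* Gapless clone alignment cannot place reads with indels; such clones
  raise rather than mis-call.
* `cpg_obs_exp` on very short sequences is noisy by nature (integer
  counts); the classifier's 200-bp length gate is the guard.
* The scanner holds all windows of a chromosome in memory; fine for
  desk-scale FASTA and whole mouse chromosomes, but it makes no attempt
  at streaming.
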