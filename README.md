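# cpgkit

Toolkit for designing and analysing CpG-island-like DNA sequences.

CpG islands (CGIs) are short (~200–2000 bp) genomic stretches that combine
an elevated G+C content (~65%, against ~40% for the bulk genome) with a
high density of the CpG dinucleotide, and they mark most vertebrate
promoters. Length, G+C content and CpG density are entangled in natural
CGIs, so asking which property drives CGI chromatin behaviour requires
synthetic sequences in which each can be set independently — e.g. a
sequence with CGI-level CpG density on a bulk-genome A+T-rich backbone,
or the converse. cpgkit is aimed at researchers building or analysing
such constructs and at anyone profiling genome composition at CGI scale.

It provides:

* **`cpgkit.composition`** — GC fraction, plus-strand CpG counts and
  densities, the observed/expected CpG ratio
  (o/e = n_CpG · L / (n_C · n_G), Gardiner-Garden & Frommer), sliding
  window profiles, and a threshold CGI classifier
  (length ≥ 200 bp, GC ≥ 0.50, o/e ≥ 0.6 by default).
* **`cpgkit.design`** — random sequences satisfying *exact* joint
  constraints: exactly `round(gc·L)` G+C bases and exactly
  `round(L·density/100)` CpGs, no accidental extras, fully seeded.
* **`cpgkit.scan`** — 100-bp window tiling of a genome and detection of
  maximal blocks of windows with atypical composition (A+T-rich/CpG-rich:
  GC < 50% and ≥5 CpGs per window; G+C-rich/CpG-poor: GC ≥ 61% and ≤1 CpG
  per window), plus uniform random background fragments.
* **`cpgkit.bisulfite`** — per-CpG methylation calls from Sanger-style
  bisulfite clone reads (C = methylated, T = unmethylated), conversion
  efficiency QC from non-CpG cytosines, lollipop-style matrices, and the
  GC-vs-methylation transition locator.
* **`cpgkit.intervals`** — equal-count quartile binning of interval
  features (length, CpG density) against a signal such as ChIP-seq read
  counts, interval-overlap fractions, Spearman correlation.
* **`cpgkit.simulate`** — seeded generators of synthetic genomes with
  planted composition blocks (truth BED included), simulated bisulfite
  clone sets, and feature/signal interval sets.

## Worked example

Design a 1-kb CGI-like island — 65% G+C, one CpG per 10 bp — and verify
its composition:

```python
from cpgkit import DesignSpec, design_sequence, composition_stats, classify_cgi

spec = DesignSpec(length=1000, gc_target=0.65, cpg_per_100bp=10.0,
                  seed=1, label="artificial_cgi_1")
seq = design_sequence(spec)
st = composition_stats(seq)
print(f"{seq.id}: {len(seq)} bp")
print(f"GC fraction     : {st.gc_fraction:.3f}")
print(f"CpG count       : {st.n_cpg}")
print(f"CpG / 100 bp    : {st.cpg_per_100bp:.1f}")
print(f"CpG o/e ratio   : {st.cpg_obs_exp:.3f}")
print(f"CGI by rule     : {classify_cgi(seq)}")
```

prints

```
artificial_cgi_1: 1000 bp
GC fraction     : 0.650
CpG count       : 100
CpG / 100 bp    : 10.0
CpG o/e ratio   : 1.015
CGI by rule     : True
```

The constraints are met exactly (100 CpGs, 650 G+C bases in 1000 bp);
the o/e of ~1.0 says the CpGs occur as often as the base composition
predicts — unlike bulk genomic DNA, where CpG depletion pushes o/e to
~0.2. Swapping `gc_target=0.40` keeps the CpG density but yields an
A+T-rich backbone (o/e ≈ 2.5, since fewer C and G make the same CpG
count more surprising); `cpg_per_100bp=1.0` at 65% GC gives the
CpG-deficient converse.

The same is available from the shell:

```sh
cpgkit design --length 1000 --gc 0.65 --cpg-per-100bp 10 --seed 1 \
       --label artificial_cgi_1 --out island.fa --report island.tsv
cpgkit profile --fasta island.fa --out profile.tsv
cpgkit scan --fasta genome.fa --criteria gc-rich-cpg-poor --out blocks.bed
cpgkit fixtures genome --chrom-length 8000 --plant chr1:3000:1000:0.40:10 \
       --seed 11 --out-fasta genome.fa --out-bed truth.bed
cpgkit bisulfite --reference amp.fa --clones clones.fa \
       --out-matrix calls.tsv --out-summary sites.tsv
cpgkit bins --intervals intervals.tsv --feature cpg_density --out bins.tsv
```

See `docs/methods.md` for the models, conventions (0-based half-open
coordinates, plus-strand CpG counting, window boundary rule) and the
design of the generators.

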