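# iscensus

Census and characterization of bacterial insertion-sequence (IS) elements.

Insertion sequences are small (<2.5 kbp) mobile genetic elements that encode
only their own transposition machinery.  In host-restricted bacteria they
accumulate, decay and leave a quantifiable record: full-length versus
truncated copies, intact versus pseudogenized transposases, the presence or
absence of the target-site duplications (TSDs) created at insertion, and the
conservation of terminal inverted repeats (TIRs).  `iscensus` turns that
record into numbers.  It was built around the census of the obligate
intracellular amoeba symbiont *Amoebophilus asiaticus* 5a2, whose 1.88 Mbp
chromosome carries 354 transposase genes (23% of all genes) in 16 IS
families, and ships that per-family census as bundled reference data.

The package is a library first (importable API plus `examples/` scripts),
with a thin `iscensus` command-line wrapper for shell use.

## What it computes

* **Transposase detection** — six-frame ORF scan; candidates retained by a
  catalytic-motif hit (DDE triad at class-typical spacers, or the HuH/Y1
  signature of IS200-type elements) or ≥30% global amino-acid identity to a
  bundled exemplar per IS family class.
* **Family building** — copies sharing >80% nucleotide and amino-acid
  identity over ≥98% of their length are isoforms (single-linkage);
  full-length boundaries are delineated from cross-copy conservation,
  refined by terminal-inverted-repeat evidence; every genomic occurrence is
  then mapped (full-length ⇔ ≥98% consensus coverage).
* **Repeats** — exhaustive TIR search scored einverted-style (+3/−4),
  reported as matches/arm-length (e.g. `17/21`); exact flanking direct
  repeats of 2–12 bp as TSDs.
* **Translational recoding** — −1/+1 programmed ribosomal frameshifts
  (slippery heptamer `X XXY YYZ`, canonically `AAAAAAG`, with a stimulatory
  stem-loop), stop-codon read-through at weak `UGA-A` quartets, regulatory
  hairpins near element termini, and transframe protein merging.
* **Census statistics** — genome totals and per-family rows (copy counts,
  identity ranges, GC, IR/DR observations), with half-up integer
  percentages.
* **Genome context** — cumulative GC skew with origin/terminus calling and
  a major-shift count (a stability signal: 2 = regular, more = rearranged),
  plus screening for full-length copies with a co-oriented downstream gene
  within 300 bp (read-through transcription candidates).
* **Virtual Southern blot** — restriction digest (Eco32I/HindIII bundled),
  probe-to-fragment band patterns, and pattern comparison at 5% gel
  resolution to detect transposition between genome states.
* **Synthetic genomes** — a generator that plants IS families with full
  ground truth (boundaries, TSDs, divergence, broken transposases, recoding
  signals, a two-segment GC-skew signature), so the whole pipeline is
  testable without external data.

## Worked example

```bash
$ iscensus simulate --seed 3 --background-len 400000 --out g.fasta --truth t.tsv
wrote g.fasta (589446 bp) and t.tsv (265 planted copies)
$ iscensus scan --genome g.fasta --out-prefix demo
16 families, 122 full + 143 partial copies, 188248 bp IS (32% of genome)
$ iscensus skew --genome g.fasta --out skew.tsv
ori=0 ter=297000 major_shifts=2
$ iscensus southern --genome g.fasta --copies demo.copies.tsv --family ISSyn1 --out bands.tsv
27 bands
```

The simulated chromosome plants the bundled reference census (16 families,
122 full-length and 143 partial copies); the scan recovers every family and
copy count, writes `demo.copies.tsv` / `demo.families.tsv` /
`demo.census.tsv` / `demo.gff3`, and the skew profile shows the regular
two-shift origin/terminus pattern of an unrearranged chromosome.  From
Python, `examples/01_simulate_and_census.py` through
`examples/05_virtual_southern.py` walk the same capabilities with
commentary.

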