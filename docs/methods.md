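# Methods

This note records the models, parameter choices and known limitations of
`iscensus`, in the spirit of a methods section: everything below is what the
code actually does, and no empirical claim is made that the test suite or
`scripts/acceptance.py` does not itself compute.

## The census model

An IS element is modelled as a family: a consensus nucleotide sequence with
terminal inverted repeats (TIRs), one transposase gene unit (one or more
ORFs fused by a recoding event), and a set of genomic copies.  A copy is
*full-length* when its local alignment covers ≥98% of the family consensus
— the only coverage constant the underlying census methodology states (the
isoform rule's "at least 98% of their length") — and *partial* otherwise.
A full copy has an *intact transposase* when every ORF of the family
architecture retains a valid start codon and is free of premature stops
(the declared read-through stop excepted).  Copies are assigned to exactly
one family; cross-family overlap conflicts are resolved toward the
higher-identity, longer hit.

### Candidate transposases

Six-frame maximal ORFs (start codons ATG/GTG/TTG — Bacteroidetes-style
usage; the methodology this reimplements does not state start codons) of
≥80 aa are candidates when they either

* align at ≥30% global amino-acid identity to a bundled exemplar
  transposase (one synthetic exemplar per supported family class: IS1, IS5,
  IS982, IS110, IS200/IS605, IS481, IS1182, IS6, Tn3, IS3, YhgA-like), or
* carry a catalytic motif: a D..D..E triad with spacers inside the
  configured bounds (defaults 55–105 aa and 30–80 aa, bracketing the
  supported families; config-exposed because per-family spacer ranges are
  not stated anywhere authoritative), scored by flanking-context similarity
  to the exemplars (an unscored in-bounds triad occurs in nearly every long
  random protein, so a context score ≥1.0 of 3 is required); or an
  H-hydrophobic-H motif plus downstream catalytic tyrosine, consulted only
  for proteins <200 aa since IS200-type transposases are the shortest
  known.  A second histidine replaced by tyrosine still matches, flagged
  degenerate.

Identity is matches / aligned columns of a global alignment (BLOSUM62,
gap −11/−1 for protein; +2/−3, gap −5/−2 for DNA), terminal gaps excluded
from the count; coverage is aligned columns / max(length).  Exemplar hits
additionally require ≥30% coverage because the identity of a near-empty
alignment core is meaningless.

### Families and boundaries

Overlapping or near-adjacent (≤25 bp) same-strand candidates merge into
transposase units (the frameshift and read-through gene architectures).
Units cluster by single linkage at the isoform thresholds (>80% nt AND
>80% aa identity, ≥98% mutual coverage) — single linkage being the most
permissive reading of "shared identity", declared so results are
reproducible.  Clustering operates on transposase units rather than whole
elements because element boundaries are only known after delineation; a
config switch is left for element-level re-checking.

Boundary delineation emulates cross-copy alignment curation.  A probe (the
median-length unit of the cluster, 5'-trimmed by up to 120 bp because a
maximal ORF may begin at a start codon in the flank) is mapped genome-wide;
every hit anchors a member window in a rigid common coordinate system (the
generator's divergence model is substitution-only, so no gapped alignment
is needed — and a gapped aligner was observed to fabricate agreement
between random flanks).  Scanning outward from the shared core, the
boundary sits where the fraction of agreeing member pairs drops below 0.5
sustained over 15 columns, with three safeguards:

* members vote only while their trailing 13-column agreement with the
  majority over the full-length members stays ≥0.55, so truncated copies
  stop diluting conservation at their truncation point instead of dragging
  the boundary inward;
* the "full-length member" reference set is the largest clique of members
  that agree pairwise along the whole delineated span (≥0.82), ordered by
  mean agreement — long fragments that happen to contain the probe core
  cannot masquerade as full copies;
* when boundary support is thin (≤3 members) the extent may be refined by
  a terminal-inverted-repeat snap: a strong IR pair (einverted-style score
  ≥34) whose arms contain and extend the evidence-backed extent, accepted
  only when the extension is corroborated by copy sequence (or no
  corroboration is possible because a single full copy exists).  An IR
  already sitting at the current boundaries confirms them instead.

The consensus is the column majority over the full-member element
sequences (ties to the first member), re-oriented so the transposase reads
forward.  Classification follows the field's three criteria: transposase
homology (≥30% exemplar identity or a motif), flanking IRs — waived for
the IS110 and IS200/IS605 families, which lack them — and at least two
copies in the genome, full or partial.  (The copy criterion counts partial
copies; a one-full-copy family with six fragments is a legitimate family.)
Families are named `ISSyn1..N` in order of first genomic occurrence; the
prefix is configurable.

### Repeats

The TIR search is exhaustive over (left-arm start in the first 50 bp, arm
length 10–40, right-arm end in the last 50 bp), scored ungapped at +3
match / −4 mismatch against the reverse complement — the einverted
convention, adopted after a matches-only score was observed to creep arms
into random flanking sequence.  Candidates need ≥75% matches and are
reported as matches/arm-length.  The reported pair is simply the best
scorer; like the EMBOSS tools this replaces, biological validation of weak
hits is left to the analyst, so IR-less elements can still report a weak
chance pair (classification is unaffected: IR-exempt classes ignore it and
genuine families have real IRs).

Direct repeats (TSDs) must be exact: the longest k ∈ [2, 12] with
identical k-mers immediately left and right of the copy.  TSDs are copies
of a single insertion site; a mismatched pair is decay and reads as
absence.  With k ≥ 2 allowed, chance 2–3-mers occur; per-family DR lengths
are reported as the set of observed lengths.

### Copy mapping

Seeded k-mer scan (k = 12) against both strands, hits grouped by exact
diagonal, X-drop extension (match +1, mismatch −3, drop 12), runs on one
diagonal chained across ≤120 bp diverged walls, and extensions within
20 bp of a consensus end snapped to it when the remainder matches at ≥50%
(terminal mutations otherwise clip a few bp).  Hits need ≥80% identity
over ≥100 bp.  The diagonal model is exact under the substitution-only
divergence model; the generator's optional indel mode is not supported by
the mapper and is off by default.

### Recoding

Hairpin free energies come from a simplified bundled nearest-neighbour
stack table (Watson–Crick stacks at RNA-like 37 °C values, a flat
−0.8 kcal/mol for wobble-containing stacks, hairpin-loop penalties for
loops of 3–8, +1 per single stem mismatch, one mismatch allowed).  The
enumeration over all (start, stem ≥5, loop 3–8) decompositions is
exhaustive, so the reported minimum is exactly reproducible; absolute
values are not comparable to full secondary-structure packages, and the
thresholds (−3 stimulatory, −8 strong/terminator-like) are calibrated to
this table and config-exposed.

Calls, in priority order: **−1 frameshift** — an overlapping ORF pair in
−1 phase with a slippery heptamer (`X XXY YYZ`) in the overlap and a
stimulatory hairpin starting 2–12 nt downstream; the hairpin is optional
for `AAAAAAG`, the heptamer that is highly shift-prone in organisms with a
single tRNA-Lys (reported as a note, not computed).  **Read-through** — an
internal in-frame TGA followed by A, ≥50 codons of in-frame continuation,
no strong hairpin within 30 nt downstream, and (when copies are supplied)
the stop conserved in ≥80% of them.  **+1 frameshift** — an overlapping
pair in +1 phase with no −1 signal.  Read-through outranks bare +1
geometry because its evidence is specific while a +1-phase overlap can
arise from spurious ORFs.  Pair members must be ≥80 aa with the downstream
ORF extending past the upstream one.

## The synthetic generator

The generator *defines* the study conditions.  Defaults mirror the bundled
reference census: 16 families of 527–1483 bp in 1–24 full-length and 0–41
partial copies, IR arms of 0–34 bp with 0–5 planted mismatches, TSDs of
0–8 bp, per-family GC of 31.9–40.7%, ORF architectures single /
−1-overlap (hairpin-free for the ISCaa3 analog) / +1-overlap /
read-through, and broken-transposase counts from the printed intact
columns.  Per-copy divergence derives from each family's printed
conservation range (half the identity spread, capped at 0.05); a uniform
override exists.  The background is i.i.d. at 35% GC — the real genome's
composition model is unknown, so uniform i.i.d. is assumed — with a
deterministic G-rich/C-rich two-segment bias so the cumulative skew has
its minimum at position 0 (origin) and maximum at the midpoint (terminus);
this is a construction, not a replication simulation.  Copies are planted
at uniform non-overlapping positions on random strands, full copies
flanked by identical TSDs generated at insertion, partial copies as
uniform 20–90% fragments with unrecorded truncation points.  Divergence is
substitution-only so identity and coverage bookkeeping stays exact.
Consensus sequences are regenerated until free of Eco32I/HindIII sites (so
virtual-Southern probes never straddle a cut by construction) and, for
read-through elements, of strong hairpins right after the recoding stop.
Transposase proteins derive from the class exemplar at 25% substitution,
backtranslated with codon choice weighted toward the family GC.

What the generator does **not** emulate: indels and rearrangements within
copies, composite transposons, gene conversion between copies, GC
amelioration over time, host gene content (a separate gene-table generator
plants downstream-gene geometries), and real sequence-composition
structure.  Passing the recovery tests therefore demonstrates the
bookkeeping and the detection logic under the stated divergence model, not
performance on real genomes with indel-rich decay.

## Problem sizes and reproducibility

The end-to-end validation simulates the full reference census on a ~1 Mbp
background (~1.19 Mbp final chromosome, 265 planted copies) — the scale of
the real chromosome — and runs in well under a minute on one CPU.  The
acceptance script performs two such runs (table-derived divergence and
zero divergence) plus the census arithmetic and the virtual-Southern
comparisons.  All randomness flows from explicit integer seeds;
regeneration is byte-identical.

Across ten generator seeds at zero divergence, family counts,
classification and recoding recovery were 16/16 in every run; full-copy
boundary accuracy was within ±5 bp except for occasional 6–18 bp errors
confined to the structurally hardest families (a single full copy plus
fragments, or two full copies with one broken transposase), where boundary
evidence is intrinsically thin — the original curation of such elements
relied on database knowledge rather than cross-copy alignment.  At 5%
divergence the same families can deviate by a few tens of bp.

## Other design choices

* Coordinates are 0-based half-open internally, 1-based inclusive in GFF3;
  features wrapping a circular origin are emitted as two parts sharing an
  ID.  Ns never match in any repeat or alignment computation; ORFs
  containing N are discarded.
* Percentages round half-up to integers, which reproduces printed census
  parentheticals exactly from their numerator/denominator.
* The per-element GC "range" is reported only when full copies differ by
  ≥0.5 points, matching the conditional ranges of printed censuses.  The
  genome-wide average IS GC is reported per-element, per-copy and per-bp;
  none is asserted against any published average because the averaging
  weight behind such figures is typically unstated.
* GC-skew windows default to 10 kb / 1 kb step (no authoritative values
  exist; config-exposed).  "Major shift" is operationalized as a sign
  change of the 5-window-smoothed skew with both flanking runs longer than
  10 windows; the traditional judgment is visual, and this rule is
  declared, not claimed equivalent.
* Gel resolution for virtual-Southern comparison is 5% relative fragment
  length; cut offsets within recognition sites are conventions that cannot
  affect band calls at that resolution.
* The downstream-locus screen uses ≤300 bp gaps ("close" below 50 bp),
  same strand and orientation, nearest gene only.
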