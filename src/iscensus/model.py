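"""Domain types shared across the pipeline.

Coordinate convention: all internal coordinates are 0-based half-open
(``[start, end)``) on the forward strand of a replicon.  GFF3 output uses
1-based inclusive coordinates; :mod:`iscensus.io` performs the conversion.
On circular replicons a feature may wrap the origin, in which case it is
stored with ``end > replicon length`` and interpreted modulo the length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (Ns map to Ns)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """A replicon: identifier, uppercase DNA sequence, circularity flag."""

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"replicon {self.id!r}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"replicon {self.id!r}: non-DNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence ``[start, end)``; wraps the origin when circular."""
        n = len(self.seq)
        if 0 <= start <= end <= n:
            return self.seq[start:end]
        if not self.circular:
            raise IndexError(f"[{start}, {end}) outside linear replicon of length {n}")
        length = end - start
        if length > n:
            raise IndexError("interval longer than circular replicon")
        start %= n
        return (self.seq + self.seq)[start : start + length]


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval with strand."""

    replicon_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.replicon_id == other.replicon_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class OrfFeature:
    """A maximal open reading frame.

    ``frame`` is the 0-based frame index on the strand given by
    ``interval.strand``; ``stop_codon`` is ``None`` for open-ended ORFs that
    run off the end of a linear sequence.
    """

    interval: Interval
    frame: int
    protein: str
    start_codon: str
    stop_codon: Optional[str]

    def __post_init__(self):
        if len(self.interval) % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")


@dataclass(frozen=True)
class MotifHit:
    """Catalytic-motif hit in a transposase protein.

    ``kind`` is ``"DDE"`` (aspartate-aspartate-glutamate triad, regions
    N2/N3/C1) or ``"HuH_Y1"`` (His-hydrophobic-His plus catalytic Tyr of
    IS200-type Y1 transposases).  ``positions`` are 0-based protein indices.
    ``degenerate`` marks HuH hits where the second His is substituted.
    """

    kind: str
    positions: tuple
    spacers: tuple
    degenerate: bool = False
    score: float = 0.0

    def __post_init__(self):
        if list(self.positions) != sorted(self.positions):
            raise ValueError("motif positions must be strictly increasing")


@dataclass(frozen=True)
class InvertedRepeatPair:
    left_arm: Interval
    right_arm: Interval
    arm_len: int
    matches: int

    @property
    def notation(self) -> str:
        """Field-style notation, e.g. ``"17/21"`` = 17 matches over 21 bp arms."""
        return f"{self.matches}/{self.arm_len}"


@dataclass(frozen=True)
class DirectRepeat:
    """Target-site duplication: identical k-mer abutting both element ends."""

    seq: str
    left: Interval
    right: Interval


@dataclass
class ISCopy:
    """One genomic occurrence of an IS family."""

    family: str
    interval: Interval
    completeness: str  # "full" | "partial"
    nt_identity: float
    transposase_intact: bool = False
    dr: Optional[DirectRepeat] = None
    coverage: float = 1.0
    consensus_span: Optional[tuple] = None  # matched [start, end) on the consensus


@dataclass
class ISFamily:
    """A named IS element model (the ISCaaN analog)."""

    name: str
    family_class: str
    consensus_nt: str
    consensus_aa: str
    ir: Optional[InvertedRepeatPair] = None
    dr_len_observed: set = field(default_factory=set)
    n_orfs: int = 1
    recoding: str = "none"  # none | minus1 | plus1 | readthrough
    members: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.consensus_nt)


@dataclass(frozen=True)
class SlipperySite:
    """Slippery heptamer (X XXY YYZ) where the ribosome can shift frame."""

    heptamer: str
    position: int
    direction: int = -1


@dataclass(frozen=True)
class StemLoop:
    """RNA hairpin: stem length, loop length, 0-based start, free energy."""

    stem_len: int
    loop_len: int
    start: int
    dG: float
    mismatches: int = 0

    @property
    def span(self) -> int:
        return 2 * self.stem_len + self.loop_len


@dataclass
class RecodingCall:
    kind: str  # minus1 | plus1 | readthrough | none
    site: Optional[object] = None  # SlipperySite or stop-codon offset (int)
    hairpin: Optional[StemLoop] = None
    merged_protein_len: int = 0


@dataclass
class GeneFeature:
    """Minimal annotated gene used for downstream-locus screening."""

    id: str
    interval: Interval


@dataclass
class DownstreamLocus:
    is_copy: ISCopy
    gene: GeneFeature
    gap: int
    close: bool


@dataclass
class SkewProfile:
    window: int
    step: int
    positions: list
    values: list
    cumulative: list
    ori: int
    ter: int
    degenerate: bool = False


@dataclass(frozen=True)
class Fragment:
    interval: Interval

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass
class BandPattern:
    probe: str
    band_lengths: list  # sorted descending
    warnings: list = field(default_factory=list)
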