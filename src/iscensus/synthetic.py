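"""Synthetic genomes with planted IS elements and exhaustive ground truth.

The generator emulates the census substrate of an IS-rich, low-GC bacterial
chromosome: an i.i.d. background (~35% GC) with a deterministic two-segment
G/C bias (G-rich first half, C-rich second half) so the cumulative GC skew
has its minimum at the origin (position 0) and maximum at the terminus
(midpoint); and a configurable set of IS families, each with a consensus
carrying terminal inverted repeats, a transposase ORF architecture derived
from a bundled exemplar protein, and optional recoding signals (slippery
heptamer + stimulatory hairpin for -1 frameshifts, a TGA-A read-through
site, regulatory 5' hairpins).

Copies are planted without overlap at uniform positions: full-length copies
flanked by an identical target-site duplication (direct repeat), partial
copies as uniformly truncated fragments (20-90% of full length, truncation
points unrecorded in any conserved position).  Per-copy divergence is
substitution-only by default so identity and coverage bookkeeping stays
exact.  Identical inputs and seed give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Data import CodonTable

from .model import GenomeRecord, Interval, revcomp
from .orfs import Exemplar, load_exemplars
from .recoding import STOPS, fold_hairpin

ARCHITECTURES = ("single", "overlap_minus1", "overlap_plus1", "readthrough")

_TABLE = CodonTable.unambiguous_dna_by_id[11]
CODON_TO_AA: Dict[str, str] = dict(_TABLE.forward_table)
AA_TO_CODONS: Dict[str, List[str]] = {}
for codon, aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(aa, []).append(codon)

UTR5 = 20   # bp between left IR and the transposase start codon
UTR3 = 15   # minimum bp between the last stop codon and the right IR

# restriction sites kept out of consensus sequences so that virtual
# Southern probes never straddle a cut by construction
FORBIDDEN_SITES = ("GATATC", "AAGCTT")


class GenerationError(RuntimeError):
    pass


@dataclass
class FamilySpec:
    """Blueprint of one planted IS family."""

    name: str
    length: int
    n_full: int = 2
    n_partial: int = 0
    divergence: float = 0.0
    ir_arm: int = 18
    ir_mismatches: int = 0
    dr_len: int = 8
    orf_architecture: str = "single"
    gc: float = 0.37
    family_class: str = "IS5"
    n_broken: int = 0            # full copies with a planted premature stop
    hairpin: bool = True         # stimulatory hairpin for overlap_minus1
    regulatory_hairpin: bool = False

    def __post_init__(self):
        if self.n_full + self.n_partial < 1:
            raise ValueError(f"{self.name}: needs at least one copy")
        if not 0 <= self.divergence <= 0.2:
            raise ValueError(f"{self.name}: divergence outside [0, 0.2]")
        if self.ir_arm and not self.ir_arm < self.length / 2:
            raise ValueError(f"{self.name}: IR arm longer than half the element")
        if self.dr_len > 12:
            raise ValueError(f"{self.name}: direct repeat longer than 12 bp")
        if self.orf_architecture not in ARCHITECTURES:
            raise ValueError(f"{self.name}: unknown architecture "
                             f"{self.orf_architecture!r}")
        if self.n_broken > self.n_full:
            raise ValueError(f"{self.name}: n_broken exceeds n_full")


@dataclass
class ConsensusInfo:
    """Construction facts about a family consensus (element-local coords)."""

    seq: str
    orf_regions: List[Tuple[int, int]]      # start-codon..stop-codon spans, frame-exact
    slippery_pos: Optional[int] = None      # first base of the heptamer
    readthrough_pos: Optional[int] = None   # first base of the internal TGA
    hairpin_start: Optional[int] = None
    orf_start: int = 0


@dataclass
class GroundTruthCopy:
    family: str
    interval: Interval
    completeness: str                        # "full" | "partial"
    truncation: Optional[Tuple[int, int]]    # consensus span of a fragment
    identity: float
    dr_seq: Optional[str]
    transposase_intact: bool


@dataclass
class GroundTruth:
    copies: List[GroundTruthCopy] = field(default_factory=list)
    ori: int = 0
    ter: int = 0
    consensus: Dict[str, ConsensusInfo] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# consensus construction


def _codon_weights(codons: Sequence[str], gc: float) -> np.ndarray:
    pg = gc / 2.0
    pa = (1.0 - gc) / 2.0
    w = np.array([
        np.prod([pg if b in "GC" else pa for b in c]) for c in codons
    ])
    return w / w.sum()


def _encode(protein: str, gc: float, rng: np.random.Generator) -> List[str]:
    """Backtranslate with codon usage biased toward the target GC."""
    out = []
    for aa in protein:
        codons = AA_TO_CODONS.get(aa)
        if codons is None:
            codons = AA_TO_CODONS["L"]
        out.append(rng.choice(codons, p=_codon_weights(codons, gc)))
    return out


def _random_dna(n: int, gc: float, rng: np.random.Generator) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p)) if n > 0 else ""


def _derive_protein(spec: FamilySpec, n_aa: int, rng: np.random.Generator,
                    exemplars: Sequence[Exemplar]) -> str:
    """Family protein: exemplar of the family class, mutated and resized."""
    ex = next((e for e in exemplars if e.family_class == spec.family_class), None)
    if ex is None:
        raise GenerationError(f"no exemplar for class {spec.family_class!r}")
    aas = list(ex.protein[:n_aa])
    alphabet = list("ARNDCQEGHILKMFPSTWYV")
    while len(aas) < n_aa:
        aas.append(alphabet[rng.integers(len(alphabet))])
    mask = rng.random(n_aa) < 0.25  # family-level divergence from the exemplar
    for i in np.nonzero(mask)[0]:
        aas[i] = alphabet[rng.integers(len(alphabet))]
    aas[0] = "M"
    return "".join(aas)


def _fix_minus1_frame(codons: List[str], lo: int, hi: int) -> None:
    """Remove stops in the -1 frame over codon range [lo, hi).

    A -1-frame codon is (c[i][2], c[i+1][0], c[i+1][1]); it can only be a
    stop when c[i] ends in T, and the third-position T->C change is always
    synonymous.
    """
    for i in range(lo, min(hi, len(codons) - 1)):
        if codons[i][2] == "T" and codons[i + 1][:2] in ("AA", "AG", "GA"):
            codons[i] = codons[i][:2] + "C"


def _fix_plus1_frame(codons: List[str], protein: List[str], lo: int, hi: int,
                     gc: float, rng: np.random.Generator) -> None:
    """Remove stops in the +1 frame over codon range [lo, hi).

    A +1-frame codon is (c[i][1], c[i][2], c[i+1][0]); stops require c[i]
    to end in TA or TG.  Prefer a synonymous replacement; methionine (ATG
    is its only codon) is swapped for leucine.
    """
    for i in range(lo, min(hi, len(codons) - 1)):
        if codons[i][1:] in ("TA", "TG") and codons[i + 1][0] in "AG":
            alts = [c for c in AA_TO_CODONS[protein[i]]
                    if c[1:] not in ("TA", "TG")]
            if alts:
                codons[i] = alts[int(rng.integers(len(alts)))]
            else:  # only M (ATG) has no safe synonym
                protein[i] = "L"
                codons[i] = "CTC"


HAIRPIN_NT = "GGCAGCCAAGCTGCC"  # stem 6 / loop 3 / stem 6 palindrome


def _consensus_single(spec, protein, rng) -> Tuple[List[str], ConsensusInfo]:
    codons = _encode(protein, spec.gc, rng)
    return codons + ["TAA"], ConsensusInfo(
        seq="", orf_regions=[(0, 3 * len(protein) + 3)])


def _consensus_readthrough(spec, protein, rng, n_codons) -> Tuple[List[str], ConsensusInfo]:
    # [M ... P[:j]] TGA [M P[j:]] TAA with the TGA followed by A (ATG)
    j = max(86, n_codons // 3)
    rest = n_codons - j - 3
    if rest < 86:
        raise GenerationError(
            f"{spec.name}: element too short for a read-through architecture")
    p1 = protein[:j]
    p2 = "M" + protein[j : j + rest - 1]
    codons = _encode(p1, spec.gc, rng) + ["TGA"] + _encode(p2, spec.gc, rng) + ["TAA"]
    info = ConsensusInfo(
        seq="",
        orf_regions=[(0, 3 * j + 3), (3 * j + 3, 3 * (j + 1 + len(p2)) + 3)],
        readthrough_pos=3 * j,
    )
    return codons, info


def _consensus_overlap(spec, protein, rng, n_codons, direction) -> Tuple[str, ConsensusInfo]:
    """Two overlapping ORFs joined by a -1 or +1 frameshift.

    Returns raw nucleotides (not codons) because the continuation runs in a
    shifted frame.
    """
    k = max(90, int(round(0.45 * n_codons)))
    protein = list(protein)
    m = k - 18  # orfB start codon planted here
    if m < 2:
        raise GenerationError(
            f"{spec.name}: element too short for an overlap architecture")
    if direction == -1:
        protein[m], protein[m + 1] = "E", "W"       # GAG+TGG => GTG in -1 frame
        protein[k - 3 : k] = ["L", "K", "K"]
        codons = _encode(protein[:k], spec.gc, rng)
        codons[m], codons[m + 1] = "GAG", "TGG"
        # CTA ends in the A that opens the heptamer, so the only slippery
        # 7-mer is A AAA AAG (an extra upstream A would shift it)
        codons[k - 3 : k] = ["CTA", "AAA", "AAG"]
        _fix_minus1_frame(codons, m, k)
        region1 = "".join(codons)
        # continuation in the -1 frame reuses the heptamer's final G
        tail_parts = ["AC"]                         # completes GAC (Asp)
        tail_len = 2
        if spec.hairpin:
            tail_parts.append("CAG")                # pad: hairpin starts +5
            tail_parts.append(HAIRPIN_NT)
            tail_len += 18
        tail_parts.append("CTAAAA")                 # Leu+Lys; TAA in frame 0 ends orfA
        tail_len += 6
        used = 3 * k + tail_len
        r = (3 * n_codons - used - 3) // 3
        if r < 54:
            raise GenerationError(
                f"{spec.name}: element too short for a -1 overlap architecture")
        rest = protein[k + 1 : k + 1 + r]
        while len(rest) < r:
            rest.append("A")
        codons2 = _encode("".join(rest), spec.gc, rng)
        nt = region1 + "".join(tail_parts) + "".join(codons2) + "TAA"
        orf_a_end = None  # located below: first frame-0 stop after the heptamer
        p = 3 * k
        while p + 3 <= len(nt):
            if nt[p : p + 3] in STOPS:
                orf_a_end = p + 3
                break
            p += 3
        if orf_a_end is None:
            raise GenerationError(f"{spec.name}: orfA failed to terminate")
        orf_b_start = 3 * m + 2
        info = ConsensusInfo(
            seq="",
            orf_regions=[(0, orf_a_end), (orf_b_start, len(nt))],
            slippery_pos=3 * k - 7,
            hairpin_start=3 * k + 5 if spec.hairpin else None,
        )
        return nt, info
    else:  # +1
        protein[m], protein[m + 1] = "S", "E"       # AGT+GAG => GTG in +1 frame
        codons = _encode(protein[:k], spec.gc, rng)
        codons[m], codons[m + 1] = "AGT", "GAG"
        _fix_plus1_frame(codons, protein, m, k, spec.gc, rng)
        region1 = "".join(codons)
        # filler base T at 3k; continuation codons start at 3k+1 with AAA
        # so frame 0 reads TAA and orfA terminates immediately
        used = 3 * k + 1
        r = (3 * n_codons - used - 3) // 3 - 1
        if r < 62:
            raise GenerationError(
                f"{spec.name}: element too short for a +1 overlap architecture")
        rest = protein[k + 1 : k + 1 + r]
        while len(rest) < r:
            rest.append("A")
        codons2 = _encode("".join(rest), spec.gc, rng)
        nt = region1 + "T" + "AAA" + "".join(codons2) + "TAA"
        orf_b_start = 3 * m + 1
        info = ConsensusInfo(
            seq="",
            orf_regions=[(0, 3 * k + 3), (orf_b_start, len(nt))],
        )
        return nt, info


def _plant_ir(arm: str, mismatches: int, rng: np.random.Generator) -> str:
    """Right IR arm: reverse complement of the left with planted mismatches."""
    right = list(revcomp(arm))
    if mismatches:
        pos = rng.choice(len(right), size=min(mismatches, len(right)),
                         replace=False)
        for i in pos:
            alts = [b for b in "ACGT" if b != right[i]]
            right[i] = alts[int(rng.integers(3))]
    return "".join(right)


STRONG_HAIRPIN_BLOCK = "CC" + HAIRPIN_NT + "GG"  # 19 nt, dG well below -8


def make_consensus(spec: FamilySpec, seed: int,
                   exemplars: Optional[Sequence[Exemplar]] = None) -> str:
    """Build a family consensus sequence (see :func:`consensus_with_info`)."""
    return consensus_with_info(spec, seed, exemplars).seq


def consensus_with_info(spec: FamilySpec, seed: int,
                        exemplars: Optional[Sequence[Exemplar]] = None,
                        max_tries: int = 60) -> ConsensusInfo:
    """Consensus plus construction facts; deterministic in (spec, seed).

    Retries with derived seeds until the consensus is free of the forbidden
    restriction sites and (for read-through elements) of strong hairpins
    right after the recoding stop codon.
    """
    if exemplars is None:
        exemplars = load_exemplars()
    for attempt in range(max_tries):
        rng = np.random.default_rng((seed, attempt))
        info = _try_consensus(spec, rng, exemplars)
        if any(site in info.seq for site in FORBIDDEN_SITES):
            continue
        if spec.orf_architecture == "readthrough":
            stop_end = info.readthrough_pos + 3
            window = info.seq[stop_end : stop_end + 50]
            if len(window) >= 20 and fold_hairpin(window, max_dg=-8.0) is not None:
                continue
        return info
    raise GenerationError(f"{spec.name}: could not build a clean consensus")


def _try_consensus(spec: FamilySpec, rng, exemplars) -> ConsensusInfo:
    ir = spec.ir_arm
    u5 = UTR5 + (19 if spec.regulatory_hairpin else 0)
    coding_nt = spec.length - 2 * ir - u5 - UTR3
    n_codons = coding_nt // 3
    if n_codons < 110:
        raise GenerationError(
            f"{spec.name}: length {spec.length} too short for architecture "
            f"{spec.orf_architecture}")
    protein = _derive_protein(spec, n_codons, rng, exemplars)

    arch = spec.orf_architecture
    if arch == "single":
        codons, info = _consensus_single(spec, protein[: n_codons - 1], rng)
        body = "".join(codons)
    elif arch == "readthrough":
        codons, info = _consensus_readthrough(spec, protein, rng, n_codons)
        body = "".join(codons)
    else:
        body, info = _consensus_overlap(
            spec, protein, rng, n_codons, -1 if arch == "overlap_minus1" else +1)

    left_ir = _random_dna(ir, 0.5, rng) if ir else ""
    right_ir = _plant_ir(left_ir, spec.ir_mismatches, rng) if ir else ""
    u5_fill = _random_dna(u5 - (19 if spec.regulatory_hairpin else 0) - 3, spec.gc, rng)
    hairpin5 = STRONG_HAIRPIN_BLOCK if spec.regulatory_hairpin else ""
    # keep start-codon context clean and free of accidental upstream starts
    pre_start = "CCC"
    head = left_ir + hairpin5 + u5_fill + pre_start
    orf_start = len(head)
    tail_len = spec.length - orf_start - len(body) - ir
    if tail_len < 0:
        raise GenerationError(f"{spec.name}: architecture overflows the element")
    tail = _random_dna(tail_len, spec.gc, rng)
    seq = head + body + tail + right_ir
    assert len(seq) == spec.length
    info.seq = seq
    info.orf_start = orf_start
    info.orf_regions = [(orf_start + a, orf_start + b) for a, b in info.orf_regions]
    if info.slippery_pos is not None:
        info.slippery_pos += orf_start
    if info.hairpin_start is not None:
        info.hairpin_start += orf_start
    if info.readthrough_pos is not None:
        info.readthrough_pos += orf_start
    return info


# ---------------------------------------------------------------------------
# copy planting


def _transposase_ok(seq: str, info: ConsensusInfo, offset: int = 0) -> bool:
    """Does ``seq`` still encode the consensus ORF architecture intact?

    Checks, for every declared ORF region, that the start codon is valid
    and no premature stop appears (the declared read-through TGA excluded).
    Coordinates assume no indels between ``seq`` and the consensus.
    """
    starts = ("ATG", "GTG", "TTG")
    for a, b in info.orf_regions:
        a -= offset
        b -= offset
        if a < 0 or b > len(seq):
            return False
        if seq[a : a + 3] not in starts:
            return False
        for p in range(a, b - 3, 3):
            codon = seq[p : p + 3]
            if codon in STOPS:
                return False
    return True


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> Tuple[str, int]:
    if rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    mask = rng.random(len(arr)) < rate
    idx = np.nonzero(mask)[0]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in idx:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode(), len(idx)


def generate_genome(specs: Sequence[FamilySpec], background_len: int,
                    background_gc: float = 0.35, seed: int = 0,
                    replicon_id: str = "synthetic", circular: bool = True,
                    skew_bias: float = 0.3,
                    exemplars: Optional[Sequence[Exemplar]] = None,
                    ) -> Tuple[GenomeRecord, GroundTruth]:
    """Generate a genome with planted IS copies and full ground truth.

    The background is i.i.d. at ``background_gc`` with the G:C ratio biased
    by ``skew_bias`` toward G in the first half and C in the second half,
    so the cumulative GC skew rises to a maximum at the terminus (midpoint)
    and falls to a minimum at the origin (position 0).
    """
    rng = np.random.default_rng((seed, 1009))
    if exemplars is None:
        exemplars = load_exemplars()
    fam_seeds = [int(rng.integers(2 ** 31)) for _ in specs]

    blocks: List[tuple] = []   # (family, block_seq, kind, truncation, ident, dr, intact)
    consensus_infos: Dict[str, ConsensusInfo] = {}
    total_planted = 0
    for spec, fam_seed in zip(specs, fam_seeds):
        info = consensus_with_info(spec, fam_seed, exemplars)
        consensus_infos[spec.name] = info
        cons = info.seq
        for c in range(spec.n_full + spec.n_partial):
            is_full = c < spec.n_full
            if is_full:
                body = cons
                trunc = None
            else:
                frac = rng.uniform(0.2, 0.9)
                flen = max(60, int(round(frac * len(cons))))
                a = int(rng.integers(0, len(cons) - flen + 1))
                body = cons[a : a + flen]
                trunc = (a, a + flen)
            body, n_sub = _mutate(body, spec.divergence, rng)
            broken = is_full and c < spec.n_broken
            if broken:
                # premature stop early in the first ORF
                a0, _b0 = info.orf_regions[0]
                p = a0 + 30
                body = body[:p] + "TAA" + body[p + 3:]
            ident = 1.0 - (n_sub + (3 if broken else 0)) / len(body)
            intact = is_full and _transposase_ok(body, info)
            dr = None
            if is_full and spec.dr_len:
                dr = _random_dna(spec.dr_len, background_gc, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            blocks.append((spec.name, body, "full" if is_full else "partial",
                           trunc, ident, dr, intact, strand))
            total_planted += len(body) + 2 * (len(dr) if dr else 0)
    if total_planted >= background_len / 2:
        raise GenerationError("planted sequence exceeds half the background")

    # background with a two-segment skew signature
    half = background_len // 2

    def seg(n, g_frac):
        pg = background_gc * g_frac
        pc = background_gc - pg
        p = [(1 - background_gc) / 2, pc, pg, (1 - background_gc) / 2]
        return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                          size=n, p=p)

    bg = np.concatenate([seg(half, 0.5 + skew_bias / 2),
                         seg(background_len - half, 0.5 - skew_bias / 2)])
    background = bg.tobytes().decode()

    margin = 500
    n_blocks = len(blocks)
    if background_len - 2 * margin <= 4 * n_blocks:
        raise GenerationError("background too short to place all copies")
    points = np.sort(rng.choice(
        np.arange(margin, background_len - margin), size=n_blocks, replace=False))
    order = rng.permutation(n_blocks)

    pieces = []
    truth_copies = []
    cursor = 0
    offset = 0
    for point, bi in zip(points, order):
        fam, body, kind, trunc, ident, dr, intact, strand = blocks[bi]
        pieces.append(background[cursor:point])
        offset += point - cursor
        cursor = point
        oriented = body if strand == "+" else revcomp(body)
        if dr:
            pieces.append(dr)
            offset += len(dr)
        start = offset
        pieces.append(oriented)
        offset += len(oriented)
        end = offset
        if dr:
            pieces.append(dr)
            offset += len(dr)
        truth_copies.append(GroundTruthCopy(
            family=fam,
            interval=Interval(replicon_id, start, end, strand),
            completeness=kind, truncation=trunc, identity=round(ident, 4),
            dr_seq=dr, transposase_intact=intact,
        ))
    pieces.append(background[cursor:])
    offset += background_len - cursor
    seq = "".join(pieces)

    genome = GenomeRecord(id=replicon_id, seq=seq, circular=circular)
    # terminus: background midpoint mapped through the insertions
    inserted_before_half = sum(
        len(b[1]) + 2 * (len(b[5]) if b[5] else 0)
        for p, b in zip(points, (blocks[i] for i in order)) if p <= half
    )
    truth = GroundTruth(copies=truth_copies, ori=0,
                        ter=half + inserted_before_half,
                        consensus=consensus_infos)
    return genome, truth


_ARCH_BY_RECODING = {
    "none": "single",
    "minus1": "overlap_minus1",
    "plus1": "overlap_plus1",
    "readthrough": "readthrough",
}


def reference_family_specs(divergence: Optional[float] = None,
                           divergence_cap: float = 0.05) -> List[FamilySpec]:
    """Family specs mirroring the bundled reference census table.

    Lengths, copy numbers, IR/DR geometry, GC content, ORF architecture
    and broken-transposase counts follow the per-family reference rows.
    Per-copy divergence is derived from each family's printed full-copy
    conservation range (half the identity spread, capped at
    ``divergence_cap``) unless an explicit ``divergence`` is given.
    """
    from .census import load_reference_census

    specs = []
    for row in load_reference_census():
        ir = row["ir"]
        if ir == "0":
            arm, mism = 0, 0
        else:
            m, a = ir.split("/")
            arm, mism = int(a), int(a) - int(m)
        dr = row["dr"]
        dr_len = 0 if dr == "0" else int(dr.split("/")[0])
        if divergence is not None:
            div = divergence
        else:
            rng_s = row.get("full_range") or ""
            low = int(rng_s.split("-")[0]) if rng_s else 100
            div = min(divergence_cap, (1.0 - low / 100.0) / 2.0)
        specs.append(FamilySpec(
            name=row["element"], length=row["length_bp"],
            n_full=row["n_full"], n_partial=row["n_partial"],
            divergence=div, ir_arm=arm, ir_mismatches=mism, dr_len=dr_len,
            orf_architecture=_ARCH_BY_RECODING[row["recoding"]],
            gc=row["gc_pct"] / 100.0, family_class=row["family_class"],
            n_broken=row["n_full"] - row["n_intact"],
            hairpin=row.get("fs_hairpin", "1") == "1",
        ))
    return specs
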