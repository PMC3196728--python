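"""Six-frame ORF detection and transposase-motif recognition.

Candidate transposase genes are ORFs that either carry a catalytic motif
(DDE triad or the HuH/Y1 signature of IS200-type elements) or align to a
bundled exemplar transposase at >= 30% amino-acid identity.  The exemplar
set is synthetic (one representative per supported IS family class,
generated once and versioned with the package) and replaces a database
search with a deterministic equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from Bio.Seq import Seq

from .align import pairwise_identity
from .model import GenomeRecord, Interval, MotifHit, OrfFeature, revcomp

START_CODONS = ("ATG", "GTG", "TTG")  # Bacteroidetes-style start usage
STOP_CODONS = ("TAA", "TAG", "TGA")

#: default DDE spacer bounds (aa): N2..N3 then N3..C1
DDE_SPACER_BOUNDS = ((55, 105), (30, 80))

HYDROPHOBIC = set("AVLIMFWC")

FAMILY_CLASSES = (
    "IS1", "IS5", "IS982", "IS110", "IS200/IS605", "IS481", "IS1182",
    "IS6", "Tn3", "IS3", "YhgA-like",
)


def _scan_strand(seq: str, n: int, strand: str, circular: bool,
                 min_protein_len: int) -> List[OrfFeature]:
    """Maximal start-to-stop ORFs on one strand of a (possibly circular) seq."""
    s = seq if strand == "+" else revcomp(seq)
    scan = s + s if circular else s
    orfs = []
    for frame in range(3):
        start = None
        p = frame
        while p + 3 <= len(scan):
            codon = scan[p : p + 3]
            if codon in STOP_CODONS:
                if start is not None and start < n:
                    orfs.append((start, p + 3, frame, codon))
                start = None
            elif start is None and codon in START_CODONS:
                start = p
            p += 3
        if start is not None and start < n and not circular:
            end = frame + 3 * ((len(scan) - frame) // 3)
            if end > start:
                orfs.append((start, end, frame, None))
    out = []
    for start, end, frame, stop in orfs:
        if end - start > n:  # wrapped onto itself
            continue
        nt = scan[start:end]
        if "N" in nt:
            continue
        protein = str(Seq(nt[: len(nt) - (3 if stop else 0)]).translate())
        if len(protein) < min_protein_len:
            continue
        if strand == "+":
            iv_start, iv_end = start, end
        else:  # map back to forward coordinates
            iv_start, iv_end = n - end, n - start
            if iv_start < 0:  # wrapped the origin on the reverse strand
                iv_start += n
                iv_end += n
        out.append(
            OrfFeature(
                interval=Interval("", iv_start, iv_end, strand),
                frame=frame,
                protein=protein,
                start_codon=nt[:3],
                stop_codon=stop,
            )
        )
    return out


def find_orfs(genome: GenomeRecord, min_protein_len: int = 80) -> List[OrfFeature]:
    """All maximal ATG/GTG/TTG-initiated ORFs in six frames.

    ORFs are maximal per stop (first start codon after the previous stop);
    linear sequences may yield open-ended ORFs at their 3' ends
    (``stop_codon is None``).  Circular replicons are scanned across the
    origin; ORFs containing N are discarded.
    """
    n = len(genome.seq)
    orfs = (_scan_strand(genome.seq, n, "+", genome.circular, min_protein_len)
            + _scan_strand(genome.seq, n, "-", genome.circular, min_protein_len))
    fixed = [
        OrfFeature(
            interval=Interval(genome.id, o.interval.start, o.interval.end,
                              o.interval.strand),
            frame=o.frame, protein=o.protein,
            start_codon=o.start_codon, stop_codon=o.stop_codon,
        )
        for o in orfs
    ]
    fixed.sort(key=lambda o: (o.interval.start, o.interval.end, o.interval.strand))
    return fixed


# ---------------------------------------------------------------------------
# Catalytic motifs


@dataclass(frozen=True)
class Exemplar:
    """A bundled reference transposase for one IS family class."""

    name: str
    family_class: str
    protein: str
    dde: Optional[Tuple[int, int, int]] = None
    huh: Optional[Tuple[int, int, int, int]] = None


def load_exemplars(path=None) -> List[Exemplar]:
    """Load the bundled (or a user-supplied) exemplar FASTA.

    Headers carry ``class=`` and optional ``dde=i,j,k`` / ``huh=i,j,k,y``
    annotations giving 0-based motif positions in the protein.
    """
    if path is None:
        ref = resources.files("iscensus").joinpath("data/exemplars.faa")
        text = ref.read_text()
    else:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"exemplar file not found: {p}")
        text = p.read_text()
    exemplars = []
    name = None
    meta: Dict[str, str] = {}
    chunks: List[str] = []

    def flush():
        if name is None:
            return
        protein = "".join(chunks)
        dde = tuple(int(x) for x in meta["dde"].split(",")) if "dde" in meta else None
        huh = tuple(int(x) for x in meta["huh"].split(",")) if "huh" in meta else None
        exemplars.append(Exemplar(name=name, family_class=meta["class"],
                                  protein=protein, dde=dde, huh=huh))

    for line in text.splitlines():
        if line.startswith(">"):
            flush()
            fields = line[1:].split()
            name = fields[0]
            meta = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    flush()
    if not exemplars:
        raise FileNotFoundError("no exemplars parsed")
    return exemplars


def _context_score(protein: str, pos: int, exemplar: str, ex_pos: int,
                   flank: int = 5) -> float:
    """Fraction of matching residues in aligned +-flank windows."""
    matches = 0
    total = 0
    for d in range(-flank, flank + 1):
        i, j = pos + d, ex_pos + d
        if 0 <= i < len(protein) and 0 <= j < len(exemplar):
            total += 1
            if protein[i] == exemplar[j]:
                matches += 1
    return matches / total if total else 0.0


def detect_dde(protein: str,
               spacer_bounds: Tuple[Tuple[int, int], Tuple[int, int]] = DDE_SPACER_BOUNDS,
               exemplars: Optional[Sequence[Exemplar]] = None) -> Optional[MotifHit]:
    """Best D..D..E catalytic triad with in-bounds spacers, or None.

    Enumerates every (D, D, E) triple whose spacers fall inside
    ``spacer_bounds`` and scores each by flanking-context similarity to the
    DDE-annotated exemplars (sum of the three window identities).  Ties go
    to the leftmost triple.
    """
    if len(protein) < 100:
        return None
    (lo1, hi1), (lo2, hi2) = spacer_bounds
    d_pos = [i for i, aa in enumerate(protein) if aa == "D"]
    e_pos = [i for i, aa in enumerate(protein) if aa == "E"]
    refs = [ex for ex in (exemplars or []) if ex.dde is not None]
    best = None
    for i in d_pos:
        for j in d_pos:
            if not lo1 <= j - i <= hi1:
                continue
            for k in e_pos:
                if not lo2 <= k - j <= hi2:
                    continue
                score = 0.0
                if refs:
                    score = max(
                        _context_score(protein, i, ex.protein, ex.dde[0])
                        + _context_score(protein, j, ex.protein, ex.dde[1])
                        + _context_score(protein, k, ex.protein, ex.dde[2])
                        for ex in refs
                    )
                cand = (score, -(i + j + k), (i, j, k))
                if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                    best = cand
    if best is None:
        return None
    i, j, k = best[2]
    return MotifHit(kind="DDE", positions=(i, j, k), spacers=(j - i, k - j),
                    score=best[0])


def detect_huh_y1(protein: str) -> Optional[MotifHit]:
    """HuH motif (His-hydrophobic-His) plus catalytic Tyr, or None.

    The motif must start in the N-terminal half; a downstream tyrosine
    supplies the Y1 catalytic residue.  If the second histidine is replaced
    by tyrosine but the rest matches, the hit is flagged ``degenerate``
    (naturally occurring decayed copies show exactly this substitution).
    """
    half = len(protein) // 2
    for degenerate in (False, True):
        second = "Y" if degenerate else "H"
        for i in range(max(half - 2, 0)):
            if (protein[i] == "H" and protein[i + 1] in HYDROPHOBIC
                    and protein[i + 2] == second):
                y = protein.find("Y", i + 3)
                if y != -1:
                    return MotifHit(kind="HuH_Y1",
                                    positions=(i, i + 1, i + 2, y),
                                    spacers=(1, 1, y - (i + 2)),
                                    degenerate=degenerate)
    return None


@dataclass
class Candidate:
    """A retained transposase candidate ORF."""

    orf: OrfFeature
    motif: Optional[MotifHit]
    best_identity: float
    best_class: str
    nt: str = ""  # gene sequence, coding strand


def candidate_transposases(orfs: Sequence[OrfFeature],
                           exemplars: Sequence[Exemplar],
                           genome: Optional[GenomeRecord] = None,
                           identity_threshold: float = 0.30,
                           spacer_bounds=DDE_SPACER_BOUNDS,
                           dde_score_min: float = 1.0,
                           huh_max_len: int = 200,
                           min_coverage: float = 0.30) -> List[Candidate]:
    """Filter ORFs to transposase candidates (motif OR exemplar identity).

    An ORF is retained if it carries a convincing catalytic motif or aligns
    to any exemplar at >= ``identity_threshold`` global amino-acid
    identity; each retained ORF is annotated with the best-matching family
    class.  A DDE triad counts only when its flanking-context score against
    the exemplars reaches ``dde_score_min`` (in-bounds D..D..E triples occur
    in nearly every long random protein); the HuH/Y1 motif is consulted
    only for proteins shorter than ``huh_max_len`` aa, since IS200-type
    transposases are the shortest known.
    """
    if not exemplars:
        raise FileNotFoundError("exemplar set is empty or missing")
    out = []
    for orf in orfs:
        best_id, best_class = 0.0, ""
        for ex in exemplars:
            ident, cov = pairwise_identity(orf.protein, ex.protein, kind="aa")
            # a near-empty alignment core can show spuriously high identity;
            # demand that a reasonable fraction of the sequences aligned
            if cov >= min_coverage and ident > best_id:
                best_id, best_class = ident, ex.family_class
        motif = None
        motif_ok = False
        if len(orf.protein) >= 100:
            motif = detect_dde(orf.protein, spacer_bounds, exemplars)
            if motif is not None:
                motif_ok = motif.score >= dde_score_min
        if not motif_ok and len(orf.protein) < huh_max_len:
            huh = detect_huh_y1(orf.protein)
            if huh is not None:
                motif, motif_ok = huh, True
        if motif_ok or best_id >= identity_threshold:
            nt = ""
            if genome is not None:
                iv = orf.interval
                raw = genome.fetch(iv.start, iv.end)
                nt = raw if iv.strand == "+" else revcomp(raw)
            out.append(Candidate(orf=orf, motif=motif, best_identity=best_id,
                                 best_class=best_class, nt=nt))
    return out
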