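"""Element boundaries, terminal inverted repeats, direct repeats, copy mapping.

Boundary delineation emulates cross-copy alignment curation: columns inside
the element are conserved across copies while flanking columns are random
host DNA, so the element edge is where per-column conservation collapses.
Copy mapping is a seeded k-mer scan (k=12) with X-drop extension along the
diagonal, classifying hits as full-length (>=98% consensus coverage) or
partial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from .model import DirectRepeat, GenomeRecord, Interval, InvertedRepeatPair, ISCopy, revcomp
from .recoding import STOPS

log = logging.getLogger(__name__)

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def _seq_codes(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(vals: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """(codes, valid) for every k-window; windows containing N are invalid."""
    n = len(vals)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    m = n - k + 1
    codes = np.zeros(m, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + np.minimum(vals[j : m + j], 3)
    bad = (vals > 3).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    return codes, valid


class KmerIndex:
    """Sorted k-mer index of a genome for seeded scanning."""

    def __init__(self, seq: str, k: int = 12):
        self.k = k
        codes, valid = _kmer_codes(_seq_codes(seq), k)
        pos = np.nonzero(valid)[0]
        codes = codes[pos]
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = pos[order]

    def lookup(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        return self._pos[lo:hi]


# ---------------------------------------------------------------------------
# boundary delineation


@dataclass
class BoundaryResult:
    element_intervals: List[Interval]
    element_seqs: List[str]            # oriented (element-forward) sequences
    member_indices: List[int]          # anchor index behind each interval/seq
    bounds: Tuple[int, int]            # boundaries in core-anchored coords
    left_reason: str = "drop"          # "drop" | "exhausted" | "clamped"
    right_reason: str = "drop"
    left_support: int = 0              # active members just inside each edge
    right_support: int = 0
    warnings: List[str] = field(default_factory=list)


def _conservation(columns: List[List[int]]) -> np.ndarray:
    """Per-column fraction of agreeing member pairs (0 with <2 members)."""
    out = np.zeros(len(columns))
    for x, bases in enumerate(columns):
        n = len(bases)
        if n < 2:
            continue
        counts: Dict[int, int] = {}
        for b in bases:
            counts[b] = counts.get(b, 0) + 1
        agree = sum(c * (c - 1) // 2 for c in counts.values())
        out[x] = agree / (n * (n - 1) // 2)
    return out


def delineate_boundaries(genome: GenomeRecord, anchors: Sequence,
                         reach: int = 700, window: int = 15,
                         threshold: float = 0.5,
                         activity_threshold: float = 0.55,
                         n_reference: int = 0) -> BoundaryResult:
    """Element boundaries from cross-copy conservation around anchor hits.

    ``anchors`` are either plain :class:`Interval` objects (assumed to span
    the same homologous region, e.g. transposase units of isoform copies)
    or :class:`ISCopy` hits carrying ``consensus_span`` offsets, which pin
    every member to a common coordinate system without alignment.  Columns
    inside the element are conserved across copies; flanking columns are
    random host sequence, so scanning outward from the shared core the
    boundary sits at the first column where conservation (fraction of
    agreeing member pairs) drops below ``threshold`` sustained over
    ``window`` columns.

    Truncated copies are handled by activity tracking: a member only votes
    at columns where its running agreement with the column majority (over
    ``activity_window`` columns) is at least ``activity_threshold``, so a
    copy that decays into background sequence stops diluting conservation
    instead of pulling the boundary inward.  A side where fewer than two
    members remain active before any conservation drop is reported
    ``"exhausted"`` (the data ran out, not the element).
    """
    if len(anchors) < 2:
        raise ValueError("delineation needs at least two members")
    warnings = []
    n = len(genome.seq)

    members = []   # (interval, span_start, span_end)
    for a in anchors:
        if isinstance(a, Interval):
            iv, span = a, (0, len(a))
        else:
            iv = a.interval
            span = a.consensus_span or (0, len(a.interval))
        # two hits of the same genomic locus (e.g. a split alignment)
        # would vote twice and agree with themselves into the flanks
        if any(iv.replicon_id == m[0].replicon_id
               and iv.start < m[0].end + 50 and m[0].start < iv.end + 50
               for m in members):
            continue
        members.append((iv, span[0], span[1]))
    if len(members) < 2:
        raise ValueError("delineation needs at least two distinct members")
    core_len = max(m[2] for m in members)

    wins = []
    for iv, a0, _b0 in members:
        lo = iv.start - reach
        hi = iv.end + reach
        lo_c, hi_c = max(lo, 0), min(hi, n)
        if not genome.circular and (lo_c > iv.start - 50 or hi_c < iv.end + 50):
            warnings.append(f"flank shorter than 50 bp near {iv.start}")
        seq = genome.seq[lo_c:hi_c]
        if iv.strand == "-":
            seq = revcomp(seq)
        # offset of consensus coordinate 0 inside the oriented window
        hit_off = (iv.start - lo_c) if iv.strand == "+" else (hi_c - iv.end)
        wins.append((iv, lo_c, hi_c, seq, hit_off - a0))

    # column t runs over core-anchored coordinates [-reach, core_len+reach)
    width = core_len + 2 * reach
    n_mem = len(wins)
    bases = np.zeros((n_mem, width), dtype=np.uint8)   # 0 = absent
    for mi, (_iv, _lo, _hi, seq, zero_off) in enumerate(wins):
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        t0 = -reach
        src_start = t0 + zero_off
        dst_start = 0
        if src_start < 0:
            dst_start = -src_start
            src_start = 0
        length = min(len(arr) - src_start, width - dst_start)
        if length > 0:
            bases[mi, dst_start : dst_start + length] = \
                arr[src_start : src_start + length]

    present = bases > 0
    # agreement is measured against the majority over the leading
    # ``n_reference`` members (the full-length core hits): a majority over
    # everyone would degrade wherever truncated copies outnumber intact
    # ones and silence the very members that still carry element sequence
    n_ref = max(1, min(n_reference or n_mem, n_mem))
    majority = np.zeros(width, dtype=np.uint8)
    ref_present = present[:n_ref]
    for x in range(width):
        col = bases[:n_ref, x][ref_present[:, x]]
        if len(col) == 0:
            col = bases[present[:, x], x]
        if len(col):
            vals, counts = np.unique(col, return_counts=True)
            majority[x] = vals[np.argmax(counts)]
    agree = (bases == majority[None, :]) & present

    # short trailing (direction-aware) running agreement with the majority:
    # a member only votes at a column if it matched the majority over the
    # preceding ~13 columns of the scan, so truncated copies stop voting
    # almost immediately after their content ends while full copies keep
    # voting right up to the element edge
    trail = 13
    agree_f = agree.astype(float)
    csum = np.cumsum(agree_f, axis=1)
    pad = np.zeros((n_mem, 1))
    csum = np.concatenate([pad, csum], axis=1)
    act_right = np.zeros_like(agree_f)   # trailing window [x-trail+1, x]
    act_left = np.zeros_like(agree_f)    # leading window  [x, x+trail-1]
    for x in range(width):
        lo_w = max(x - trail + 1, 0)
        act_right[:, x] = (csum[:, x + 1] - csum[:, lo_w]) / (x + 1 - lo_w)
        hi_w = min(x + trail, width)
        act_left[:, x] = (csum[:, hi_w] - csum[:, x]) / (hi_w - x)
    active_right = (act_right >= activity_threshold) & present
    active_left = (act_left >= activity_threshold) & present

    def cons_at(x: int, direction: int) -> Tuple[float, bool]:
        """(pairwise agreement at column x among currently active members)."""
        act = active_right if direction > 0 else active_left
        sel = act[:, x] & present[:, x]
        k = int(sel.sum())
        if k < 2:
            return 0.0, True
        col = bases[sel, x]
        _vals, counts = np.unique(col, return_counts=True)
        pairs = int((counts * (counts - 1) // 2).sum())
        return pairs / (k * (k - 1) // 2), False

    off = reach  # array index of consensus coordinate 0

    def scan(direction: int) -> Tuple[int, str]:
        start = off + core_len if direction > 0 else off
        limit = width - window if direction > 0 else window - 1
        xs = range(start, limit, direction)
        cvals = {}

        def c(x):
            if x not in cvals:
                cvals[x] = cons_at(x, direction)
            return cvals[x]

        for x in xs:
            wmean = np.mean([c(x + direction * i)[0] for i in range(window)])
            if wmean < threshold:
                y = x
                # continue outward only over runs of >=2 conserved columns:
                # single chance-conserved flank columns must not creep the
                # boundary outward
                while (0 <= y < width and c(y)[0] >= threshold
                       and 0 <= y + direction < width
                       and c(y + direction)[0] >= threshold):
                    y += direction
                if 0 <= y < width and c(y)[0] >= threshold:
                    y += direction
                if not 0 <= y < width:
                    return y, "clamped"
                # the probe core may itself end in copy-private junk: walk
                # back through any contiguous unconserved stretch
                while (0 <= y - direction < width
                       and c(y - direction)[0] < threshold):
                    y -= direction
                return y, ("exhausted" if c(y)[1] else "drop")
        return (width if direction > 0 else 0), "clamped"

    right, right_reason = scan(+1)
    left, left_reason = scan(-1)
    if left_reason != "clamped":
        left += 1  # first conserved column
    if right <= left:  # degenerate: keep at least the core
        left, right = off, off + core_len
    # support counted 20 columns inside each edge, past the trailing-window
    # lag, so it reflects members genuinely carrying sequence to the edge
    right_support = int(active_right[:, min(max(right - 20, 0), width - 1)].sum())
    left_support = int(active_left[:, min(max(left + 20, 0), width - 1)].sum())

    intervals = []
    el_seqs = []
    indices = []
    for mi, (iv, lo_c, hi_c, seq, zero_off) in enumerate(wins):
        s_off = max(left - reach + zero_off, 0)
        e_off = min(right - reach + zero_off, len(seq))
        if e_off - s_off < core_len // 2:
            continue
        if iv.strand == "+":
            g = Interval(iv.replicon_id, lo_c + s_off, lo_c + e_off, "+")
        else:
            g = Interval(iv.replicon_id, hi_c - e_off, hi_c - s_off, "-")
        intervals.append(g)
        el_seqs.append(seq[s_off:e_off])
        indices.append(mi)
    for w in warnings:
        log.warning(w)
    return BoundaryResult(
        element_intervals=intervals, element_seqs=el_seqs,
        member_indices=indices,
        bounds=(left - reach, right - reach),
        left_reason=left_reason, right_reason=right_reason,
        left_support=left_support, right_support=right_support,
        warnings=warnings)


# ---------------------------------------------------------------------------
# terminal inverted repeats


def find_inverted_repeats(element_seq: str, min_arm: int = 10, max_arm: int = 40,
                          terminus_window: int = 50,
                          max_mismatch_frac: float = 0.25,
                          match_score: int = 3, mismatch_score: int = -4,
                          replicon_id: str = "element",
                          ) -> Optional[InvertedRepeatPair]:
    """Best terminal inverted-repeat pair of an element, or None.

    Exhaustively scores every (left start, right end, arm length)
    combination with the left arm starting in the first ``terminus_window``
    bp and the right arm ending in the last ``terminus_window`` bp.  Arms
    are scored ungapped against the reverse complement of each other with
    +3/-4 match/mismatch weights (the einverted convention, which stops
    arms from creeping into random flanking sequence); candidates need
    matches/arm_len >= 1 - ``max_mismatch_frac`` and are reported in
    matches/arm_len notation.  Ties prefer the longer arm, then the
    outermost placement.
    """
    cands = inverted_repeat_candidates(
        element_seq, min_arm, max_arm, terminus_window, max_mismatch_frac,
        match_score, mismatch_score, top_n=1, replicon_id=replicon_id)
    return cands[0] if cands else None


def inverted_repeat_candidates(element_seq: str, min_arm: int = 10,
                               max_arm: int = 40, terminus_window: int = 50,
                               max_mismatch_frac: float = 0.25,
                               match_score: int = 3, mismatch_score: int = -4,
                               top_n: int = 6,
                               replicon_id: str = "element",
                               ) -> List[InvertedRepeatPair]:
    """Top-scoring terminal inverted-repeat candidates, best first."""
    L = len(element_seq)
    if L < 100:
        return []
    tw = min(terminus_window, L // 2)
    span = tw + max_arm
    arr = _seq_codes(element_seq)[:span].astype(np.int16)
    # B[u + t] is the complement partner for right arms ending at e = L - u
    rc = _seq_codes(revcomp(element_seq))[:span].astype(np.int16)
    entries = []  # (key, s, e, a, matches)
    for d in range(-(tw - 1), tw):
        lo_i = max(0, -d)
        hi_i = min(span, span - d)
        if hi_i - lo_i < min_arm:
            continue
        eq = (arr[lo_i:hi_i] == rc[lo_i + d : hi_i + d]) & (arr[lo_i:hi_i] < 4)
        csum = np.concatenate([[0], np.cumsum(eq)])
        m = hi_i - lo_i
        for a in range(min_arm, min(max_arm, m) + 1):
            matches = csum[a:] - csum[:-a]          # index by s' = s - lo_i
            s_vals = np.arange(lo_i, lo_i + len(matches))
            u_vals = s_vals + d
            ok = (
                (s_vals < tw) & (u_vals >= 0) & (u_vals < tw)
                & (matches >= np.ceil(a * (1 - max_mismatch_frac)))
                & (2 * s_vals + d + 2 * a <= L)     # arms must not overlap
                & (s_vals + a <= span) & (u_vals + a <= span)
            )
            if not ok.any():
                continue
            scores = match_score * matches + mismatch_score * (a - matches)
            scores = np.where(ok, scores, -(10 ** 9))
            idx = int(np.argmax(scores))
            # resolve ties toward the outermost (smallest s) placement
            top = scores[idx]
            cands = np.nonzero(scores == top)[0]
            idx = int(cands[0])
            s = int(s_vals[idx])
            u = int(u_vals[idx])
            e = L - u
            key = (int(top), a, -s, e)
            entries.append((key, s, e, a, int(matches[idx])))
    entries.sort(key=lambda t: t[0], reverse=True)
    out: List[InvertedRepeatPair] = []
    for _key, s, e, a, matches in entries:
        # skip near-duplicates of an already-kept candidate
        if any(abs(p.left_arm.start - s) <= 3 and abs(p.right_arm.end - e) <= 3
               for p in out):
            continue
        out.append(InvertedRepeatPair(
            left_arm=Interval(replicon_id, s, s + a, "+"),
            right_arm=Interval(replicon_id, e - a, e, "+"),
            arm_len=a, matches=matches,
        ))
        if len(out) >= top_n:
            break
    return out


# ---------------------------------------------------------------------------
# direct repeats (target-site duplications)


def find_direct_repeats(genome: GenomeRecord, interval: Interval,
                        min_len: int = 2, max_len: int = 12,
                        ) -> Optional[DirectRepeat]:
    """Longest identical k-mer immediately flanking both element ends.

    Target-site duplications are exact copies of one insertion site, so
    only exact matches count; decayed repeats read as absence.
    """
    n = len(genome.seq)
    avail_left = interval.start if not genome.circular else max_len
    avail_right = (n - interval.end) if not genome.circular else max_len
    hi = min(max_len, avail_left, avail_right)
    for k in range(hi, min_len - 1, -1):
        left = genome.fetch(interval.start - k, interval.start) \
            if genome.circular else genome.seq[interval.start - k : interval.start]
        right = genome.fetch(interval.end, interval.end + k) \
            if genome.circular else genome.seq[interval.end : interval.end + k]
        if left == right and len(left) == k and "N" not in left:
            return DirectRepeat(
                seq=left,
                left=Interval(interval.replicon_id, interval.start - k,
                              interval.start, interval.strand),
                right=Interval(interval.replicon_id, interval.end,
                               interval.end + k, interval.strand),
            )
    return None


# ---------------------------------------------------------------------------
# genome-wide copy mapping


def orf_architecture_intact(copy_seq: str, orf_regions: Sequence[Tuple[int, int]],
                            offset: int = 0) -> bool:
    """True if every consensus ORF region is intact in a copy.

    The copy must retain a valid start codon and be free of premature stop
    codons inside each declared ORF (coordinates are consensus-based; the
    copy is assumed colinear).
    """
    starts = ("ATG", "GTG", "TTG")
    for a, b in orf_regions:
        a -= offset
        b -= offset
        if a < 0 or b > len(copy_seq):
            return False
        if copy_seq[a : a + 3] not in starts:
            return False
        for p in range(a, b - 3, 3):
            if copy_seq[p : p + 3] in STOPS:
                return False
    return True


def _xdrop_extend(gcode: np.ndarray, qcode: np.ndarray, diag: int,
                  j0: int, j1: int, xdrop: int = 12,
                  match: int = 1, mismatch: int = -3) -> Tuple[int, int]:
    """Extend a seeded diagonal match outward with an X-drop rule."""
    L = len(qcode)
    n = len(gcode)
    # left
    best = cur = 0
    jl = j0
    j = j0 - 1
    while j >= 0 and diag + j >= 0:
        cur += match if (qcode[j] == gcode[diag + j] and qcode[j] < 4) else mismatch
        if cur > best:
            best = cur
            jl = j
        if best - cur > xdrop:
            break
        j -= 1
    # right
    best = cur = 0
    jr = j1
    j = j1
    while j < L and diag + j < n:
        cur += match if (qcode[j] == gcode[diag + j] and qcode[j] < 4) else mismatch
        if cur > best:
            best = cur
            jr = j + 1
        if best - cur > xdrop:
            break
        j += 1
    return jl, jr


def map_all_copies(genome: GenomeRecord, consensus: str, family: str,
                   min_partial_len: int = 60, min_identity: float = 0.8,
                   full_coverage: float = 0.98, k: int = 12,
                   index: Optional[KmerIndex] = None,
                   orf_regions: Optional[Sequence[Tuple[int, int]]] = None,
                   ) -> List[ISCopy]:
    """All genomic occurrences of a family consensus, both strands.

    Seeded k-mer hits are grouped by diagonal, extended with an X-drop
    rule, and kept when identity >= ``min_identity`` over >=
    ``min_partial_len`` bp; coverage >= ``full_coverage`` of the consensus
    makes a copy full-length, anything less partial.  Overlapping hits are
    merged keeping the best-scoring one.  ``orf_regions`` (element-local
    ORF spans) enable the intact-transposase flag on full copies.
    """
    if index is None:
        index = KmerIndex(genome.seq, k)
    gcode = _seq_codes(genome.seq)
    L = len(consensus)
    hits = []
    for strand in "+-":
        q = consensus if strand == "+" else revcomp(consensus)
        qcode = _seq_codes(q)
        codes, valid = _kmer_codes(qcode, k)
        diag_hits: Dict[int, List[int]] = {}
        for i in np.nonzero(valid)[0]:
            for g in index.lookup(int(codes[i])):
                diag_hits.setdefault(int(g) - int(i), []).append(int(i))
        for diag, offs in diag_hits.items():
            offs.sort()
            # extend runs separated by large seedless gaps independently
            runs = []
            run_start = 0
            for t in range(1, len(offs) + 1):
                if t == len(offs) or offs[t] - offs[t - 1] > 60:
                    j0, j1 = offs[run_start], offs[t - 1] + k
                    runs.append(_xdrop_extend(gcode, qcode, diag, j0, j1))
                    run_start = t
            # chain runs on the same diagonal across short diverged walls:
            # a copy with a dense mutation patch must stay one copy
            merged = []
            for jl, jr in sorted(runs):
                if merged and jl - merged[-1][1] <= 120:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], jr))
                else:
                    merged.append((jl, jr))
            for jl, jr in merged:
                # terminal mutations clip X-drop extensions a few bp short
                # of the element ends; snap to the consensus end when the
                # remainder still matches at half rate
                snap = 20
                if 0 < jl <= snap and diag >= 0:
                    seg = qcode[:jl] == gcode[diag : diag + jl]
                    if seg.mean() >= 0.5:
                        jl = 0
                if 0 < L - jr <= snap and diag + L <= len(gcode):
                    seg = qcode[jr:] == gcode[diag + jr : diag + L]
                    if seg.mean() >= 0.5:
                        jr = L
                if jr - jl < min_partial_len:
                    continue
                seg_q = qcode[jl:jr]
                seg_g = gcode[diag + jl : diag + jr]
                matches = int(np.sum((seg_q == seg_g) & (seg_q < 4)))
                ident = matches / (jr - jl)
                if ident < min_identity:
                    continue
                hits.append((diag + jl, diag + jr, strand, jl, jr, matches))

    # merge overlapping hits, best score first
    hits.sort(key=lambda h: -h[5])
    kept = []
    for h in hits:
        if any(h[0] < o[1] and o[0] < h[1] for o in kept):
            continue
        kept.append(h)
    kept.sort(key=lambda h: h[0])

    copies = []
    for gs, ge, strand, jl, jr, matches in kept:
        coverage = (jr - jl) / L
        ident = matches / (jr - jl)
        if strand == "+":
            span = (jl, jr)
        else:
            span = (L - jr, L - jl)
        full = coverage >= full_coverage
        intact = False
        if full and orf_regions is not None:
            seq = genome.seq[gs:ge]
            if strand == "-":
                seq = revcomp(seq)
            intact = orf_architecture_intact(seq, orf_regions, offset=span[0])
        copies.append(ISCopy(
            family=family,
            interval=Interval(genome.id, gs, ge, strand),
            completeness="full" if full else "partial",
            nt_identity=round(ident, 4),
            transposase_intact=intact,
            coverage=round(coverage, 4),
            consensus_span=span,
        ))
    return copies
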