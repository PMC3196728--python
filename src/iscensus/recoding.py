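"""Translational recoding signals of IS-element transposases.

Covers the three recoding strategies mobile elements use to fuse or extend
transposase reading frames:

* programmed -1 (or +1) ribosomal frameshifting at a slippery heptamer of
  the form ``X XXY YYZ`` (canonically ``AAAAAAG``), usually stimulated by a
  stem-loop a few nucleotides downstream of the heptamer;
* stop-codon read-through at weak ``UGA-A`` stop quartets, extending the
  protein in frame (UGA decoded as tryptophan);
* regulatory stem-loops near element termini that damp transcription or
  translation.

Hairpin free energies come from a simplified bundled nearest-neighbor stack
table (Watson-Crick stacks at RNA-like 37 degC values, a flat term for G-T/G-U
wobble stacks, hairpin-loop initiation penalties).  The model is exhaustive
over all (stem, loop) decompositions -- no heuristic pruning -- so its minima
are exactly reproducible; absolute dG values are not comparable to full
secondary-structure packages and thresholds are calibrated for this table.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

from .model import OrfFeature, RecodingCall, SlipperySite, StemLoop

# Complementary pairs allowed in a stem (DNA alphabet, T standing in for U).
PAIRS = {"AT", "TA", "GC", "CG", "GT", "TG"}

# 5'->3' nearest-neighbor stack energies (kcal/mol) for Watson-Crick dimers,
# keyed by the two consecutive top-strand bases; wobble-containing stacks get
# a flat -0.8.
STACK = {
    "AA": -0.93, "AT": -1.10, "TA": -1.33, "CA": -2.11, "GT": -2.24,
    "CT": -2.08, "GA": -2.35, "CG": -2.36, "GG": -3.26, "GC": -3.42,
    "TT": -0.93, "AC": -2.24, "TG": -2.11, "AG": -2.08, "TC": -2.35,
    "CC": -3.26,
}
WOBBLE_STACK = -0.8
LOOP_PENALTY = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 6.3}
MISMATCH_PENALTY = 1.0

MIN_STEM = 5
MIN_LOOP, MAX_LOOP = 3, 8
STIMULATORY_DG = -3.0
STRONG_DG = -8.0

STOPS = {"TAA", "TAG", "TGA"}


def _pair_ok(a: str, b: str) -> bool:
    return a + b in PAIRS


def hairpin_energy(window: str, start: int, stem: int, loop: int) -> Optional[float]:
    """dG of one candidate hairpin, or None if it needs >1 stem mismatch.

    Pair ``t`` of the stem joins ``window[start+t]`` with
    ``window[start+2*stem+loop-1-t]``; mismatched pairs break stacking on
    both sides and incur a penalty.
    """
    span = 2 * stem + loop
    if start < 0 or start + span > len(window):
        return None
    ok = []
    mismatches = 0
    for t in range(stem):
        a = window[start + t]
        b = window[start + span - 1 - t]
        good = _pair_ok(a, b)
        if not good:
            mismatches += 1
            if mismatches > 1:
                return None
        ok.append(good)
    # terminal stem pairs must close the structure
    if not ok[0] or not ok[-1]:
        return None
    dg = LOOP_PENALTY[loop] + MISMATCH_PENALTY * mismatches
    for t in range(stem - 1):
        if ok[t] and ok[t + 1]:
            a1 = window[start + t]
            a2 = window[start + t + 1]
            pair1 = a1 + window[start + span - 1 - t]
            pair2 = a2 + window[start + span - 2 - t]
            if "GT" in (pair1, pair2) or "TG" in (pair1, pair2):
                dg += WOBBLE_STACK
            else:
                dg += STACK[a1 + a2]
    return dg


def fold_hairpin(window: str, max_dg: float = STIMULATORY_DG) -> Optional[StemLoop]:
    """Best (minimum-dG) hairpin in a 20-120 nt window, or None.

    Enumerates every (start, stem >= 5, loop 3-8) decomposition with at most
    one internal stem mismatch; returns the global minimum if it is at or
    below ``max_dg``.  Ties go to the earlier start, then the longer stem.
    """
    n = len(window)
    if not 20 <= n <= 120:
        raise ValueError(f"hairpin window must be 20-120 nt, got {n}")
    best = None
    for start in range(n):
        for loop in range(MIN_LOOP, MAX_LOOP + 1):
            stem = MIN_STEM
            while start + 2 * stem + loop <= n:
                dg = hairpin_energy(window, start, stem, loop)
                if dg is not None:
                    mism = sum(
                        0 if _pair_ok(window[start + t],
                                      window[start + 2 * stem + loop - 1 - t]) else 1
                        for t in range(stem)
                    )
                    cand = StemLoop(stem_len=stem, loop_len=loop, start=start,
                                    dG=round(dg, 2), mismatches=mism)
                    if (best is None or cand.dG < best.dG
                            or (cand.dG == best.dG
                                and (cand.start, -cand.stem_len)
                                < (best.start, -best.stem_len))):
                        best = cand
                stem += 1
    if best is not None and best.dG <= max_dg:
        return best
    return None


def is_slippery(heptamer: str) -> bool:
    """True for ``X XXY YYZ`` heptamers: two homopolymeric codon triplets."""
    if len(heptamer) != 7 or "N" in heptamer:
        return False
    return (heptamer[0] == heptamer[1] == heptamer[2]
            and heptamer[3] == heptamer[4] == heptamer[5])


def find_slippery_sites(element_seq: str, orfs: Sequence[OrfFeature]) -> List[SlipperySite]:
    """Slippery heptamers inside ORF overlaps (or <=10 bp upstream of orfB).

    Considers ordered forward-strand ORF pairs (a before b) whose intervals
    overlap; scans every 7-mer in the overlap window for the ``X XXY YYZ``
    grammar.  Results are unique and sorted by position.
    """
    fwd = sorted((o for o in orfs if o.interval.strand == "+"),
                 key=lambda o: o.interval.start)
    windows = []
    for i, a in enumerate(fwd):
        for b in fwd[i + 1:]:
            if b.interval.start < a.interval.end:  # overlap
                lo = max(b.interval.start - 10, 0)
                hi = a.interval.end
                windows.append((lo, hi))
    positions = set()
    for lo, hi in windows:
        for p in range(lo, min(hi, len(element_seq)) - 6):
            if is_slippery(element_seq[p : p + 7]):
                positions.add(p)
    return [SlipperySite(heptamer=element_seq[p : p + 7], position=p, direction=-1)
            for p in sorted(positions)]


def _translate_codons(seq: str, start: int) -> str:
    """Translate from ``start`` until the first stop codon (exclusive)."""
    from Bio.Seq import Seq

    aas = []
    p = start
    while p + 3 <= len(seq):
        codon = seq[p : p + 3]
        if codon in STOPS:
            break
        aas.append(str(Seq(codon).translate()))
        p += 3
    return "".join(aas)


def merge_transframe(element_seq: str, orf_a: OrfFeature, orf_b: OrfFeature,
                     site: SlipperySite, direction: int = -1) -> str:
    """Transframe protein produced by a frameshift at ``site``.

    Translates orfA up to the last codon boundary at or before the heptamer
    end, shifts by ``direction`` (so the continuation lies in orfB's frame),
    and translates on to orfB's stop.
    """
    a0 = orf_a.interval.start
    hept_end = site.position + 7
    if not (orf_b.interval.start - 10 <= site.position
            and hept_end <= orf_a.interval.end):
        raise ValueError("slippery site outside the orfA/orfB overlap")
    k = (hept_end - a0) // 3
    part1 = orf_a.protein[:k]
    shifted = a0 + 3 * k + direction
    if (shifted - orf_b.interval.start) % 3 != 0:
        raise ValueError("shifted position not in orfB frame")
    part2 = _translate_codons(element_seq, shifted)
    return part1 + part2


def _hairpin_downstream(seq: str, pos: int, lo: int = 2, hi: int = 12,
                        max_dg: float = STIMULATORY_DG) -> Optional[StemLoop]:
    """Best hairpin starting ``lo``-``hi`` nt downstream of ``pos``."""
    window = seq[pos + lo : pos + lo + 60]
    if len(window) < 20:
        return None
    hp = fold_hairpin(window, max_dg=max_dg)
    if hp is not None and hp.start <= hi - lo:
        return StemLoop(stem_len=hp.stem_len, loop_len=hp.loop_len,
                        start=pos + lo + hp.start, dG=hp.dG,
                        mismatches=hp.mismatches)
    return None


def call_recoding(consensus: str, orfs: Sequence[OrfFeature],
                  copy_seqs: Optional[Sequence[str]] = None,
                  min_continuation: int = 50,
                  conservation_frac: float = 0.8,
                  min_orf_len: int = 80) -> RecodingCall:
    """Classify the recoding strategy of an element's transposase.

    -1 frameshift: an overlapping ORF pair in -1 phase with a slippery
    heptamer in the overlap, plus a stimulatory hairpin (dG <= -3) starting
    2-12 nt downstream -- the hairpin is optional for the highly shift-prone
    ``AAAAAAG`` heptamer.  +1 frameshift: overlapping pair in +1 phase with
    no -1 signal.  Read-through: an internal in-frame ``TGA`` followed by
    ``A`` with >= ``min_continuation`` codons of in-frame continuation, no
    strong (dG <= -8) terminator-like hairpin within 30 nt downstream and,
    when aligned copy sequences are supplied, the TGA conserved in >= 80%
    of copies.
    """
    fwd = sorted((o for o in orfs if o.interval.strand == "+"),
                 key=lambda o: o.interval.start)
    # overlapping ORF pairs grouped by phase; a -1 signal anywhere takes
    # precedence over +1 geometry (spurious short ORFs in a third frame
    # must not mask a slippery-site call)
    pairs = {1: [], 2: []}
    for i, a in enumerate(fwd):
        if len(a.protein) < min_orf_len:
            continue
        for b in fwd[i + 1:]:
            if b.interval.start >= a.interval.end:
                continue
            # orfB must carry real downstream coding, not sit inside orfA
            if len(b.protein) < min_orf_len or b.interval.end <= a.interval.end:
                continue
            phase = (b.interval.start - a.interval.start) % 3
            if phase in pairs:
                pairs[phase].append((a, b))
    def by_size(pair_list):
        return sorted(pair_list,
                      key=lambda ab: -(len(ab[0].protein) + len(ab[1].protein)))

    for a, b in by_size(pairs[2]):  # -1 shift: slippery site (+ hairpin)
        for site in find_slippery_sites(consensus, [a, b]):
            hp = _hairpin_downstream(consensus, site.position + 7)
            if hp is not None or site.heptamer == "AAAAAAG":
                merged = merge_transframe(consensus, a, b, site, -1)
                return RecodingCall(kind="minus1", site=site, hairpin=hp,
                                    merged_protein_len=len(merged))
    # stop-codon read-through: checked before bare +1 geometry because its
    # evidence (TGA-A quartet, long in-frame continuation, conservation) is
    # specific, while a +1-phase overlap alone can arise from spurious ORFs
    for orf in fwd:
        if len(orf.protein) < min_orf_len or orf.stop_codon != "TGA":
            continue
        stop_pos = orf.interval.end - 3
        if orf.interval.end >= len(consensus) or consensus[orf.interval.end] != "A":
            continue
        continuation = _translate_codons(consensus, orf.interval.end)
        if len(continuation) < min_continuation:
            continue
        hp = _hairpin_downstream(consensus, orf.interval.end, lo=0, hi=30,
                                 max_dg=STRONG_DG)
        if hp is not None:
            continue
        if copy_seqs:
            conserved = sum(
                1 for s in copy_seqs
                if len(s) > stop_pos + 3 and s[stop_pos : stop_pos + 3] == "TGA"
            )
            if conserved < conservation_frac * len(copy_seqs):
                continue
        merged_len = len(orf.protein) + 1 + len(continuation)
        return RecodingCall(kind="readthrough", site=stop_pos, hairpin=None,
                            merged_protein_len=merged_len)
    for a, b in by_size(pairs[1]):  # +1 shift: overlap geometry only
        k = -(-(b.interval.start - a.interval.start) // 3)
        shifted = a.interval.start + 3 * k + 1
        merged = a.protein[:k] + _translate_codons(consensus, shifted)
        return RecodingCall(kind="plus1", site=None, hairpin=None,
                            merged_protein_len=len(merged))
    return RecodingCall(kind="none")


def find_regulatory_hairpins(element_seq: str,
                             orf_start: Optional[int] = None) -> List[StemLoop]:
    """Strong (dG <= -8) stem-loops in regulatory regions of an element.

    Scans the first 50 bp, the 40 bp upstream of the transposase start (when
    known) and the last 60 bp; windows shorter than 20 nt are skipped.
    Returned hairpins carry element-absolute start coordinates.
    """
    windows = [(0, min(50, len(element_seq)))]
    if orf_start is not None:
        windows.append((max(orf_start - 40, 0), orf_start))
    windows.append((max(len(element_seq) - 60, 0), len(element_seq)))
    out = []
    seen = set()
    for lo, hi in windows:
        if hi - lo < 20:
            continue
        hp = fold_hairpin(element_seq[lo:hi], max_dg=STRONG_DG)
        if hp is not None:
            key = (lo + hp.start, hp.stem_len, hp.loop_len)
            if key not in seen:
                seen.add(key)
                out.append(StemLoop(stem_len=hp.stem_len, loop_len=hp.loop_len,
                                    start=lo + hp.start, dG=hp.dG,
                                    mismatches=hp.mismatches))
    return sorted(out, key=lambda h: h.start)
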