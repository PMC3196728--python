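"""Independent brute-force reference implementations used as test oracles.

Each oracle re-derives the expected answer by exhaustive enumeration with
no shared code (and no shared shortcuts) with the implementation it checks.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# six-frame ORF enumeration (linear sequences)

STARTS = {"ATG", "GTG", "TTG"}
STOPS = {"TAA", "TAG", "TGA"}

CODON_TABLE = None


def _translate(nt: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(nt).translate())


def orfs_brute(seq: str, min_protein_len: int) -> set:
    """All maximal start-to-stop ORFs, as (start, end, strand) triples."""
    n = len(seq)
    out = set()
    for strand in "+-":
        s = seq if strand == "+" else rc(seq)
        for frame in range(3):
            p = frame
            start = None
            while p + 3 <= n:
                codon = s[p : p + 3]
                if codon in STOPS:
                    if start is not None:
                        _emit(out, s, start, p + 3, True, strand, n,
                              min_protein_len)
                    start = None
                elif start is None and codon in STARTS:
                    start = p
                p += 3
            if start is not None:
                end = frame + 3 * ((n - frame) // 3)
                if end > start:
                    _emit(out, s, start, end, False, strand, n,
                          min_protein_len)
    return out


def _emit(out, s, start, end, has_stop, strand, n, min_len):
    nt = s[start:end]
    if "N" in nt:
        return
    protein = _translate(nt[: len(nt) - (3 if has_stop else 0)])
    if len(protein) < min_len:
        return
    if strand == "+":
        out.add((start, end, "+", protein))
    else:
        out.add((n - end, n - start, "-", protein))


# ---------------------------------------------------------------------------
# terminal inverted repeats

def inverted_repeat_brute(seq: str, min_arm=10, max_arm=40,
                          terminus_window=50, max_mismatch_frac=0.25,
                          match_score=3, mismatch_score=-4,
                          ) -> Optional[Tuple[int, int, int, int]]:
    """(left_start, right_end, arm_len, matches) of the best IR, or None."""
    L = len(seq)
    if L < 100:
        return None
    tw = min(terminus_window, L // 2)
    best = None
    for s in range(tw):
        for e in range(L, L - tw, -1):
            for a in range(min_arm, max_arm + 1):
                if s + a > L or e - a < 0 or e - a < s + a:
                    continue
                left = seq[s : s + a]
                right = rc(seq[e - a : e])
                matches = sum(1 for x, y in zip(left, right)
                              if x == y and x in "ACGT")
                if matches < a * (1 - max_mismatch_frac):
                    continue
                score = match_score * matches + mismatch_score * (a - matches)
                key = (score, a, -s, e)
                if best is None or key > best[0]:
                    best = (key, s, e, a, matches)
    if best is None:
        return None
    return best[1:]


# ---------------------------------------------------------------------------
# direct repeats (target-site duplications)

def direct_repeat_brute(seq: str, start: int, end: int,
                        min_len=2, max_len=12) -> Optional[str]:
    for k in range(max_len, min_len - 1, -1):
        if start - k < 0 or end + k > len(seq):
            continue
        left = seq[start - k : start]
        if "N" not in left and left == seq[end : end + k]:
            return left
    return None


# ---------------------------------------------------------------------------
# hairpins

def hairpin_brute(window: str, stack, wobble, loop_penalty, mismatch_penalty,
                  min_stem=5, min_loop=3, max_loop=8,
                  ) -> Optional[Tuple[float, int, int, int]]:
    """(dG, start, stem, loop) of the minimum-energy hairpin, or None.

    Re-implements the bundled energy model by direct per-pair iteration
    (no cumulative tricks, different loop structure from the library).
    """
    pairs = {"AT", "TA", "GC", "CG", "GT", "TG"}
    n = len(window)
    best = None
    for start in range(n):
        max_stem = (n - start - min_loop) // 2
        for stem in range(min_stem, max_stem + 1):
            for loop in range(min_loop, max_loop + 1):
                span = 2 * stem + loop
                if start + span > n:
                    continue
                ok = []
                mism = 0
                for t in range(stem):
                    x = window[start + t]
                    y = window[start + span - 1 - t]
                    good = (x + y) in pairs
                    ok.append(good)
                    mism += not good
                if mism > 1 or not ok[0] or not ok[-1]:
                    continue
                dg = loop_penalty[loop] + mismatch_penalty * mism
                for t in range(stem - 1):
                    if ok[t] and ok[t + 1]:
                        p1 = window[start + t] + window[start + span - 1 - t]
                        p2 = window[start + t + 1] + window[start + span - 2 - t]
                        if "GT" in (p1, p2) or "TG" in (p1, p2):
                            dg += wobble
                        else:
                            dg += stack[window[start + t] + window[start + t + 1]]
                dg = round(dg, 2)
                cand = (dg, start, -stem, loop)
                if best is None or cand < best:
                    best = cand
    if best is None:
        return None
    return best[0], best[1], -best[2], best[3]


# ---------------------------------------------------------------------------
# restriction digest

def digest_brute(seq: str, site: str, offset: int, circular: bool) -> List[int]:
    """Sorted fragment lengths by direct position arithmetic."""
    cuts = []
    i = seq.find(site)
    while i != -1:
        cuts.append(i + offset)
        i = seq.find(site, i + 1)
    n = len(seq)
    if circular:
        if not cuts:
            return [n]
        lengths = [b - a for a, b in zip(cuts, cuts[1:])]
        lengths.append(n - cuts[-1] + cuts[0])
    else:
        bounds = [0] + cuts + [n]
        lengths = [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
    return sorted(lengths)


# ---------------------------------------------------------------------------
# slippery heptamers

def slippery_brute(seq: str, lo: int, hi: int) -> List[int]:
    out = []
    for p in range(max(lo, 0), min(hi, len(seq)) - 6):
        h = seq[p : p + 7]
        if "N" not in h and h[0] == h[1] == h[2] and h[3] == h[4] == h[5]:
            out.append(p)
    return out
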