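"""Grouping transposase copies into IS families.

Copies are isoforms of one IS element when they share >80% nucleotide AND
>80% amino-acid identity over at least 98% of their length; clusters are
built by single linkage over that relation (the most permissive reading of
"shared identity", declared so results are reproducible).  A cluster
becomes a named family only if it satisfies the field's classification
criteria: at least two copies in the genome (full or partial), flanking
inverted repeats (waived for the IS110 and IS200/IS605 families, which
lack them), and either >=30% transposase identity to a known family
exemplar or a catalytic-motif hit.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import edlib

from .align import edit_identity_lower_bound, pairwise_identity
from .model import InvertedRepeatPair

ISOFORM_NT_ID = 0.80
ISOFORM_AA_ID = 0.80
ISOFORM_COVERAGE = 0.98

IR_EXEMPT_CLASSES = ("IS110", "IS200/IS605")


def _isoform_edge(a, b) -> bool:
    # cheap rejections first: coverage demands near-equal lengths
    if min(len(a.nt), len(b.nt)) < ISOFORM_COVERAGE * max(len(a.nt), len(b.nt)):
        return False
    if edit_identity_lower_bound(a.nt, b.nt) < 0.70:
        return False
    nt_id, nt_cov = pairwise_identity(a.nt, b.nt, kind="nt")
    if nt_id <= ISOFORM_NT_ID or nt_cov < ISOFORM_COVERAGE:
        return False
    aa_id, aa_cov = pairwise_identity(a.aa, b.aa, kind="aa")
    return aa_id > ISOFORM_AA_ID and aa_cov >= ISOFORM_COVERAGE


def cluster_isoforms(candidates: Sequence) -> List[List]:
    """Single-linkage isoform clusters of transposase units.

    ``candidates`` need ``nt``, ``aa`` and ``interval`` attributes.  The
    result is independent of input order: members are sorted by genomic
    position within each cluster, clusters by (size desc, first position).
    """
    items = sorted(candidates,
                   key=lambda c: (c.interval.replicon_id, c.interval.start,
                                  c.interval.end))
    n = len(items)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) != find(j) and _isoform_edge(items[i], items[j]):
                parent[find(j)] = find(i)

    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(items[i])
    clusters = list(groups.values())
    clusters.sort(key=lambda g: (-len(g), g[0].interval.replicon_id,
                                 g[0].interval.start))
    return clusters


def _column_map(member: str, ref: str) -> List[Optional[int]]:
    """Map each position of ``ref`` to the aligned position in ``member``."""
    res = edlib.align(member, ref, task="path", mode="NW")
    cmap: List[Optional[int]] = [None] * len(ref)
    qi = ti = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        run = int(num)
        num = ""
        if ch in "=X":
            for _ in range(run):
                cmap[ti] = qi
                qi += 1
                ti += 1
        elif ch == "I":      # extra bases in member
            qi += run
        elif ch == "D":      # gap in member
            ti += run
    return cmap


def build_consensus(seqs: Sequence[str]) -> str:
    """Column-majority consensus of a star alignment against the first member.

    Every other member is globally aligned to the first; each reference
    column takes the majority base over aligned member bases, ties broken
    in favour of the first member.  With one member, the member itself.
    """
    if not seqs:
        raise ValueError("empty cluster")
    ref = seqs[0]
    if len(seqs) == 1:
        return ref
    maps = [_column_map(s, ref) for s in seqs[1:]]
    out = []
    for t, ref_base in enumerate(ref):
        counts = {ref_base: 1}
        for s, cmap in zip(seqs[1:], maps):
            qi = cmap[t]
            if qi is not None:
                b = s[qi]
                counts[b] = counts.get(b, 0) + 1
        best = max(counts.values())
        if counts.get(ref_base, 0) == best:
            out.append(ref_base)      # tie (or win) goes to the first member
        else:
            out.append(max(sorted(counts), key=lambda b: counts[b]))
    return "".join(out)


def classify_family(n_copies: int, ir: Optional[InvertedRepeatPair],
                    family_class: str, homology_ok: bool,
                    min_copies: int = 2) -> Tuple[bool, str]:
    """Apply the three family-classification criteria to one cluster.

    (i) transposase homology (>=30% exemplar identity or a motif hit),
    (ii) flanking inverted repeats, waived for IR-less families
    (IS110, IS200/IS605), (iii) at least two copies -- full or partial --
    in the genome.  Returns (classified, rationale).
    """
    reasons = []
    if not homology_ok:
        reasons.append("no transposase homology or catalytic motif")
    if ir is None and family_class not in IR_EXEMPT_CLASSES:
        reasons.append("no terminal inverted repeats")
    if n_copies < min_copies:
        reasons.append(f"only {n_copies} copy")
    if reasons:
        return False, "; ".join(reasons)
    ir_note = ir.notation if ir is not None else "0 (family exempt)"
    return True, f"{n_copies} copies, IR {ir_note}, class {family_class}"
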