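"""End-to-end IS-element census pipeline.

Stages: six-frame ORF scan -> transposase candidate filter (motif or
exemplar homology) -> merge of overlapping/adjacent ORFs into transposase
units -> single-linkage isoform clustering -> cross-copy boundary
delineation and consensus -> genome-wide copy mapping -> inverted/direct
repeat detection -> family classification and naming -> recoding calls ->
census statistics.

Clusters are processed largest-first; a cluster whose members mostly fall
inside copies already claimed by an accepted family (e.g. ORF remnants of
decayed copies) is folded into that family rather than spawning a
duplicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

from .align import pairwise_identity
from .census import CensusReport, build_census
from .cluster import build_consensus, classify_family, cluster_isoforms
from .context import SkewProfile, gc_skew
from .model import GenomeRecord, Interval, ISCopy, ISFamily, RecodingCall, revcomp
from .orfs import Candidate, Exemplar, candidate_transposases, find_orfs, load_exemplars
from .recoding import call_recoding
from .repeats import (BoundaryResult, KmerIndex, delineate_boundaries,
                      find_direct_repeats, find_inverted_repeats,
                      inverted_repeat_candidates, map_all_copies)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    min_protein_len: int = 80        # aa, genome-wide ORF scan
    identity_threshold: float = 0.30  # exemplar homology rule
    merge_gap: int = 25              # bp, ORFs closer than this form one unit
    delineate_reach: int = 700       # bp of context around each anchor
    kmer: int = 12                   # seed size for copy mapping
    min_partial_len: int = 100       # bp, shortest reportable partial copy
    min_identity: float = 0.80       # nt identity for copy mapping
    full_coverage: float = 0.98      # consensus coverage for full-length
    min_copies: int = 2              # classification criterion (iii)
    naming_prefix: str = "ISSyn"
    dr_min_len: int = 2
    dr_max_len: int = 12


@dataclass
class TransposaseUnit:
    """One or more merged candidate ORFs forming a transposase gene unit."""

    interval: Interval
    nt: str
    aa: str
    members: List[Candidate]
    best_identity: float
    best_class: str
    has_motif: bool


@dataclass
class FamilyRecord:
    family: ISFamily
    copies: List[ISCopy]
    recoding: RecodingCall
    boundary: Optional[BoundaryResult]
    rationale: str


@dataclass
class ScanResult:
    genome: GenomeRecord
    candidates: List[Candidate]
    units: List[TransposaseUnit]
    families: List[ISFamily] = field(default_factory=list)
    copies: List[ISCopy] = field(default_factory=list)
    records: List[FamilyRecord] = field(default_factory=list)
    unclassified: List[TransposaseUnit] = field(default_factory=list)
    census: Optional[CensusReport] = None
    skew: Optional[SkewProfile] = None


def merge_units(candidates: Sequence[Candidate],
                merge_gap: int = 25) -> List[TransposaseUnit]:
    """Chain same-strand candidates separated by <= ``merge_gap`` bp.

    Overlapping ORF pairs (frameshifted transposases) and near-adjacent
    in-frame ORFs (read-through transposases) become one unit whose
    protein is the concatenation of member proteins in transcription
    order.
    """
    units = []
    by_key = {}
    for c in candidates:
        by_key.setdefault((c.orf.interval.replicon_id, c.orf.interval.strand),
                          []).append(c)
    for (rep, strand), group in sorted(by_key.items()):
        group.sort(key=lambda c: c.orf.interval.start)
        chain: List[Candidate] = []
        for c in group + [None]:
            if chain and (c is None or
                          c.orf.interval.start - max(x.orf.interval.end
                                                     for x in chain) > merge_gap):
                start = min(x.orf.interval.start for x in chain)
                end = max(x.orf.interval.end for x in chain)
                ordered = chain if strand == "+" else chain[::-1]
                units.append(TransposaseUnit(
                    interval=Interval(rep, start, end, strand),
                    nt="", aa="".join(x.orf.protein for x in ordered),
                    members=list(chain),
                    best_identity=max(x.best_identity for x in chain),
                    best_class=max(chain, key=lambda x: x.best_identity).best_class,
                    has_motif=any(x.motif is not None for x in chain),
                ))
                chain = []
            if c is not None:
                chain.append(c)
    units.sort(key=lambda u: (u.interval.replicon_id, u.interval.start))
    return units


def _fill_unit_sequences(units: List[TransposaseUnit], genome: GenomeRecord):
    for u in units:
        raw = genome.fetch(u.interval.start, u.interval.end)
        u.nt = raw if u.interval.strand == "+" else revcomp(raw)


def _consensus_architecture(consensus_nt: str, merge_gap: int,
                            min_protein_len: int):
    """(orf_regions, orfs, aa) of the main transposase unit on a consensus."""
    rec = GenomeRecord(id="consensus", seq=consensus_nt)
    orfs = find_orfs(rec, min_protein_len=min_protein_len)
    fwd = [o for o in orfs if o.interval.strand == "+"]
    fwd.sort(key=lambda o: o.interval.start)
    chains = []
    chain = []
    for o in fwd + [None]:
        if chain and (o is None or
                      o.interval.start - max(x.interval.end for x in chain)
                      > merge_gap):
            chains.append(chain)
            chain = []
        if o is not None:
            chain.append(o)
    if not chains:
        return [], orfs, ""
    best = max(chains, key=lambda ch: sum(len(o.protein) for o in ch))
    regions = [(o.interval.start, o.interval.end) for o in best]
    aa = "".join(o.protein for o in best)
    return regions, orfs, aa


def _single_member_element(genome: GenomeRecord, unit: TransposaseUnit,
                           reach: int = 150) -> str:
    """Fallback boundaries for a one-member cluster: ORF +- IR search."""
    n = len(genome.seq)
    lo = max(unit.interval.start - reach, 0)
    hi = min(unit.interval.end + reach, n)
    window = genome.seq[lo:hi]
    if unit.interval.strand == "-":
        window = revcomp(window)
    ir = find_inverted_repeats(window, terminus_window=reach)
    if ir is not None:
        return window[ir.left_arm.start : ir.right_arm.end]
    off = unit.interval.start - lo if unit.interval.strand == "+" \
        else hi - unit.interval.end
    return window[off : off + len(unit.interval)]


def _agreement_clique(seqs: Sequence[str], indices: Sequence[int],
                      threshold: float = 0.82) -> List[int]:
    """Largest greedy clique of members that agree along their whole span.

    Copies that truly span the delineated element agree with each other
    over every column; a truncated copy agrees only over its fragment and
    shows background beyond it, diluting its global agreement.  Operates
    on the modal-length member sequences; returns their anchor indices.
    """
    import numpy as np
    from collections import Counter

    lengths = Counter(len(s) for s in seqs)
    if not lengths:
        return []
    modal = lengths.most_common(1)[0][0]
    idx = [i for i, s in zip(indices, seqs) if len(s) == modal]
    arrs = {i: np.frombuffer(s.encode(), dtype=np.uint8)
            for i, s in zip(indices, seqs) if len(s) == modal}
    if len(idx) < 2:
        return idx
    agree = {}
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = idx[a], idx[b]
            agree[(i, j)] = agree[(j, i)] = float(
                np.mean(arrs[i] == arrs[j]))
    best = max(agree, key=lambda k: agree[k])
    if agree[best] < threshold:
        return idx[:1]
    clique = [min(best), max(best)]
    candidates = [i for i in idx if i not in clique]
    while candidates:
        scored = [(min(agree[(k, c)] for c in clique), k) for k in candidates]
        score, k = max(scored)
        if score < threshold:
            break
        clique.append(k)
        candidates.remove(k)
    # order by mean agreement with the rest of the clique: members spanning
    # the whole element rank above near-full fragments, so downstream
    # reference choice and consensus tie-breaks favour genuine full copies
    def mean_agree(i):
        others = [c for c in clique if c != i]
        return sum(agree[(i, c)] for c in others) / len(others) if others else 1.0

    return sorted(clique, key=lambda i: (-mean_agree(i), i))


def _column_majority(seqs: Sequence[str]) -> str:
    """Column-majority consensus of already-coregistered same-length seqs.

    Delineation emits member element sequences in a rigid common coordinate
    system, so no alignment is needed (and a gapped aligner would shuffle
    tied mismatch runs); sequences deviating from the modal length are left
    out, ties go to the first member.
    """
    from collections import Counter

    lengths = Counter(len(s) for s in seqs)
    modal = lengths.most_common(1)[0][0]
    stack = [s for s in seqs if len(s) == modal]
    if len(stack) == 1:
        return stack[0]
    out = []
    for col in zip(*stack):
        counts = Counter(col)
        best = max(counts.values())
        out.append(col[0] if counts[col[0]] == best
                   else max(sorted(counts), key=lambda b: counts[b]))
    return "".join(out)


def _map_for_verification(genome: GenomeRecord, consensus: str, index,
                          cfg: PipelineConfig):
    return map_all_copies(
        genome, consensus, family="?", index=index,
        min_partial_len=cfg.min_partial_len,
        min_identity=cfg.min_identity, k=cfg.kmer)


def _count_tight(hits, tight: float = 0.998) -> int:
    return sum(1 for h in hits if h.coverage >= tight)


def _ir_snap(genome: GenomeRecord, ref_iv: Interval, consensus_nt: str,
             index, cfg: PipelineConfig,
             widen: int = 250, min_score: int = 34,
             max_len_change: int = 400) -> Optional[str]:
    """Refine thin-support boundaries by snapping to a terminal inverted
    repeat.

    Searches a window widened around the rough element for a strong IR
    pair whose arms contain and extend the evidence-backed rough extent,
    and re-extracts the element between the outer arm edges.  When the
    current consensus is already spanned end-to-end by three or more
    copies, the snapped extension must itself be conserved in at least two
    copies -- an unconserved extension is flank sequence, not element.
    """
    n = len(genome.seq)
    lo = max(ref_iv.start - widen, 0)
    hi = min(ref_iv.end + widen, n)
    w = genome.seq[lo:hi]
    if ref_iv.strand == "-":
        w = revcomp(w)
        l0, r0 = hi - ref_iv.end, hi - ref_iv.start
    else:
        l0, r0 = ref_iv.start - lo, ref_iv.end - lo
    candidates = inverted_repeat_candidates(w, terminus_window=2 * widen)
    candidates = [ir for ir in candidates
                  if 3 * ir.matches - 4 * (ir.arm_len - ir.matches) >= min_score]
    # a strong IR already sitting at the current boundaries confirms them
    for ir in candidates:
        nl, nr = ir.left_arm.start, ir.right_arm.end
        if abs(nl - l0) <= 4 and abs(nr - r0) <= 4:
            return None
    cur_tight = None
    for ir in candidates:
        # arms must contain the evidence-backed rough element and
        # genuinely extend it -- a chance IR inside the element loses
        nl, nr = ir.left_arm.start, ir.right_arm.end
        if nl > l0 + 5 or nr < r0 - 5:
            continue
        if (l0 - nl) <= 4 and (nr - r0) <= 4:
            continue
        snapped = w[nl:nr]
        if abs(len(snapped) - len(consensus_nt)) > max_len_change:
            continue
        if cur_tight is None:
            cur_tight = _count_tight(
                _map_for_verification(genome, consensus_nt, index, cfg))
        if cur_tight >= 2:
            # the current extent is spanned end-to-end by >=2 copies, so a
            # genuine extension must leave a trace in other copies: either
            # >=2 copies span the snapped extent too, or some copy carries
            # sequence inside the extension region
            snap_hits = _map_for_verification(genome, snapped, index, cfg)
            if _count_tight(snap_hits) < 2:
                ext_l = l0 - nl
                ext_r = len(snapped) - (nr - r0)
                corroborated = any(
                    min(h.consensus_span[1], ext_l)
                    - h.consensus_span[0] >= 15
                    or h.consensus_span[1]
                    - max(h.consensus_span[0], ext_r) >= 15
                    for h in snap_hits)
                if not corroborated:
                    continue
        return snapped
    return None


def _midpoint_claimed(iv: Interval, claimed: List[Interval]) -> bool:
    mid = (iv.start + iv.end) // 2
    return any(c.replicon_id == iv.replicon_id and c.start <= mid < c.end
               for c in claimed)


def run_scan(genome: GenomeRecord, exemplars: Optional[Sequence[Exemplar]] = None,
             config: Optional[PipelineConfig] = None,
             n_protein_genes: int = 0) -> ScanResult:
    """Run the full census pipeline on one replicon."""
    cfg = config or PipelineConfig()
    if exemplars is None:
        exemplars = load_exemplars()

    orfs = find_orfs(genome, min_protein_len=cfg.min_protein_len)
    candidates = candidate_transposases(
        orfs, exemplars, genome=genome,
        identity_threshold=cfg.identity_threshold)
    units = merge_units(candidates, cfg.merge_gap)
    _fill_unit_sequences(units, genome)
    log.info("%d ORFs, %d candidates, %d transposase units",
             len(orfs), len(candidates), len(units))

    clusters = cluster_isoforms(units)
    index = KmerIndex(genome.seq, cfg.kmer)
    result = ScanResult(genome=genome, candidates=candidates, units=units)

    claimed: List[Interval] = []
    accepted: List[FamilyRecord] = []
    for cluster in clusters:
        inside = sum(_midpoint_claimed(u.interval, claimed) for u in cluster)
        if inside >= 0.5 * len(cluster):
            result.unclassified.extend(cluster)
            continue
        # pass 1: locate every occurrence of the transposase-gene core,
        # including copies whose ORFs decayed below candidate status; the
        # hits anchor the boundary delineation.  The median-length member
        # serves as the probe (averaging ragged ORF extents would garble
        # the ends); its 5' side is trimmed because a maximal ORF may
        # begin at a start codon in the flank, dragging copy-private
        # sequence into the unit.
        by_len = sorted(cluster, key=lambda u: (len(u.nt), u.interval.start))
        unit_cons = by_len[len(by_len) // 2].nt
        lt = min(120, max(len(unit_cons) - 250, 0))
        rt = min(15, max(len(unit_cons) - 250 - lt, 0))
        core = unit_cons[lt : len(unit_cons) - rt] if rt else unit_cons[lt:]
        pre_hits = map_all_copies(
            genome, core, family="?", index=index,
            min_partial_len=cfg.min_partial_len,
            min_identity=cfg.min_identity, full_coverage=cfg.full_coverage,
            k=cfg.kmer)
        # a fragment-seeded probe may still carry copy-private flank; trim
        # the core to the region supported by at least two hits and remap
        if len(pre_hits) >= 2:
            import numpy as np

            cov = np.zeros(len(core) + 1)
            for h in pre_hits:
                cov[h.consensus_span[0]] += 1
                cov[h.consensus_span[1]] -= 1
            sup = np.nonzero(np.cumsum(cov[:-1]) >= 2)[0]
            if (len(sup) >= 150
                    and (sup[0] > 10 or sup[-1] < len(core) - 11)):
                core = core[sup[0] : sup[-1] + 1]
                pre_hits = map_all_copies(
                    genome, core, family="?", index=index,
                    min_partial_len=cfg.min_partial_len,
                    min_identity=cfg.min_identity,
                    full_coverage=cfg.full_coverage, k=cfg.kmer)
        full_hits = [h for h in pre_hits if h.coverage >= cfg.full_coverage]
        inside = sum(_midpoint_claimed(h.interval, claimed) for h in full_hits)
        if full_hits and inside >= 0.5 * len(full_hits):
            result.unclassified.extend(cluster)
            continue
        boundary = None
        if len(full_hits) >= 1 and len(pre_hits) >= 2:
            # best full-core hit leads; fragments join with activity voting
            full_hits.sort(key=lambda h: -h.nt_identity)
            members = full_hits + [h for h in pre_hits
                                   if h.coverage < cfg.full_coverage]
            boundary = delineate_boundaries(
                genome, members, reach=cfg.delineate_reach,
                n_reference=len(full_hits))
            # fragments long enough to contain the probe core masquerade as
            # full copies; keep only the members that agree across the
            # whole delineated span and re-delineate anchored on them
            clique = _agreement_clique(boundary.element_seqs,
                                       boundary.member_indices)
            if len(clique) >= 2 and (set(clique) != set(range(len(full_hits)))
                                     or clique[0] != 0):
                reordered = ([members[i] for i in clique]
                             + [m for i, m in enumerate(members)
                                if i not in clique])
                boundary = delineate_boundaries(
                    genome, reordered, reach=cfg.delineate_reach,
                    n_reference=len(clique))
                full_n = len(clique)
            else:
                full_n = len(full_hits)
            cons_seqs = [s for s, mi in zip(boundary.element_seqs,
                                            boundary.member_indices)
                         if mi < full_n]
            consensus_nt = _column_majority(cons_seqs or boundary.element_seqs)
            # thin support means the boundary may reflect where fragments
            # ran out rather than the element edge; let a strong terminal
            # IR extend it
            if ("exhausted" in (boundary.left_reason, boundary.right_reason)
                    or min(boundary.left_support,
                           boundary.right_support) <= 3):
                snapped = _ir_snap(genome, boundary.element_intervals[0],
                                   consensus_nt, index, cfg)
                if snapped is not None:
                    consensus_nt = snapped
        else:
            consensus_nt = _single_member_element(genome, cluster[0])
        if len(consensus_nt) < 100:
            result.unclassified.extend(cluster)
            continue
        # orient the consensus so the transposase reads forward: a cluster
        # seeded from an antisense ORF would otherwise carry the element
        # reverse-complemented through every protein-level analysis
        orf_regions, cons_orfs, consensus_aa = _consensus_architecture(
            consensus_nt, cfg.merge_gap, cfg.min_protein_len)
        rc = revcomp(consensus_nt)
        regions_rc, orfs_rc, aa_rc = _consensus_architecture(
            rc, cfg.merge_gap, cfg.min_protein_len)
        if (sum(b - a for a, b in regions_rc)
                > sum(b - a for a, b in orf_regions)):
            consensus_nt = rc
            orf_regions, cons_orfs, consensus_aa = regions_rc, orfs_rc, aa_rc
        if not orf_regions:
            result.unclassified.extend(cluster)
            continue
        copies = map_all_copies(
            genome, consensus_nt, family="?", index=index,
            min_partial_len=cfg.min_partial_len,
            min_identity=cfg.min_identity, full_coverage=cfg.full_coverage,
            k=cfg.kmer, orf_regions=orf_regions)
        overlapping = sum(
            1 for c in copies
            if any(c.interval.overlaps(cl) for cl in claimed))
        if copies and overlapping >= 0.5 * len(copies):
            result.unclassified.extend(cluster)
            continue
        ir = find_inverted_repeats(consensus_nt)
        best_class, best_ident = "", 0.0
        for ex_rec in exemplars:
            ident, cov = pairwise_identity(consensus_aa, ex_rec.protein,
                                           kind="aa")
            if cov >= 0.30 and ident > best_ident:
                best_class, best_ident = ex_rec.family_class, ident
        if not best_class:
            best_class = max(cluster, key=lambda u: u.best_identity).best_class
        homology_ok = (any(u.best_identity >= cfg.identity_threshold
                           for u in cluster)
                       or any(u.has_motif for u in cluster))
        ok, rationale = classify_family(len(copies), ir, best_class,
                                        homology_ok, cfg.min_copies)
        if not ok:
            result.unclassified.extend(cluster)
            log.info("cluster at %d unclassified: %s",
                     cluster[0].interval.start, rationale)
            continue
        # recoding: call on the consensus with full-copy conservation
        full_seqs = []
        for c in copies:
            if c.completeness == "full":
                s = genome.seq[c.interval.start : c.interval.end]
                if c.interval.strand == "-":
                    s = revcomp(s)
                full_seqs.append("N" * c.consensus_span[0] + s)
        recoding = call_recoding(consensus_nt, cons_orfs, copy_seqs=full_seqs)
        dr_lengths = set()
        for c in copies:
            if c.completeness != "full":
                continue
            dr = find_direct_repeats(genome, c.interval,
                                     cfg.dr_min_len, cfg.dr_max_len)
            c.dr = dr
            if dr is not None:
                dr_lengths.add(len(dr.seq))
        family = ISFamily(
            name="?", family_class=best_class, consensus_nt=consensus_nt,
            consensus_aa=consensus_aa, ir=ir, dr_len_observed=dr_lengths,
            n_orfs=len(orf_regions), recoding=recoding.kind,
            members=list(cluster),
        )
        accepted.append(FamilyRecord(family=family, copies=copies,
                                     recoding=recoding, boundary=boundary,
                                     rationale=rationale))
        claimed.extend(c.interval for c in copies)

    # cross-family overlap resolution: keep the better-supported copy
    all_copies = [c for rec in accepted for c in rec.copies]
    all_copies.sort(key=lambda c: -(c.nt_identity * len(c.interval)))
    kept: List[ISCopy] = []
    for c in all_copies:
        if any(c.interval.overlaps(o.interval) for o in kept):
            continue
        kept.append(c)
    kept.sort(key=lambda c: c.interval.start)
    kept_ids = {id(c) for c in kept}
    for rec in accepted:
        rec.copies = [c for c in rec.copies if id(c) in kept_ids]
    # a family whose copies were all claimed by others was a duplicate
    for rec in accepted:
        if not rec.copies:
            result.unclassified.extend(rec.family.members)
    accepted = [rec for rec in accepted if rec.copies]
    kept = [c for rec in accepted for c in rec.copies]
    kept.sort(key=lambda c: c.interval.start)

    # name families in order of first genomic occurrence
    accepted.sort(key=lambda r: min(c.interval.start for c in r.copies))
    for i, rec in enumerate(accepted):
        rec.family.name = f"{cfg.naming_prefix}{i + 1}"
        for c in rec.copies:
            c.family = rec.family.name

    result.records = accepted
    result.families = [rec.family for rec in accepted]
    result.copies = kept

    # assignment: a candidate belongs to a family if its midpoint falls
    # inside one of that family's mapped copies
    n_assigned = sum(
        1 for cand in candidates
        if _midpoint_claimed(cand.orf.interval, [c.interval for c in kept]))
    result.census = build_census(
        result.families, kept, genome, n_protein_genes=n_protein_genes,
        n_transposase_genes=len(candidates), n_assigned=n_assigned)
    result.skew = gc_skew(genome) if len(genome.seq) >= 20000 else None
    return result
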