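"""Genome-stability context: cumulative GC skew and IS->downstream-gene loci.

In rearrangement-free bacterial chromosomes the per-window GC skew
(G-C)/(G+C) changes sign twice -- at the replication origin and terminus --
so the cumulative skew is V-shaped with its minimum at the origin and
maximum at the terminus.  Genomes reshuffled by transposition lose this
signature.  The module also screens for full-length IS copies with a
co-oriented downstream gene within a configurable distance, the geometry
under which IS-driven read-through transcription is plausible.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

from .model import DownstreamLocus, GeneFeature, GenomeRecord, Interval, ISCopy, SkewProfile


def gc_skew(genome: GenomeRecord, window: int = 10000, step: int = 1000) -> SkewProfile:
    """Sliding-window GC skew and its cumulative curve.

    Windows with G+C = 0 score 0; circular genomes wrap.  ``ori`` and
    ``ter`` are the window positions of the cumulative minimum and maximum;
    a flat (all-zero) profile is flagged degenerate.
    """
    n = len(genome.seq)
    if n < 2 * window:
        raise ValueError("genome shorter than two windows")
    arr = np.frombuffer(genome.seq.encode(), dtype=np.uint8)
    is_g = (arr == ord("G")).astype(np.int32)
    is_c = (arr == ord("C")).astype(np.int32)
    if genome.circular:
        is_g = np.concatenate([is_g, is_g[:window]])
        is_c = np.concatenate([is_c, is_c[:window]])
        starts = np.arange(0, n, step)
    else:
        starts = np.arange(0, n - window + 1, step)
    cg = np.concatenate([[0], np.cumsum(is_g)])
    cc = np.concatenate([[0], np.cumsum(is_c)])
    g = cg[starts + window] - cg[starts]
    c = cc[starts + window] - cc[starts]
    denom = g + c
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(denom > 0, (g - c) / np.maximum(denom, 1), 0.0)
    cumulative = np.cumsum(vals)
    degenerate = bool(np.allclose(vals, 0.0))
    ori = int(starts[int(np.argmin(cumulative))])
    ter = int(starts[int(np.argmax(cumulative))])
    return SkewProfile(window=window, step=step, positions=starts.tolist(),
                       values=vals.tolist(), cumulative=cumulative.tolist(),
                       ori=ori, ter=ter, degenerate=degenerate)


def count_major_shifts(profile: SkewProfile, smooth: int = 5,
                       min_run: int = 10) -> int:
    """Number of major sign changes of the smoothed per-window skew.

    The skew is smoothed with a ``smooth``-window moving mean (circularly),
    reduced to sign runs (zeros dropped), and a transition counts as major
    when both adjacent runs exceed ``min_run`` windows.  A regular genome
    (one origin, one terminus) yields 2; extra shifts betray rearranged
    segments; a flat profile yields 0.
    """
    vals = np.array(profile.values)
    if len(vals) < smooth or np.allclose(vals, 0.0):
        return 0
    kernel = np.ones(smooth) / smooth
    ext = np.concatenate([vals[-(smooth // 2):], vals, vals[: smooth // 2]])
    smoothed = np.convolve(ext, kernel, mode="valid")[: len(vals)]
    signs = np.sign(smoothed)
    runs = []  # (sign, length), zeros ignored
    for s in signs:
        if s == 0:
            continue
        if runs and runs[-1][0] == s:
            runs[-1][1] += 1
        else:
            runs.append([s, 1])
    if len(runs) < 2:
        return 0
    # circular: merge first/last runs of equal sign
    if runs[0][0] == runs[-1][0] and len(runs) > 1:
        runs[0][1] += runs[-1][1]
        runs.pop()
    if len(runs) < 2:
        return 0
    count = 0
    for i, run in enumerate(runs):
        nxt = runs[(i + 1) % len(runs)]
        if run[1] > min_run and nxt[1] > min_run:
            count += 1
    return count


def find_downstream_loci(copies: Sequence[ISCopy], genes: Sequence[GeneFeature],
                         max_gap: int = 300, close_gap: int = 50,
                         ) -> List[DownstreamLocus]:
    """Full-length IS copies with a co-oriented downstream gene within range.

    For each full-length copy, the nearest gene on the same strand starting
    after the element's 3' end (in transcription direction) qualifies when
    the gap is <= ``max_gap``; loci with gap < ``close_gap`` are flagged
    close.  Opposite-strand or divergently oriented neighbours are excluded.
    """
    loci = []
    for copy in copies:
        if copy.completeness != "full":
            continue
        iv = copy.interval
        best: Optional[GeneFeature] = None
        best_gap = None
        for gene in genes:
            gv = gene.interval
            if gv.replicon_id != iv.replicon_id or gv.strand != iv.strand:
                continue
            if iv.strand == "+":
                gap = gv.start - iv.end
            else:
                gap = iv.start - gv.end
            if gap < 0:
                continue
            if best_gap is None or gap < best_gap:
                best, best_gap = gene, gap
        if best is not None and best_gap <= max_gap:
            loci.append(DownstreamLocus(is_copy=copy, gene=best, gap=best_gap,
                                        close=best_gap < close_gap))
    return loci


def generate_gene_table(genome_len: int, copies: Sequence[ISCopy],
                        n_qualifying: int, n_total: int, seed: int = 0,
                        max_gap: int = 300, close_gap: int = 50,
                        replicon_id: Optional[str] = None) -> List[GeneFeature]:
    """Synthetic gene annotation with a known number of qualifying loci.

    Plants ``n_qualifying`` genes immediately downstream (same strand,
    gap < ``max_gap``) of distinct full-length copies; the remaining genes
    are placed on the opposite strand of the nearest copy or far from all
    copies, so exactly the planted loci qualify.  Gene lengths are uniform
    in 300-1500 bp.
    """
    rng = np.random.default_rng(seed)
    full = [c for c in copies if c.completeness == "full"]
    if n_qualifying > len(full):
        raise ValueError("more qualifying loci requested than full copies")
    if replicon_id is None and full:
        replicon_id = full[0].interval.replicon_id
    chosen = rng.choice(len(full), size=n_qualifying, replace=False)
    genes = []
    gid = 0
    claimed = []
    for ci in chosen:
        iv = full[ci].interval
        gap = int(rng.integers(5, max_gap))
        length = int(rng.integers(300, 1501))
        if iv.strand == "+":
            start = iv.end + gap
            g = Interval(replicon_id, start, start + length, "+")
        else:
            end = iv.start - gap
            g = Interval(replicon_id, max(end - length, 1), end, "-")
        genes.append(GeneFeature(id=f"gene{gid:04d}", interval=g))
        claimed.append((g.start, g.end))
        gid += 1
    # decoys: same strand as a copy but far beyond max_gap, or anywhere on
    # the strand opposite to every nearby copy
    exclusion = [(c.interval.start - max_gap - 1600, c.interval.end + max_gap + 1600)
                 for c in full]
    while gid < n_total:
        length = int(rng.integers(300, 1501))
        start = int(rng.integers(1, max(genome_len - length - 1, 2)))
        if any(lo < start < hi or lo < start + length < hi for lo, hi in exclusion):
            continue
        if any(lo < start < hi for lo, hi in claimed):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneFeature(
            id=f"gene{gid:04d}",
            interval=Interval(replicon_id, start, start + length, strand)))
        claimed.append((start, start + length))
        gid += 1
    genes.sort(key=lambda g: g.interval.start)
    return genes
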