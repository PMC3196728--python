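"""Virtual Southern blot: restriction digest, probe bands, pattern comparison.

Models the transposition-monitoring readout: genomic DNA is digested with
an enzyme that does not cut inside the probed IS element, fragments are
separated on a gel, and a labelled element-specific probe lights up every
fragment carrying at least one copy.  A transposition or rearrangement
moves copies across fragment boundaries and changes the banding pattern;
identical patterns over time imply genomic stability.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

from .model import BandPattern, Fragment, GenomeRecord, Interval, ISCopy

#: enzyme name -> (recognition site, cut offset within the site)
ENZYMES: Dict[str, Tuple[str, int]] = {
    "Eco32I": ("GATATC", 3),   # blunt cutter, GAT^ATC (isoschizomer of EcoRV)
    "EcoRV": ("GATATC", 3),
    "HindIII": ("AAGCTT", 1),  # A^AGCTT
}


def digest(genome: GenomeRecord, site: str, cut_offset: int = None) -> List[Fragment]:
    """Fragments produced by cutting at every exact occurrence of ``site``.

    Cut positions are ``site start + cut_offset`` (default: the blunt
    middle).  A circular genome with k sites yields k fragments (one of
    which wraps the origin); a linear genome yields k+1.  Fragment lengths
    always sum to the genome length.
    """
    if len(site) < 4:
        raise ValueError("recognition site must be at least 4 bp")
    site = site.upper()
    if cut_offset is None:
        cut_offset = len(site) // 2
    n = len(genome.seq)
    cuts = []
    p = genome.seq.find(site)
    while p != -1:
        cuts.append(p + cut_offset)
        p = genome.seq.find(site, p + 1)
    frags = []
    if genome.circular:
        if not cuts:
            return [Fragment(Interval(genome.id, 0, n, "+"))]
        for a, b in zip(cuts, cuts[1:]):
            frags.append(Fragment(Interval(genome.id, a, b, "+")))
        # wrap fragment: from the last cut around the origin to the first
        frags.append(Fragment(Interval(genome.id, cuts[-1], n + cuts[0], "+")))
    else:
        bounds = [0] + cuts + [n]
        for a, b in zip(bounds, bounds[1:]):
            if b > a:
                frags.append(Fragment(Interval(genome.id, a, b, "+")))
    return frags


def _overlaps_wrapped(frag: Fragment, copy_iv: Interval, n: int) -> bool:
    a, b = frag.interval.start, frag.interval.end
    spans = [(a, min(b, n))] + ([(0, b - n)] if b > n else [])
    return any(s < copy_iv.end and copy_iv.start < e for s, e in spans)


def probe_bands(fragments: Sequence[Fragment], copies: Sequence[ISCopy],
                probe: str = None, genome_len: int = None) -> BandPattern:
    """Band lengths of fragments hybridizing to a family's copies.

    Each fragment that overlaps at least one copy contributes one band
    (several copies on one fragment co-migrate); bands are sorted
    descending.  Copies that an enzyme cuts within are reported as
    warnings -- their signal would split across two bands.
    """
    if probe is None:
        probe = copies[0].family if copies else "?"
    if genome_len is None:
        genome_len = max(f.interval.end for f in fragments) if fragments else 0
    bands = []
    warnings = []
    for frag in fragments:
        if any(_overlaps_wrapped(frag, c.interval, genome_len) for c in copies):
            bands.append(frag.length)
    for c in copies:
        covering = [f for f in fragments
                    if _overlaps_wrapped(f, c.interval, genome_len)]
        if len(covering) > 1:
            warnings.append(
                f"copy at {c.interval.start}-{c.interval.end} is cut internally "
                f"({len(covering)} fragments)")
    return BandPattern(probe=probe, band_lengths=sorted(bands, reverse=True),
                       warnings=warnings)


def compare_patterns(p1: BandPattern, p2: BandPattern,
                     resolution_frac: float = 0.05) -> str:
    """``"identical"`` or ``"changed"`` under a relative gel resolution.

    Patterns match when they have the same band count and each pair of
    size-ranked bands differs by less than ``resolution_frac`` relative
    length; anything else reads as changed.
    """
    if p1.probe != p2.probe:
        raise ValueError(f"patterns probe different families: "
                         f"{p1.probe!r} vs {p2.probe!r}")
    if len(p1.band_lengths) != len(p2.band_lengths):
        return "changed"
    for a, b in zip(p1.band_lengths, p2.band_lengths):
        if abs(a - b) / max(a, b) >= resolution_frac:
            return "changed"
    return "identical"
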