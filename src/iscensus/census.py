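"""Genome-level and per-family IS census statistics.

Aggregates copies and families into the two standard summary tables of an
IS-element census: genome totals (transposase genes, assignment rate,
full-length/partial/intact copy counts, direct-repeat absence, IS fraction
of the genome) and per-family rows (length, inverted-repeat notation,
direct-repeat lengths, GC content, transposase size, copy counts with
identity ranges).

Percentages are rounded half-up to integers, which reproduces standard
printed census parentheticals exactly from their numerator/denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence

from .model import GenomeRecord, ISCopy, ISFamily


def gc_content(seq: str) -> float:
    """GC percentage, Ns excluded from the denominator, to 1 decimal."""
    if not seq:
        raise ValueError("empty sequence")
    g = seq.count("G") + seq.count("C")
    acgt = g + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return round(100.0 * g / acgt, 1)


def percentage(numerator: float, denominator: float) -> int:
    """Integer percent, rounded half-up."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    x = 100.0 * numerator / denominator
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


def host_generations(days: float, generation_time_h: float,
                     round_to: int = 100) -> int:
    """Host generations elapsed over ``days``, rounded to ``round_to``."""
    g = days * 24.0 / generation_time_h
    return int(g / round_to + 0.5) * round_to


@dataclass
class CensusReport:
    n_protein_genes: int
    n_transposase_genes: int
    n_assigned: int
    n_full: int
    n_partial: int
    n_full_intact: int
    n_full_no_dr: int
    pct_transposase: int
    pct_assigned: int
    pct_intact: int
    pct_no_dr: int
    total_is_bp: int = 0
    pct_genome_is: int = 0
    per_family: List[dict] = field(default_factory=list)

    def validate(self) -> None:
        assert self.n_assigned <= self.n_transposase_genes
        assert self.n_full_intact <= self.n_full
        assert self.n_full_no_dr <= self.n_full
        if self.per_family:
            assert sum(r["n_full"] for r in self.per_family) == self.n_full
            assert sum(r["n_partial"] for r in self.per_family) == self.n_partial
            assert sum(r["n_intact"] for r in self.per_family) == self.n_full_intact


def census_from_counts(full: Sequence[int], partial: Sequence[int],
                       intact: Sequence[int],
                       n_full_no_dr: int,
                       n_transposase_genes: int,
                       n_assigned: int,
                       n_protein_genes: int,
                       is_bp: int = 0, genome_bp: int = 0) -> CensusReport:
    """Genome totals from per-family count vectors plus genome-level inputs.

    Totals are sums over the per-family vectors; every percentage is
    recomputed from its own numerator/denominator with half-up rounding.
    """
    n_full = sum(full)
    n_partial = sum(partial)
    n_intact = sum(intact)
    report = CensusReport(
        n_protein_genes=n_protein_genes,
        n_transposase_genes=n_transposase_genes,
        n_assigned=n_assigned,
        n_full=n_full,
        n_partial=n_partial,
        n_full_intact=n_intact,
        n_full_no_dr=n_full_no_dr,
        pct_transposase=percentage(n_transposase_genes, n_protein_genes),
        pct_assigned=percentage(n_assigned, n_transposase_genes),
        pct_intact=percentage(n_intact, n_full),
        pct_no_dr=percentage(n_full_no_dr, n_full),
        total_is_bp=is_bp,
        pct_genome_is=percentage(is_bp, genome_bp) if genome_bp else 0,
    )
    report.validate()
    return report


def _union_length(copies: Sequence[ISCopy]) -> int:
    ivs = sorted((c.interval.start, c.interval.end) for c in copies)
    total = 0
    cur_s = cur_e = None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def build_census(families: Sequence[ISFamily], copies: Sequence[ISCopy],
                 genome: GenomeRecord, n_protein_genes: int,
                 n_transposase_genes: int, n_assigned: int) -> CensusReport:
    """Full census from one pipeline run.

    Per-family rows carry copy counts, identity ranges over full copies,
    GC mean (and range when full copies differ by >=0.5 points), IR/DR
    observations and transposase length; genome totals are sums over rows.
    """
    by_family: Dict[str, List[ISCopy]] = {f.name: [] for f in families}
    for c in copies:
        if c.family not in by_family:
            raise ValueError(f"copy references unknown family {c.family!r}")
        by_family[c.family].append(c)

    rows = []
    for fam in families:
        fam_copies = by_family[fam.name]
        fulls = [c for c in fam_copies if c.completeness == "full"]
        partials = [c for c in fam_copies if c.completeness == "partial"]
        gcs = []
        for c in fulls:
            seq = genome.seq[c.interval.start : c.interval.end]
            gcs.append(gc_content(seq))
        gc_mean = round(sum(gcs) / len(gcs), 1) if gcs else None
        gc_range = None
        if gcs and max(gcs) - min(gcs) >= 0.5:
            gc_range = (min(gcs), max(gcs))
        idents = [round(100 * c.nt_identity) for c in fulls]
        rows.append({
            "family": fam.name,
            "class": fam.family_class,
            "n_orfs": fam.n_orfs,
            "recoding": fam.recoding,
            "length_bp": fam.length,
            "ir": fam.ir.notation if fam.ir else "0",
            "dr": ",".join(str(x) for x in sorted(fam.dr_len_observed, reverse=True)) or "0",
            "gc_mean": gc_mean,
            "gc_range": gc_range,
            "tpase_aa": len(fam.consensus_aa),
            "n_full": len(fulls),
            "full_identity_range": (min(idents), max(idents)) if idents else None,
            "n_partial": len(partials),
            "n_intact": sum(1 for c in fulls if c.transposase_intact),
            "n_full_no_dr": sum(1 for c in fulls if c.dr is None),
        })

    n_full = sum(r["n_full"] for r in rows)
    n_partial = sum(r["n_partial"] for r in rows)
    n_intact = sum(r["n_intact"] for r in rows)
    n_no_dr = sum(r["n_full_no_dr"] for r in rows)
    is_bp = _union_length(copies)
    report = CensusReport(
        n_protein_genes=n_protein_genes,
        n_transposase_genes=n_transposase_genes,
        n_assigned=n_assigned,
        n_full=n_full,
        n_partial=n_partial,
        n_full_intact=n_intact,
        n_full_no_dr=n_no_dr,
        pct_transposase=(percentage(n_transposase_genes, n_protein_genes)
                         if n_protein_genes else 0),
        pct_assigned=(percentage(n_assigned, n_transposase_genes)
                      if n_transposase_genes else 0),
        pct_intact=percentage(n_intact, n_full) if n_full else 0,
        pct_no_dr=percentage(n_no_dr, n_full) if n_full else 0,
        total_is_bp=is_bp,
        pct_genome_is=percentage(is_bp, len(genome.seq)),
        per_family=rows,
    )
    report.validate()
    return report


# ---------------------------------------------------------------------------
# bundled reference census (printed per-family table used as input data)


def load_reference_census() -> List[dict]:
    """Per-family reference census rows bundled with the package."""
    text = resources.files("iscensus").joinpath(
        "data/is_reference_census.tsv").read_text()
    lines = [l for l in text.splitlines() if l.strip()]
    header = lines[0].split("\t")
    rows = []
    for line in lines[1:]:
        vals = line.split("\t")
        row = dict(zip(header, vals))
        for key in ("n_orfs", "length_bp", "tpase_aa", "n_full", "n_partial",
                    "n_intact"):
            row[key] = int(row.get(key) or 0)
        row["gc_pct"] = float(row["gc_pct"])
        rows.append(row)
    return rows


def load_reference_stats() -> Dict[str, int]:
    """Genome-level reference statistics bundled with the package."""
    text = resources.files("iscensus").joinpath(
        "data/genome_stats.tsv").read_text()
    out = {}
    for line in text.splitlines()[1:]:
        if line.strip():
            key, value = line.split("\t")
            out[key] = int(value)
    return out
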