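"""Reading and writing of the standard formats the pipeline touches.

FASTA parsing is delegated to Bio.SeqIO; GFF3 emission/parsing is a minimal
9-column implementation restricted to the single feature type this package
writes (``mobile_genetic_element``), guaranteed to round-trip losslessly.
"""

from __future__ import annotations

import csv
from typing import Iterable, List, Optional

from Bio import SeqIO

from .model import DNA_ALPHABET, DirectRepeat, GenomeRecord, ISCopy, ISFamily, Interval


class FormatError(ValueError):
    """Raised on malformed or inconsistent input files."""


def read_fasta(path) -> List[GenomeRecord]:
    """Read a (multi-)FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased; characters outside ``{A,C,G,T,N}`` are
    rejected.  Record ids must be unique; an empty file is an error.
    A trailing ``[circular]`` token in the description marks the replicon
    circular (written by :func:`write_fasta`).
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {rec.id!r}: non-DNA alphabet characters {sorted(bad)}"
            )
        circular = "[circular]" in rec.description
        records.append(GenomeRecord(id=rec.id, seq=seq, circular=circular))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            tag = " [circular]" if rec.circular else ""
            fh.write(f">{rec.id}{tag}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_FEATURE_TYPE = "mobile_genetic_element"


def _esc(value: str) -> str:
    return value.replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def write_gff(copies: List[ISCopy], families: List[ISFamily], path,
              replicon_lengths: Optional[dict] = None) -> None:
    """Write IS copies as GFF3 ``mobile_genetic_element`` features.

    Internal 0-based half-open coordinates become 1-based inclusive columns
    4/5.  Features wrapping the origin of a circular replicon are emitted as
    two parts sharing an ``ID``.
    """
    known = {f.name for f in families}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, copy in enumerate(copies):
            if copy.family not in known:
                raise FormatError(
                    f"copy at {copy.interval.start} references unknown family "
                    f"{copy.family!r}"
                )
            iv = copy.interval
            attrs = [
                f"ID=iscopy{i}",
                f"family={_esc(copy.family)}",
                f"completeness={copy.completeness}",
                f"identity={copy.nt_identity:.4f}",
                f"intact={'true' if copy.transposase_intact else 'false'}",
            ]
            if copy.dr is not None:
                attrs.append(f"dr_seq={copy.dr.seq}")
            attr_s = ";".join(attrs)
            n = replicon_lengths.get(iv.replicon_id) if replicon_lengths else None
            parts = [(iv.start, iv.end)]
            if n is not None and iv.end > n:  # wraps the origin
                parts = [(iv.start, n), (0, iv.end - n)]
            for s, e in parts:
                fh.write(
                    "\t".join(
                        [
                            iv.replicon_id,
                            "iscensus",
                            _FEATURE_TYPE,
                            str(s + 1),
                            str(e),
                            ".",
                            iv.strand,
                            ".",
                            attr_s,
                        ]
                    )
                    + "\n"
                )


def read_gff(path) -> List[ISCopy]:
    """Read back a GFF3 file written by :func:`write_gff`.

    Two-part (origin-wrapping) features are re-joined into a single copy
    with ``end > replicon length``.
    """
    by_id: dict = {}
    order: list = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"bad GFF line: {line!r}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attr_s = cols
            if ftype != _FEATURE_TYPE:
                continue
            attrs = {}
            for kv in attr_s.split(";"):
                if kv:
                    k, _, v = kv.partition("=")
                    attrs[k] = v.replace("%3B", ";").replace("%3D", "=").replace("%2C", ",")
            key = attrs.get("ID")
            entry = (seqid, int(start) - 1, int(end), strand, attrs)
            if key in by_id:
                by_id[key].append(entry)
            else:
                by_id[key] = [entry]
                order.append(key)
    copies = []
    for key in order:
        parts = sorted(by_id[key], key=lambda t: t[1], reverse=True)
        seqid, start, end, strand, attrs = parts[0]
        if len(parts) == 2:  # wrapped feature: [start, n) + [0, e2)
            end = end + parts[1][2]
        dr = None
        if "dr_seq" in attrs:
            drs = attrs["dr_seq"]
            dr = DirectRepeat(
                seq=drs,
                left=Interval(seqid, start - len(drs), start, strand),
                right=Interval(seqid, end, end + len(drs), strand),
            )
        copies.append(
            ISCopy(
                family=attrs["family"],
                interval=Interval(seqid, start, end, strand),
                completeness=attrs["completeness"],
                nt_identity=float(attrs["identity"]),
                transposase_intact=attrs.get("intact") == "true",
                dr=dr,
            )
        )
    return copies


# ---------------------------------------------------------------------------
# TSV helpers


def write_tsv(rows: List[dict], path, columns: Optional[List[str]] = None) -> None:
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t")
        writer.writeheader()
        for row in rows:
            writer.writerow(row)


def read_tsv(path) -> List[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
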