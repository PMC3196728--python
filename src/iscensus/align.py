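"""Pairwise global alignment identities.

One definition serves every identity threshold in the pipeline (the 30%
transposase-homology rule and the 80%/98% isoform rule): a global alignment,
identity = matches / aligned columns with terminal gaps excluded,
coverage = aligned columns / max(sequence lengths).

Protein alignments use BLOSUM62; nucleotide alignments a simple +2/-3
scheme.  edlib provides a fast edit-distance prefilter for all-vs-all
clustering; it never replaces the scored alignment.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Tuple

import edlib
from Bio import Align
from Bio.Align import substitution_matrices


@lru_cache(maxsize=2)
def _aligner(kind: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if kind == "aa":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
    else:
        aligner.match_score = 2.0
        aligner.mismatch_score = -3.0
        aligner.open_gap_score = -5.0
        aligner.extend_gap_score = -2.0
    return aligner


def pairwise_identity(a: str, b: str, kind: str = "nt") -> Tuple[float, float]:
    """(identity, coverage) of the best global alignment of ``a`` and ``b``.

    Identity counts matches over alignment columns between the first and
    last aligned residue pair (terminal gaps excluded); coverage is that
    column count over ``max(len(a), len(b))``.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if kind == "aa":
        # internal stops (broken transposases) align as unknown residues
        a = a.replace("*", "X")
        b = b.replace("*", "X")
    aln = _aligner(kind).align(a, b)[0]
    blocks_t, blocks_q = aln.aligned
    if len(blocks_t) == 0:
        return 0.0, 0.0
    matches = 0
    pairs = 0
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        pairs += te - ts
        for i, j in zip(range(ts, te), range(qs, qe)):
            if a[i] == b[j]:
                matches += 1
    t0, t1 = blocks_t[0][0], blocks_t[-1][1]
    q0, q1 = blocks_q[0][0], blocks_q[-1][1]
    columns = (t1 - t0) + (q1 - q0) - pairs
    identity = matches / columns if columns else 0.0
    coverage = min(1.0, columns / max(len(a), len(b)))
    return identity, coverage


def edit_identity_lower_bound(a: str, b: str) -> float:
    """Cheap upper bound on attainable identity from the edit distance."""
    d = edlib.align(a, b)["editDistance"]
    m = max(len(a), len(b))
    return 1.0 - d / m if m else 0.0
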