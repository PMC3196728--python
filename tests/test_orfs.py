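import numpy as np
import pytest

from iscensus.model import GenomeRecord
from iscensus.orfs import (Candidate, candidate_transposases, detect_dde,
                           detect_huh_y1, find_orfs)
from iscensus.synthetic import FamilySpec, consensus_with_info

from .oracles import orfs_brute


def test_minimal_orf():
    orfs = find_orfs(GenomeRecord("x", "ATGAAATAA"), min_protein_len=1)
    fwd = [o for o in orfs if o.interval.strand == "+"]
    assert len(fwd) == 1
    assert fwd[0].protein == "MK"
    assert fwd[0].stop_codon == "TAA"


def test_poly_a_has_no_orfs():
    assert find_orfs(GenomeRecord("x", "A" * 500), min_protein_len=1) == []


@pytest.mark.parametrize("seed,length,min_len", [
    (11, 5000, 20), (12, 5000, 20), (13, 8000, 50), (14, 2000, 10),
])
def test_find_orfs_matches_bruteforce(seed, length, min_len):
    """Six-frame scan equals exhaustive enumeration on random sequences."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    found = {(o.interval.start, o.interval.end, o.interval.strand, o.protein)
             for o in find_orfs(GenomeRecord("x", seq), min_len)}
    assert found == orfs_brute(seq, min_len)


def test_find_orfs_spans_circular_origin():
    # ORF deliberately split by the origin: ATG near the end, stop after wrap
    seq = "TAA" + "C" * 198 + "ATGAAA"
    circ = GenomeRecord("c", seq, circular=True)
    wrapped = [o for o in find_orfs(circ, min_protein_len=2)
               if o.interval.end > len(seq)]
    assert any(o.interval.start == 201 and o.protein == "MK" for o in wrapped)


def test_detect_dde_unique_candidate():
    protein = "A" * 60 + "D" + "A" * 70 + "D" + "A" * 40 + "E" + "A" * 20
    hit = detect_dde(protein)
    assert hit is not None
    assert hit.positions == (60, 131, 172)
    assert hit.spacers == (71, 41)


def test_detect_dde_requires_aspartates():
    assert detect_dde("A" * 200) is None


def test_detect_dde_matches_enumeration(exemplars, rng):
    """Scored detection equals brute-force enumeration over in-bounds triples."""
    aas = list("ARNDCQEGHILKMFPSTWYV")
    bounds = ((55, 105), (30, 80))
    for _ in range(40):
        protein = "".join(rng.choice(aas, size=250))
        hit = detect_dde(protein, bounds, exemplars)
        # independent enumeration with the same context scoring
        best = None
        for i, x in enumerate(protein):
            if x != "D":
                continue
            for j in range(i + 55, min(i + 106, len(protein))):
                if protein[j] != "D":
                    continue
                for k in range(j + 30, min(j + 81, len(protein))):
                    if protein[k] != "E":
                        continue
                    score = max(
                        sum(_ctx(protein, p, ex.protein, q)
                            for p, q in zip((i, j, k), ex.dde))
                        for ex in exemplars if ex.dde)
                    cand = (score, -(i + j + k), (i, j, k))
                    if best is None or cand[:2] > best[:2]:
                        best = cand
        if best is None:
            assert hit is None
        else:
            assert hit is not None
            assert hit.positions == best[2]


def _ctx(protein, pos, ex, ex_pos, flank=5):
    m = t = 0
    for d in range(-flank, flank + 1):
        i, j = pos + d, ex_pos + d
        if 0 <= i < len(protein) and 0 <= j < len(ex):
            t += 1
            m += protein[i] == ex[j]
    return m / t if t else 0.0


def test_huh_motif_detection():
    hit = detect_huh_y1("MAA" + "HLH" + "AAAA" + "Y" + "A" * 20)
    assert hit is not None and not hit.degenerate
    degen = detect_huh_y1("MAA" + "HLY" + "AAAA" + "Y" + "A" * 20)
    assert degen is not None and degen.degenerate
    assert detect_huh_y1("MAAAAAAAAYAAAA") is None


def test_planted_transposase_is_retained(exemplars):
    spec = FamilySpec("f", 900, orf_architecture="single", family_class="IS982")
    info = consensus_with_info(spec, 5, exemplars)
    orfs = find_orfs(GenomeRecord("c", info.seq), 80)
    cands = candidate_transposases(orfs, exemplars)
    assert cands, "planted transposase not retained"
    assert max(c.best_identity for c in cands) >= 0.30


def test_random_protein_is_not_retained(exemplars):
    rng = np.random.default_rng(3)
    protein = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=250))
    # backtranslate trivially (no stops by construction of the codon map)
    from iscensus.synthetic import AA_TO_CODONS
    nt = "ATG" + "".join(AA_TO_CODONS[a][0] for a in protein) + "TAA"
    orfs = find_orfs(GenomeRecord("x", nt), 80)
    fwd = [o for o in orfs if o.interval.strand == "+"
           and len(o.protein) >= 200]
    cands = candidate_transposases(fwd, exemplars)
    assert cands == []


def test_motif_route_retains_low_identity_orf(exemplars):
    """The motif/identity OR-rule: strong DDE context alone suffices."""
    ex = next(e for e in exemplars if e.dde)
    rng = np.random.default_rng(8)
    aas = list(rng.choice(list("GPSTAV"), size=260))  # low BLOSUM similarity
    i, j, k = 60, 140, 185
    for planted, src in zip((i, j, k), ex.dde):
        for d in range(-5, 6):
            if 0 <= planted + d < len(aas) and 0 <= src + d < len(ex.protein):
                aas[planted + d] = ex.protein[src + d]
    aas[i], aas[j], aas[k] = "D", "D", "E"
    protein = "".join(aas)
    hit = detect_dde(protein, exemplars=exemplars)
    assert hit is not None and hit.score >= 1.0
    from iscensus.synthetic import AA_TO_CODONS
    nt = "ATG" + "".join(AA_TO_CODONS[a][0] for a in protein) + "TAA"
    orfs = [o for o in find_orfs(GenomeRecord("x", nt), 80)
            if o.interval.strand == "+" and len(o.protein) >= 200]
    cands = candidate_transposases(orfs, exemplars)
    assert any(c.motif is not None and c.motif.kind == "DDE" for c in cands)
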