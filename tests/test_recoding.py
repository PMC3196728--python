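import numpy as np
import pytest

from iscensus.model import GenomeRecord
from iscensus.orfs import find_orfs
from iscensus.recoding import (LOOP_PENALTY, MISMATCH_PENALTY, STACK,
                               WOBBLE_STACK, call_recoding,
                               find_regulatory_hairpins, find_slippery_sites,
                               fold_hairpin, is_slippery, merge_transframe)
from iscensus.synthetic import FamilySpec, consensus_with_info, generate_genome

from .oracles import hairpin_brute, slippery_brute


def test_strong_gc_hairpin_is_found():
    window = "ATATAT" + "GGGGG" + "AAAA" + "CCCCC" + "ATATAT"
    hp = fold_hairpin(window)
    assert hp is not None
    assert hp.stem_len >= 5
    assert hp.dG < -3


def test_poly_a_window_folds_nothing():
    assert fold_hairpin("A" * 40) is None


@pytest.mark.parametrize("seed", range(8))
def test_fold_hairpin_matches_exhaustive_minimum(seed):
    """No pruning: the returned dG is the global minimum over all hairpins."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(25, 90))
    window = "".join(rng.choice(list("ACGT"), size=n,
                                p=[0.25, 0.27, 0.27, 0.21]))
    got = fold_hairpin(window, max_dg=100.0)  # no threshold: pure minimum
    want = hairpin_brute(window, STACK, WOBBLE_STACK, LOOP_PENALTY,
                         MISMATCH_PENALTY)
    if want is None:
        assert got is None
    else:
        assert got is not None
        assert got.dG == pytest.approx(want[0], abs=1e-9)


def test_slippery_grammar():
    assert is_slippery("AAAAAAG")
    assert is_slippery("TTTAAAG")
    assert not is_slippery("ACGTACG")
    assert not is_slippery("AAAAGAG")


def test_sites_found_in_overlap(exemplars):
    spec = FamilySpec("f", 914, orf_architecture="overlap_minus1",
                      family_class="IS5")
    info = consensus_with_info(spec, 3, exemplars)
    orfs = find_orfs(GenomeRecord("c", info.seq), 80)
    sites = find_slippery_sites(info.seq, orfs)
    assert any(s.heptamer == "AAAAAAG" and s.position == info.slippery_pos
               for s in sites)


def test_sites_match_bruteforce_scan(rng):
    """All X XXY YYZ heptamers in the overlap window, nothing else."""
    from iscensus.model import Interval, OrfFeature

    for _ in range(10):
        seq = "".join(rng.choice(list("ACGT"), size=300, p=[0.4, .1, .1, .4]))
        # fake overlapping ORF pair covering [30, 240) and [150, 300)
        a = OrfFeature(Interval("c", 30, 240, "+"), 0, "M" * 69, "ATG", "TAA")
        b = OrfFeature(Interval("c", 150, 300, "+"), 0, "M" * 49, "ATG", "TAA")
        got = [s.position for s in find_slippery_sites(seq, [a, b])]
        assert got == slippery_brute(seq, 150 - 10, 240)


@pytest.mark.parametrize("arch,expected", [
    ("single", "none"),
    ("overlap_minus1", "minus1"),
    ("overlap_plus1", "plus1"),
    ("readthrough", "readthrough"),
])
def test_recoding_called_from_architecture(arch, expected, exemplars):
    length = {"single": 991, "overlap_minus1": 914,
              "overlap_plus1": 893, "readthrough": 881}[arch]
    spec = FamilySpec("f", length, orf_architecture=arch, family_class="IS5")
    info = consensus_with_info(spec, 17, exemplars)
    orfs = find_orfs(GenomeRecord("c", info.seq), 80)
    call = call_recoding(info.seq, orfs)
    assert call.kind == expected
    if expected == "minus1":
        assert call.site.heptamer == "AAAAAAG"
        assert call.merged_protein_len > 0


def test_hairpin_free_minus1_still_called_for_canonical_heptamer(exemplars):
    """The highly shift-prone AAAAAAG needs no stimulatory structure."""
    spec = FamilySpec("f", 914, orf_architecture="overlap_minus1",
                      family_class="IS5", hairpin=False)
    info = consensus_with_info(spec, 4, exemplars)
    orfs = find_orfs(GenomeRecord("c", info.seq), 80)
    call = call_recoding(info.seq, orfs)
    assert call.kind == "minus1"
    assert call.hairpin is None


def test_readthrough_requires_conserved_stop(exemplars):
    spec = FamilySpec("f", 881, n_full=5, orf_architecture="readthrough",
                      divergence=0.0, family_class="IS5")
    genome, truth = generate_genome([spec], 60_000, 0.35, seed=31,
                                    exemplars=exemplars)
    info = truth.consensus["f"]
    orfs = find_orfs(GenomeRecord("c", info.seq), 80)
    copy_seqs = []
    for c in truth.copies:
        s = genome.seq[c.interval.start : c.interval.end]
        if c.interval.strand == "-":
            from iscensus.model import revcomp
            s = revcomp(s)
        copy_seqs.append(s)
    call = call_recoding(info.seq, orfs, copy_seqs=copy_seqs)
    assert call.kind == "readthrough"
    assert call.site == info.readthrough_pos
    # breaking the stop in most copies withdraws the call
    broken = [s[: info.readthrough_pos] + "TGG" + s[info.readthrough_pos + 3:]
              for s in copy_seqs]
    call2 = call_recoding(info.seq, orfs, copy_seqs=broken)
    assert call2.kind != "readthrough"


def test_merge_transframe_bookkeeping(exemplars):
    spec = FamilySpec("f", 914, orf_architecture="overlap_minus1",
                      family_class="IS5")
    info = consensus_with_info(spec, 9, exemplars)
    orfs = sorted((o for o in find_orfs(GenomeRecord("c", info.seq), 80)
                   if o.interval.strand == "+"),
                  key=lambda o: o.interval.start)
    pairs = [(a, b) for a in orfs for b in orfs
             if b.interval.start < a.interval.end
             and b.interval.end > a.interval.end
             and (b.interval.start - a.interval.start) % 3 == 2]
    a, b = max(pairs, key=lambda ab: len(ab[0].protein) + len(ab[1].protein))
    sites = find_slippery_sites(info.seq, [a, b])
    site = next(s for s in sites if s.position == info.slippery_pos)
    merged = merge_transframe(info.seq, a, b, site, -1)
    assert len(merged) > max(len(a.protein), len(b.protein))
    # hand computation: codons of orfA up to the heptamer end, then the
    # -1-frame continuation to orfB's stop covers the rest of orfB
    k = (site.position + 7 - a.interval.start) // 3
    cont_nt = b.interval.end - 3 - (a.interval.start + 3 * k - 1)
    assert len(merged) == k + cont_nt // 3


def test_merged_protein_restores_split_dde(exemplars):
    """Neither single ORF carries the full catalytic triad; the merge does."""
    from iscensus.orfs import detect_dde

    spec = FamilySpec("f", 914, orf_architecture="overlap_minus1",
                      family_class="IS5")
    for seed in range(6):
        info = consensus_with_info(spec, seed, exemplars)
        orfs = [o for o in find_orfs(GenomeRecord("c", info.seq), 80)
                if o.interval.strand == "+"]
        call = call_recoding(info.seq, orfs)
        assert call.kind == "minus1"
        # D and E of the triad live on opposite sides of the shift site in
        # this construction, so the merged protein spans both
        assert call.merged_protein_len > max(len(o.protein) for o in orfs)


def test_regulatory_hairpin_in_first_50bp(exemplars):
    spec = FamilySpec("f", 900, orf_architecture="single",
                      family_class="IS982", regulatory_hairpin=True,
                      ir_arm=0)
    info = consensus_with_info(spec, 6, exemplars)
    hairpins = find_regulatory_hairpins(info.seq, orf_start=info.orf_start)
    assert any(h.start < 50 and h.dG <= -8 for h in hairpins)


def test_windows_shorter_than_20nt_are_skipped():
    assert find_regulatory_hairpins("ATATATATATATAT") == []
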