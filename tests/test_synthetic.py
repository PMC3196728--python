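import numpy as np
import pytest

from iscensus.align import pairwise_identity
from iscensus.model import GenomeRecord, revcomp
from iscensus.orfs import find_orfs
from iscensus.synthetic import (FamilySpec, GenerationError, consensus_with_info,
                                generate_genome, reference_family_specs)


def test_generation_is_deterministic(exemplars):
    spec = [FamilySpec("f", 800, n_full=3, n_partial=1, divergence=0.05,
                       family_class="IS5")]
    g1, t1 = generate_genome(spec, 50_000, 0.35, seed=11, exemplars=exemplars)
    g2, t2 = generate_genome(spec, 50_000, 0.35, seed=11, exemplars=exemplars)
    assert g1.seq == g2.seq
    assert [(c.interval, c.identity) for c in t1.copies] == \
           [(c.interval, c.identity) for c in t2.copies]
    g3, _ = generate_genome(spec, 50_000, 0.35, seed=12, exemplars=exemplars)
    assert g3.seq != g1.seq


def test_empty_spec_list_gives_bare_background(exemplars):
    genome, truth = generate_genome([], 10_000, 0.35, seed=1,
                                    exemplars=exemplars)
    assert len(genome.seq) == 10_000
    assert truth.copies == []


def test_planted_full_copies_have_exact_geometry(exemplars):
    spec = FamilySpec("f", 800, n_full=5, n_partial=0, divergence=0.0,
                      dr_len=8, family_class="IS5")
    genome, truth = generate_genome([spec], 60_000, 0.35, seed=7,
                                    exemplars=exemplars)
    assert len(truth.copies) == 5
    for c in truth.copies:
        assert len(c.interval) == 800
        assert c.identity == 1.0
        left = genome.seq[c.interval.start - 8 : c.interval.start]
        right = genome.seq[c.interval.end : c.interval.end + 8]
        assert left == right == c.dr_seq
        assert len(c.dr_seq) == 8


def test_reference_config_plants_printed_copy_totals(exemplars):
    specs = reference_family_specs()
    assert len(specs) == 16
    assert sum(s.n_full for s in specs) == 122
    assert sum(s.n_partial for s in specs) == 143
    assert sum(s.n_full - s.n_broken for s in specs) == 106


def test_single_architecture_has_one_long_orf(exemplars):
    spec = FamilySpec("f", 800, orf_architecture="single", family_class="IS5")
    info = consensus_with_info(spec, 3, exemplars)
    orfs = [o for o in find_orfs(GenomeRecord("c", info.seq), 80)
            if o.interval.strand == "+"]
    longest = max(orfs, key=lambda o: len(o.interval))
    assert len(longest.interval) >= 0.7 * 800


def test_minus1_architecture_carries_the_canonical_heptamer(exemplars):
    spec = FamilySpec("f", 914, orf_architecture="overlap_minus1",
                      family_class="IS5")
    info = consensus_with_info(spec, 3, exemplars)
    a, b = info.orf_regions
    overlap = info.seq[b[0] : a[1]]
    assert "AAAAAAG" in overlap
    assert info.seq[info.slippery_pos : info.slippery_pos + 7] == "AAAAAAG"


def test_readthrough_architecture_has_in_frame_tga_followed_by_a(exemplars):
    spec = FamilySpec("f", 881, orf_architecture="readthrough",
                      family_class="IS5")
    info = consensus_with_info(spec, 3, exemplars)
    p = info.readthrough_pos
    orf_start = info.orf_regions[0][0]
    assert (p - orf_start) % 3 == 0
    assert info.seq[p : p + 3] == "TGA"
    assert info.seq[p + 3] == "A"


def test_short_element_rejects_overlap_architecture(exemplars):
    spec = FamilySpec("f", 510, orf_architecture="overlap_minus1",
                      family_class="IS1")
    with pytest.raises(GenerationError):
        consensus_with_info(spec, 1, exemplars)


def test_ground_truth_identity_matches_realignment(exemplars):
    spec = FamilySpec("f", 900, n_full=4, n_partial=0, divergence=0.08,
                      family_class="IS982")
    genome, truth = generate_genome([spec], 60_000, 0.35, seed=9,
                                    exemplars=exemplars)
    cons = truth.consensus["f"].seq
    for c in truth.copies:
        seq = genome.seq[c.interval.start : c.interval.end]
        if c.interval.strand == "-":
            seq = revcomp(seq)
        ident, cov = pairwise_identity(seq, cons, kind="nt")
        assert abs(ident - c.identity) <= 0.02


def test_consensus_avoids_restriction_sites(exemplars):
    for seed in range(5):
        spec = FamilySpec("f", 1000, family_class="IS481")
        info = consensus_with_info(spec, seed, exemplars)
        assert "GATATC" not in info.seq
        assert "AAGCTT" not in info.seq


def test_skew_signature_background():
    genome, truth = generate_genome([], 100_000, 0.35, seed=2)
    half = 50_000
    first = genome.seq[:half]
    second = genome.seq[half:]
    assert first.count("G") > first.count("C")
    assert second.count("C") > second.count("G")
    assert truth.ori == 0
    assert truth.ter == half
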