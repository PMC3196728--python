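import numpy as np
import pytest

from iscensus.model import BandPattern, GenomeRecord, Interval, ISCopy
from iscensus.southern import ENZYMES, compare_patterns, digest, probe_bands

from .oracles import digest_brute


def _copy(start, end, family="f"):
    return ISCopy(family=family, interval=Interval("g", start, end, "+"),
                  completeness="full", nt_identity=1.0)


def test_uncut_circular_genome_is_one_fragment():
    genome = GenomeRecord("g", "A" * 10_000, circular=True)
    frags = digest(genome, "GATATC")
    assert len(frags) == 1
    assert frags[0].length == 10_000


def test_circular_fragment_arithmetic():
    rng = np.random.default_rng(5)
    seq = list("".join(rng.choice(list("ACT"), size=9000)))  # no G: no sites
    positions = [1000, 4000, 6500]
    for p in positions:
        seq[p : p + 6] = "GATATC"
    genome = GenomeRecord("g", "".join(seq), circular=True)
    frags = digest(genome, "GATATC", 3)
    lengths = sorted(f.length for f in frags)
    p1, p2, p3 = positions
    assert lengths == sorted([p2 - p1, p3 - p2, 9000 - p3 + p1])


def test_linear_digest_keeps_total_length():
    genome = GenomeRecord("g", "AAGATATCAA")
    frags = digest(genome, "GATATC", 3)
    assert len(frags) == 2
    assert sum(f.length for f in frags) == 10


@pytest.mark.parametrize("seed,circular", [(1, True), (2, False), (3, True),
                                           (4, False)])
def test_digest_matches_position_arithmetic(seed, circular):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=50_000))
    genome = GenomeRecord("g", seq, circular=circular)
    for enzyme, (site, offset) in ENZYMES.items():
        frags = digest(genome, site, offset)
        assert sorted(f.length for f in frags) == digest_brute(
            seq, site, offset, circular)
        assert sum(f.length for f in frags) == len(seq)


def test_each_occupied_fragment_is_one_band():
    frags = digest(GenomeRecord("g", "A" * 10_000, circular=True), "GATATC")
    # 5 copies on a single fragment co-migrate into one band
    copies = [_copy(i * 1500, i * 1500 + 700) for i in range(5)]
    pattern = probe_bands(frags, copies, genome_len=10_000)
    assert pattern.band_lengths == [10_000]


def test_copies_on_distinct_fragments_give_distinct_bands():
    rng = np.random.default_rng(6)
    seq = list("".join(rng.choice(list("ACT"), size=30_000)))
    for p in (5000, 11000, 18000, 24000):
        seq[p : p + 6] = "GATATC"
    genome = GenomeRecord("g", "".join(seq), circular=True)
    frags = digest(genome, "GATATC", 3)
    copies = [_copy(6000, 6900), _copy(12000, 12900), _copy(19000, 19900)]
    pattern = probe_bands(frags, copies, genome_len=30_000)
    assert len(pattern.band_lengths) == 3
    assert pattern.warnings == []


def test_cut_within_copy_raises_warning():
    rng = np.random.default_rng(7)
    seq = list("".join(rng.choice(list("ACT"), size=10_000)))
    seq[2000:2006] = "GATATC"
    seq[5000:5006] = "GATATC"
    genome = GenomeRecord("g", "".join(seq), circular=True)
    frags = digest(genome, "GATATC", 3)
    pattern = probe_bands(frags, [_copy(4500, 5600)], genome_len=10_000)
    assert pattern.warnings
    assert len(pattern.band_lengths) == 2  # the signal splits across bands


def test_compare_patterns_reflexive_and_symmetric():
    p = BandPattern(probe="f", band_lengths=[9000, 4000, 1500])
    q = BandPattern(probe="f", band_lengths=[9100, 4020, 1480])
    assert compare_patterns(p, p) == "identical"
    assert compare_patterns(p, q) == compare_patterns(q, p) == "identical"


def test_resolution_model():
    p = BandPattern(probe="f", band_lengths=[5000])
    q = BandPattern(probe="f", band_lengths=[5100])
    assert compare_patterns(p, q) == "identical"      # 2% < 5%
    r = BandPattern(probe="f", band_lengths=[5600])
    assert compare_patterns(p, r) == "changed"


def test_different_probes_cannot_be_compared():
    p = BandPattern(probe="f", band_lengths=[5000])
    q = BandPattern(probe="h", band_lengths=[5000])
    with pytest.raises(ValueError):
        compare_patterns(p, q)


def test_band_count_never_exceeds_copy_count(small_scan):
    genome, truth, specs, result = small_scan
    site, offset = ENZYMES["Eco32I"]
    frags = digest(genome, site, offset)
    for fam in result.families:
        copies = [c for c in result.copies if c.family == fam.name]
        pattern = probe_bands(frags, copies, probe=fam.name,
                              genome_len=len(genome.seq))
        assert len(pattern.band_lengths) <= len(copies)


def test_planted_consensus_is_never_cut(small_genome):
    """The generator excludes digestion sites from consensus sequences."""
    genome, truth, specs = small_genome
    for info in truth.consensus.values():
        assert "GATATC" not in info.seq
        assert "AAGCTT" not in info.seq
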