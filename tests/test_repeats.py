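import numpy as np
import pytest

from iscensus.model import GenomeRecord, Interval, revcomp
from iscensus.repeats import (KmerIndex, delineate_boundaries,
                              find_direct_repeats, find_inverted_repeats,
                              map_all_copies, orf_architecture_intact)
from iscensus.synthetic import FamilySpec, generate_genome

from .oracles import direct_repeat_brute, inverted_repeat_brute, rc


def _random_seq(rng, n, gc=0.4):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def test_perfect_terminal_ir_reported_exactly():
    rng = np.random.default_rng(0)
    arm = "GATTCCGGAATCCGTAGC"          # 18 bp
    mid = _random_seq(rng, 700)
    # inner spacers chosen so inward arm extension only loses score
    elem = arm + "A" * 8 + mid + "G" * 8 + revcomp(arm)
    ir = find_inverted_repeats(elem)
    assert ir is not None
    assert ir.notation == "18/18"
    assert ir.left_arm.start == 0
    assert ir.right_arm.end == len(elem)


def test_poly_a_element_has_no_ir():
    assert find_inverted_repeats("A" * 500) is None


@pytest.mark.parametrize("seed", range(6))
def test_ir_detector_matches_bruteforce(seed):
    """Detector equals exhaustive (s, e, a) scoring, planted or not."""
    rng = np.random.default_rng(seed)
    elem = _random_seq(rng, 400)
    if seed % 2:
        arm = _random_seq(rng, 21)
        right = list(revcomp(arm))
        for p in rng.choice(21, size=4, replace=False):
            right[p] = next(c for c in "ACGT" if c != right[p])
        elem = arm + elem[21:-21] + "".join(right)
    got = find_inverted_repeats(elem)
    want = inverted_repeat_brute(elem)
    if want is None:
        assert got is None
    else:
        s, e, a, matches = want
        assert (got.left_arm.start, got.right_arm.end, got.arm_len,
                got.matches) == (s, e, a, matches)


def test_direct_repeat_of_planted_tsd():
    rng = np.random.default_rng(4)
    seq = _random_seq(rng, 200) + "GATCGATC" + "X".replace("X", "") + \
        _random_seq(rng, 300) + "GATCGATC" + _random_seq(rng, 200)
    genome = GenomeRecord("g", seq)
    iv = Interval("g", 208, 508, "+")
    dr = find_direct_repeats(genome, iv)
    assert dr is not None and dr.seq == "GATCGATC"


def test_direct_repeat_absent_when_flanks_differ():
    genome = GenomeRecord("g", "A" * 50 + "G" * 300 + "C" * 50)
    dr = find_direct_repeats(genome, Interval("g", 50, 350, "+"))
    assert dr is None


def test_direct_repeat_prefers_longest():
    seq = "T" * 42 + "ACACACAC" + "G" * 300 + "ACACACAC" + "T" * 42
    genome = GenomeRecord("g", seq)
    dr = find_direct_repeats(genome, Interval("g", 50, 350, "+"))
    assert dr is not None and len(dr.seq) == 8


@pytest.mark.parametrize("seed", range(8))
def test_direct_repeat_matches_bruteforce(seed):
    rng = np.random.default_rng(100 + seed)
    seq = _random_seq(rng, 600)
    if seed % 2:  # plant a TSD
        k = int(rng.integers(2, 11))
        tsd = _random_seq(rng, k)
        seq = seq[:200] + tsd + seq[200:420] + tsd + seq[420:]
    genome = GenomeRecord("g", seq)
    start, end = (200 + (k if seed % 2 else 0),
                  420 + (k if seed % 2 else 0)) if seed % 2 else (200, 420)
    dr = find_direct_repeats(genome, Interval("g", start, end, "+"))
    want = direct_repeat_brute(seq, start, end)
    assert (dr.seq if dr else None) == want


# ---------------------------------------------------------------------------
# boundary delineation


def test_boundaries_exact_at_zero_divergence(exemplars):
    spec = FamilySpec("f", 800, n_full=5, n_partial=0, divergence=0.0,
                      dr_len=0, ir_arm=18, family_class="IS982")
    genome, truth = generate_genome([spec], 80_000, 0.35, seed=21,
                                    exemplars=exemplars)
    anchors = [c.interval for c in truth.copies]
    # anchor on the element itself; conservation must stop at the edges
    res = delineate_boundaries(genome, anchors)
    for iv, c in zip(res.element_intervals, truth.copies):
        assert iv.start == c.interval.start
        assert iv.end == c.interval.end


def test_boundaries_within_5bp_at_5pct_divergence(exemplars):
    spec = FamilySpec("f", 900, n_full=6, n_partial=0, divergence=0.05,
                      dr_len=0, ir_arm=18, family_class="IS5")
    genome, truth = generate_genome([spec], 80_000, 0.35, seed=22,
                                    exemplars=exemplars)
    anchors = [c.interval for c in truth.copies]
    res = delineate_boundaries(genome, anchors)
    by_start = {c.interval.start // 1000: c for c in truth.copies}
    for iv in res.element_intervals:
        c = min(truth.copies,
                key=lambda t: abs(t.interval.start - iv.start))
        assert abs(iv.start - c.interval.start) <= 5
        assert abs(iv.end - c.interval.end) <= 5


def test_adjacent_copies_do_not_capture_shared_flank(exemplars):
    """Two copies inserted back-to-back must not fuse across the junction."""
    from iscensus.synthetic import consensus_with_info

    spec = FamilySpec("f", 700, family_class="IS6", ir_arm=15, divergence=0.0)
    cons = consensus_with_info(spec, 1, exemplars).seq
    rng = np.random.default_rng(9)
    bg = _random_seq(rng, 30_000, 0.35)
    # copy1 and copy2 adjacent; copies 3 and 4 isolated
    seq = (bg[:5000] + cons + cons + bg[5000:15000] + cons
           + bg[15000:25000] + cons + bg[25000:])
    genome = GenomeRecord("g", seq)
    anchors = [Interval("g", 5000, 5700, "+"),
               Interval("g", 5700, 6400, "+"),
               Interval("g", 16400, 17100, "+"),
               Interval("g", 27100, 27800, "+")]
    res = delineate_boundaries(genome, anchors)
    iv = res.element_intervals[0]
    assert abs(iv.start - 5000) <= 10
    assert abs(iv.end - 5700) <= 10


# ---------------------------------------------------------------------------
# genome-wide copy mapping


def test_map_recovers_planted_copies_exactly(exemplars):
    spec = FamilySpec("f", 900, n_full=5, n_partial=3, divergence=0.02,
                      family_class="IS5", dr_len=8)
    genome, truth = generate_genome([spec], 100_000, 0.35, seed=23,
                                    exemplars=exemplars)
    cons = truth.consensus["f"].seq
    info = truth.consensus["f"]
    copies = map_all_copies(genome, cons, "f", orf_regions=info.orf_regions)
    assert len(copies) == len(truth.copies)
    det = sorted((c.interval.start, c.interval.end, c.completeness)
                 for c in copies)
    want = sorted((c.interval.start, c.interval.end, c.completeness)
                  for c in truth.copies)
    for (ds, de, dk), (ws, we, wk) in zip(det, want):
        assert dk == wk
        assert abs(ds - ws) <= 5 and abs(de - we) <= 5


def test_broken_transposase_flagged_not_intact(exemplars):
    spec = FamilySpec("f", 900, n_full=4, n_partial=0, divergence=0.0,
                      family_class="IS982", n_broken=2)
    genome, truth = generate_genome([spec], 60_000, 0.35, seed=24,
                                    exemplars=exemplars)
    info = truth.consensus["f"]
    copies = map_all_copies(genome, info.seq, "f",
                            orf_regions=info.orf_regions)
    assert sum(1 for c in copies if c.completeness == "full") == 4
    assert sum(1 for c in copies if c.transposase_intact) == 2
    # detection agrees with the generator's record, copy by copy
    det = {c.interval.start: c.transposase_intact for c in copies}
    for t in truth.copies:
        assert det[t.interval.start] == t.transposase_intact


def test_map_on_background_only_is_empty(exemplars):
    genome, _ = generate_genome([], 30_000, 0.35, seed=25,
                                exemplars=exemplars)
    rng = np.random.default_rng(77)
    cons = _random_seq(rng, 900)
    assert map_all_copies(genome, cons, "f") == []


def test_full_copy_coverage_threshold(exemplars):
    """Full vs partial respects the 98% consensus-coverage rule."""
    spec = FamilySpec("f", 800, n_full=3, n_partial=3, divergence=0.0,
                      family_class="IS6")
    genome, truth = generate_genome([spec], 60_000, 0.35, seed=26,
                                    exemplars=exemplars)
    cons = truth.consensus["f"].seq
    for c in map_all_copies(genome, cons, "f"):
        if c.completeness == "full":
            assert c.coverage >= 0.98
        else:
            assert c.coverage < 0.98
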