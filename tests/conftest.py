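import numpy as np
import pytest

from iscensus.orfs import load_exemplars
from iscensus.pipeline import run_scan
from iscensus.synthetic import FamilySpec, generate_genome


@pytest.fixture(scope="session")
def exemplars():
    return load_exemplars()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20110926)


def three_family_specs():
    return [
        FamilySpec("famA", 914, n_full=5, n_partial=3, divergence=0.02,
                   ir_arm=22, ir_mismatches=1, dr_len=8,
                   orf_architecture="overlap_minus1", family_class="IS5"),
        FamilySpec("famB", 527, n_full=4, n_partial=2, divergence=0.0,
                   ir_arm=0, dr_len=0, orf_architecture="single",
                   family_class="IS200/IS605"),
        FamilySpec("famC", 1031, n_full=3, n_partial=2, divergence=0.03,
                   ir_arm=11, ir_mismatches=1, dr_len=6,
                   orf_architecture="single", family_class="IS481",
                   n_broken=1),
    ]


@pytest.fixture(scope="session")
def small_genome():
    """120 kb genome with three planted families (seed 5)."""
    specs = three_family_specs()
    genome, truth = generate_genome(specs, 120_000, 0.35, seed=5)
    return genome, truth, specs


@pytest.fixture(scope="session")
def small_scan(small_genome, exemplars):
    genome, truth, specs = small_genome
    result = run_scan(genome, exemplars=exemplars, n_protein_genes=0)
    return genome, truth, specs, result
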