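import numpy as np
import pytest

from ngsdesk import simulate
from ngsdesk.types import RefSeq


@pytest.fixture(scope="session")
def ancestor():
    return simulate.make_genome(10_000, 0.5, seed=11, id="ancestor")


@pytest.fixture(scope="session")
def diverged_pair(ancestor):
    """Two genomes each ~5% diverged from a shared ancestor (~10% pairwise)."""
    a, _ = simulate.mutate(ancestor, snv_rate=0.05, seed=21, id="A")
    b, _ = simulate.mutate(ancestor, snv_rate=0.05, seed=22, id="B")
    return a, b


@pytest.fixture(scope="session")
def haplotype_mixture(ancestor):
    """A backbone genome plus two haplotypes with 3 private SNVs each.

    SNVs sit 40 bp apart so 100 bp reads span adjacent pairs often.
    Returns (ref, hap1, hap2, truth1, truth2).
    """
    ref = simulate.make_genome(1_000, 0.5, seed=31, id="ref")

    def plant(positions, new_id, seed):
        rng = np.random.default_rng(seed)
        seq = list(ref.seq)
        truth = []
        for pos in positions:
            alt = rng.permutation([b for b in "ACGT" if b != seq[pos]])[0]
            truth.append((pos, seq[pos], alt))
            seq[pos] = alt
        return RefSeq(id=new_id, seq="".join(seq)), truth

    hap1, t1 = plant([500, 540, 580], "hap1", 41)
    hap2, t2 = plant([520, 560, 600], "hap2", 42)
    return ref, hap1, hap2, t1, t2
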