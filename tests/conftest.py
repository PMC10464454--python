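import random

import pytest

from plastophylo.orthofilter import Orthogroup, RunConfig
from plastophylo.seqio import SeqRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return random.Random(1234)


def random_peptide(rng, lo=10, hi=60):
    return "".join(rng.choice(AA) for _ in range(rng.randint(lo, hi)))


@pytest.fixture
def peptide_factory(rng):
    def make(species="sp", gene="g0", seq=None, suffix=""):
        seq = seq or random_peptide(rng)
        return SeqRecord(id=f"{species}@{gene}{suffix}", seq=seq,
                         species=species, moltype="aa")

    return make


@pytest.fixture
def simple_og(peptide_factory):
    members = [peptide_factory(species=sp, gene="g1") for sp in "ABCDE"]
    return Orthogroup(og_id="OG0001", members=members)


@pytest.fixture
def default_cfg():
    return RunConfig(outgroup={"outgroup"})
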