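import numpy as np
import pytest

from seloscan import synth
from seloscan.motifs import AMINO_ACIDS


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def no_cys_freqs():
    """Composition with zero C/U mass: chance ring membership impossible."""
    f = {a: 1 / 19 for a in AMINO_ACIDS if a != "C"}
    f["C"] = 0.0
    f["U"] = 0.0
    total = sum(f.values())
    return {a: v / total for a, v in f.items()}


@pytest.fixture(scope="session")
def family_census_fixture(no_cys_freqs):
    """143 sequences planted to the family's ring counts: 12 with the
    CxxCxx> outer motif and 99 more with a bare Cxx> inner terminus,
    so the generalised [CU]xx> motif occurs 111 times."""
    cfg = synth.SimProteomeConfig(
        n_seqs=143,
        terminal_spec={"CxxCxx>": 12 / 143, "Cxx>": 99 / 143},
        residue_freqs=no_cys_freqs,
        seed=7,
    )
    return synth.gen_proteome(cfg)


@pytest.fixture(scope="session")
def readthrough_143():
    """A 143-member family with exactly 6 planted Sec misannotations."""
    cfg = synth.SimReadthroughConfig(n_proteins=143, sec_fraction=6 / 143, seed=11)
    return synth.gen_readthrough_cds(cfg)
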