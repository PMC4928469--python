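import numpy as np
import pytest

from plastcomp import SynthParams, generate_pair, generate_plastome

GENBANK_FIXTURE = """\
LOCUS       testloc                  100 bp    DNA     circular PLN 01-JAN-2020
DEFINITION  handcrafted two-gene record.
ACCESSION   testloc
FEATURES             Location/Qualifiers
     CDS             join(11..30,51..70)
                     /gene="tstA"
     gene            complement(75..95)
                     /gene="ycf3"
                     /pseudo
ORIGIN
        1 aaaaaaaaaa cccccccccc gggggggggg tttttttttt aaaaaaaaaa cccccccccc
       61 gggggggggg tttttttttt aaaaaaaaaa cccccccccc
//
"""


@pytest.fixture
def genbank_file(tmp_path):
    path = tmp_path / "fixture.gb"
    path.write_text(GENBANK_FIXTURE)
    return path


@pytest.fixture(scope="session")
def toy_genome():
    """A small sanitised quadripartite genome with planted truth."""
    return generate_plastome(SynthParams.toy(seed=11))


@pytest.fixture(scope="session")
def toy_pair():
    """Toy genome plus diverged sister with true alignment and mutation log."""
    params = SynthParams.toy(
        seed=23,
        planted_ssrs=(),
    )
    return generate_pair(params)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
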