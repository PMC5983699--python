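"""Shared fixtures: a small hand-written GenBank record and reusable
synthetic data sets (generated once per session; everything is code-built,
no stored data files)."""

import pytest

from plastcomp.simulate import SimConfig, evolve_on_tree, generate_root

GENBANK_TEXT = """\
LOCUS       testrec                  100 bp    DNA     circular PLN 01-JAN-2024
DEFINITION  synthetic three-gene test record.
ACCESSION   testrec
VERSION     testrec.1
SOURCE      synthetic construct
  ORGANISM  synthetic construct
            .
FEATURES             Location/Qualifiers
     source          1..100
     gene            5..25
                     /gene="psbA"
     CDS             5..25
                     /gene="psbA"
     gene            complement(join(10..20,31..40))
                     /gene="rps12"
     CDS             complement(join(10..20,31..40))
                     /gene="rps12"
     gene            50..70
                     /gene="trnI-CAU"
     tRNA            50..70
                     /gene="trnI-CAU"
ORIGIN
        1 atgaaacccg ggtttaaacc cgggtttaaa cccgggttta aacccgggtt taaacccggg
       61 tttaaacccg ggtttaaacc cgggtttaaa cccgggttta
//
"""


@pytest.fixture
def genbank_path(tmp_path):
    p = tmp_path / "testrec.gb"
    p.write_text(GENBANK_TEXT)
    return p


@pytest.fixture(scope="session")
def default_sim():
    """Default four-taxon simulated data set with ground truth."""
    return evolve_on_tree(SimConfig(seed=11))


@pytest.fixture(scope="session")
def root_genome():
    """Root genome of the default configuration (no evolution)."""
    return generate_root(SimConfig(seed=11))
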