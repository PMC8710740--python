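import numpy as np
import pytest

from plastevo.simulate import (
    LayoutGene,
    SimulationConfig,
    Template,
    simulate,
    triticeae_preset,
)
from plastevo.trees import PhyloTree


@pytest.fixture(scope="session")
def mini_template() -> Template:
    """A very small quadripartite layout for fast simulation tests."""
    return Template(
        lsc_len=500,
        ir_len=300,
        ssc_len=200,
        lsc_genes=[
            LayoutGene("psbA", "protein_cds", "+", 100, 50),
            LayoutGene("petN", "protein_cds", "-", 60, 150, filler=True),
            LayoutGene("trnC", "trna", "+", 40, 50),
        ],
        ir_genes=[
            LayoutGene("rpl2", "protein_cds", "-", 80, 40),
            LayoutGene("ycf2", "pseudogene", "+", 60, 100, filler=True),
        ],
        ssc_genes=[LayoutGene("ndhF", "protein_cds", "-", 80, 40, filler=True)],
        jsa_spanner=("ndhH", 30, 150),
    )


@pytest.fixture(scope="session")
def quartet_tree() -> PhyloTree:
    """((A,B),(C,D)) plus outgroup O, ultrametric in MY."""
    t = PhyloTree.from_newick("(((A:1,B:1)ab:1,(C:1,D:1)cd:1)in:1,O:3)root;")
    t.assign_ages_from_lengths()
    return t


@pytest.fixture(scope="session")
def clean_preset_result():
    """Noise-free triticeae preset: planted clade deletions only."""
    cfg = triticeae_preset(seed=7, indel_rate=0.0, subst_rate=0.0)
    return simulate(cfg)


@pytest.fixture(scope="session")
def mini_config(mini_template):
    return SimulationConfig(
        seed=11,
        newick="(((A:1,B:1)ab:1,(C:1,D:1)cd:1)in:1,O:3)root;",
        template=mini_template,
        indel_rate=0.5,
        subst_rate=0.002,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
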