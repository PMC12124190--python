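import pytest

from introgain.synthetic_data import (GainSpec, SimulationConfig,
                                      simulate_gene_family, simulate_taxonomy)


@pytest.fixture(scope="session")
def clean_family():
    """Six species, no noise, one generic gain in the focal species only."""
    config = SimulationConfig(
        n_species=6, seed=3, loss_rate=0.0, substitution_rate=0.0,
        gain_events=[GainSpec(clade=("human",), coding_offset=301,
                              mechanism="generic", intron_length=100)],
    )
    tree = simulate_taxonomy(config)
    family, truth = simulate_gene_family(tree, config)
    return family, truth


@pytest.fixture(scope="session")
def intronization_clean():
    """Five species, no noise, one phase-0 intronization gain of 90 nt."""
    from introgain.studies import intronization_family

    config = SimulationConfig(
        n_species=5, birth_model="fixed-topology",
        topology="((human:1,sister:1)ingroup:1,((out1:1,out2:1)n2:1,out3:2)n3:1)root;",
        focal_species="human", seed=5, loss_rate=0.0, substitution_rate=0.0,
        intron_substitution_rate=0.0,
        gain_events=[GainSpec(clade="ingroup", coding_offset=300,
                              mechanism="intronization", intron_length=90)],
    )
    tree = simulate_taxonomy(config)
    return simulate_gene_family(tree, config)
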