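import pytest

from t6kit import synthdata as sd


@pytest.fixture(scope="session")
def small_genome():
    return sd.random_genome(n_genes=20, mean_gene_length=900, seed=11)


@pytest.fixture(scope="session")
def toy_locus_parts():
    """(cds, protein_map) for a small RnfDGEA-style cassette."""
    return sd.make_toy_locus({"rnfD": 60, "rnfG": 40, "rnfE": 40, "rnfA": 40},
                             seed=21)


@pytest.fixture(scope="session")
def resistance_rules(toy_locus_parts):
    """SelectionRules with a single reachable resistance allele at rnfG 5 and
    absolute toxin killing of sensitive clones."""
    cds, pmap = toy_locus_parts
    alt = sorted(sd.reachable_alt_aas(cds, pmap, "rnfG", 5))[0]
    return sd.SelectionRules(resistance_alleles={("rnfG", 5, alt)},
                             s_sensitive=0.0, s_resistant=1.0,
                             rnf_selection_kill=0.0)
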