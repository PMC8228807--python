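import pytest

from chprev.acmg import classify_all
from chprev.genespec import DomainInterval, EngineConfig, GeneSpec, default_gene_specs
from chprev.simulate import default_simulation_config, sample_cohort
from chprev.variant_io import InSilicoScores, PopulationCounts, VariantRecord

#: fixed seed for every stochastic fixture in the suite
SEED = 20240601


@pytest.fixture(scope="session")
def toy_spec() -> GeneSpec:
    """1000-aa loss-of-function gene; NMD boundary at codon 950, one
    critical domain at residues 450..550."""
    return GeneSpec(
        gene="TOY",
        transcript="NM_TOY.1",
        coding_length_aa=1000,
        last_junction_cds=2850,
        domains=(DomainInterval(450, 550, "core"),),
    )


def make_record(**kwargs) -> VariantRecord:
    defaults = dict(
        gene="TOY",
        transcript="NM_TOY.1",
        hgvs_c="c.298C>T",
        hgvs_p="p.Gln100Ter",
        consequence="nonsense",
        loftee="HC",
        counts={"GLOBAL": PopulationCounts(2, 200000, 0)},
    )
    defaults.update(kwargs)
    return VariantRecord(**defaults)


def record_with_af(af: float, an: int = 100000, **kwargs) -> VariantRecord:
    ac = round(af * an)
    return make_record(counts={"GLOBAL": PopulationCounts(ac, an, 0)}, **kwargs)


@pytest.fixture(scope="session")
def simulated_study():
    """Default 12-gene, 7-population study sampled once per session."""
    config = default_simulation_config(seed=SEED)
    records, truth = sample_cohort(config)
    return config, records, truth


@pytest.fixture(scope="session")
def classified_study(simulated_study):
    config, records, truth = simulated_study
    specs = default_gene_specs()
    results = classify_all(
        records, specs, config.engine, pm3_observations=config.pm3_map()
    )
    return config, truth, results
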