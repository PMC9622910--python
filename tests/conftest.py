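import pytest

from tadlink.correlation import correlate_within_tads, filter_features
from tadlink.simulate import (
    CohortDesign,
    GenomeConfig,
    generate_cohort,
    generate_genome,
)


@pytest.fixture(scope="session")
def genome():
    """Default synthetic genome (2 x 10 Mb, 200 genes, 2,000 CpG sites)."""
    return generate_genome(GenomeConfig(), seed=1)


@pytest.fixture(scope="session")
def cohort_truth(genome):
    return generate_cohort(genome, CohortDesign(), seed=1)


@pytest.fixture(scope="session")
def discovery(genome, cohort_truth):
    """Filtered matrices plus the within-TAD correlation table (seed-1 cohort)."""
    cohort, truth = cohort_truth
    expr, meth = filter_features(cohort.expression, cohort.methylation)
    table = correlate_within_tads(expr, meth, genome.partition, genome.genes)
    return expr, meth, table, truth
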