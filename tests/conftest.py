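import numpy as np
import pytest

from cnvassoc import CohortSpec, GeneModel


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def diploid_gene():
    """Everyone carries exactly one copy per haplotype."""
    return GeneModel("DIP", (0.0, 1.0))


@pytest.fixture
def biallelic_gene():
    """Half the haplotypes are deleted: total CN ~ (0.25, 0.5, 0.25)."""
    return GeneModel("BI", (0.5, 0.5))


@pytest.fixture
def cnv_gene():
    """A CCL3L3-like gene with a nontrivial null class."""
    return GeneModel("CNV3", (0.159, 0.602, 0.239))


@pytest.fixture
def small_spec(cnv_gene, biallelic_gene):
    return CohortSpec(
        n_cases=80,
        n_controls=80,
        genes=(cnv_gene, biallelic_gene),
        case_or={"CNV3": (0, 5.0)},
        assay_failure_rate=0.0,
        low_dna_rate_cases=0.0,
        noise_cv=0.02,
        seed=11,
    )
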