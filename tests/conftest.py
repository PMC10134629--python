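import pytest

from priorpower import TestDesign
from priorpower.stats_core import TailConvention


@pytest.fixture
def gwas():
    """GWAS design, threshold 5e-8 treated as a single-tail area."""
    return TestDesign.gwas()


@pytest.fixture
def gwas_halved():
    """GWAS design with the two-sided-halved convention (zeta = 5.45)."""
    return TestDesign.gwas(TailConvention.TWO_SIDED_HALVED)


@pytest.fixture
def rnaseq():
    """RNAseq design: 25,000 gene tests at FWER 0.05 (threshold 2e-6)."""
    return TestDesign.rnaseq()
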