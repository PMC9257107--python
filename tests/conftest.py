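import numpy as np
import pandas as pd
import pytest

from tracegp.data import MarkerMap, PhasedGenotypes
from tracegp.simulate import make_fixture


@pytest.fixture(scope="session")
def tiny():
    """30 individuals, 200 SNPs, 2 traits."""
    return make_fixture("tiny", seed=11)


@pytest.fixture(scope="session")
def rice250():
    """The full calibrated panel: 250 individuals, ~5k SNPs, 5 traits."""
    return make_fixture("rice250", seed=7)


def geno_from_dosage(dosage: np.ndarray, pos=None, chrom=None) -> PhasedGenotypes:
    """Helper: wrap a dosage matrix as (arbitrarily phased) genotypes."""
    dosage = np.asarray(dosage)
    n, m = dosage.shape
    a = np.zeros((n, m, 2), dtype=np.uint8)
    a[:, :, 0] = dosage >= 1
    a[:, :, 1] = dosage >= 2
    pos = np.arange(1, m + 1) * 1000 if pos is None else np.asarray(pos)
    chrom = np.ones(m, dtype=int) if chrom is None else np.asarray(chrom)
    mmap = MarkerMap(
        pd.DataFrame(
            {"snp_id": [f"s{i}" for i in range(m)], "chrom": chrom, "pos_bp": pos}
        )
    )
    return PhasedGenotypes(alleles=a, map=mmap, ids=[f"i{i}" for i in range(n)])
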