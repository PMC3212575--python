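import numpy as np
import pytest

from polyfst.fst import SNPCounts, SNPPanel


@pytest.fixture
def rng():
    return np.random.default_rng(20211109)


def random_snp_counts(rng, snp_id="snp", r=None, n_max=80):
    """A random valid SNPCounts with 2..5 populations."""
    r = r or int(rng.integers(2, 6))
    n = rng.integers(2, n_max, size=r)
    n_AA = np.array([rng.integers(0, ni + 1) for ni in n])
    n_Aa = np.array([rng.integers(0, ni - aa + 1) for ni, aa in zip(n, n_AA)])
    n_aa = n - n_AA - n_Aa
    return SNPCounts(snp_id, n=n, n_AA=n_AA, n_Aa=n_Aa, n_aa=n_aa)


@pytest.fixture
def small_panel():
    """3 SNPs x 3 populations with assorted variation."""
    counts = np.array(
        [
            [[30, 20, 10], [10, 20, 30], [20, 20, 20]],   # polymorphic everywhere
            [[60, 0, 0], [60, 0, 0], [60, 0, 0]],         # monomorphic everywhere (same allele)
            [[59, 1, 0], [58, 2, 0], [59, 1, 0]],         # rare variant (MAF < 5% in all)
        ],
        dtype=float,
    )
    return SNPPanel(np.array(["rs1", "rs2", "rs3"], dtype=object), ["CEU", "YRI", "ASN"], counts)
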