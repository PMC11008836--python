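import numpy as np
import pandas as pd
import pytest

from msatqc import GenotypeDataset, Locus


def make_dataset(pairs, populations=None, sexes=None, loci=None, gps=None):
    """Build a small dataset from an (n, L, 2) array of allele sizes."""
    pairs = np.asarray(pairs, dtype=np.int64)
    if pairs.ndim == 2:
        pairs = pairs[:, None, :]
    n, L, _ = pairs.shape
    populations = list(populations) if populations is not None else ["pop1"] * n
    sexes = list(sexes) if sexes is not None else ["unknown"] * n
    loci = loci or [Locus(name=f"L{j + 1}") for j in range(L)]
    individuals = pd.DataFrame(
        {"id": [f"ind{i + 1}" for i in range(n)], "population": populations,
         "sex": sexes}
    )
    return GenotypeDataset(loci, individuals, pairs, populations=dict(gps or {}))


def anova_components(pair, codes):
    """Independent Weir-Cockerham oracle: moment ANOVA on allele indicators.

    Partitions indicator variance through nested mean squares (genes within
    individuals / individuals within populations / populations) rather than
    the closed-form estimator formulas, so it checks the implementation by a
    different route.  Returns summed (a, b, c) or None if uninformative.
    """
    from msatqc import MISSING

    ok = pair[:, 0] != MISSING
    pair, codes = pair[ok], codes[ok]
    alleles = np.unique(pair)
    if alleles.size < 2:
        return None
    pops = np.unique(codes)
    r = pops.size
    n_i = np.array([(codes == p).sum() for p in pops], dtype=float)
    N = n_i.sum()
    nc = (N - (n_i**2).sum() / N) / (r - 1)
    A = B = C = 0.0
    for u in alleles:
        y = (pair == u).astype(float)
        ybar_ij = y.mean(axis=1)
        MSG = np.sum((y - ybar_ij[:, None]) ** 2) / N
        SSI = SSP = 0.0
        ybar = y.mean()
        for pi, p in enumerate(pops):
            sel = codes == p
            ybar_i = y[sel].mean()
            SSI += 2 * np.sum((ybar_ij[sel] - ybar_i) ** 2)
            SSP += 2 * n_i[pi] * (ybar_i - ybar) ** 2
        MSI = SSI / (N - r)
        MSP = SSP / (r - 1)
        C += MSG
        B += (MSI - MSG) / 2
        A += (MSP - MSI) / (2 * nc)
    return A, B, C


@pytest.fixture
def two_pop_fixed():
    """Two populations fixed for different alleles: complete differentiation."""
    pairs = np.array([[100, 100]] * 8 + [[102, 102]] * 8)
    return make_dataset(pairs, populations=["a"] * 8 + ["b"] * 8)


@pytest.fixture
def hw_single_pop():
    """One population: 4 x AA, 2 x AB, 4 x BB (heterozygote deficit)."""
    pairs = np.array([[100, 100]] * 4 + [[100, 102]] * 2 + [[102, 102]] * 4)
    return make_dataset(pairs)
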