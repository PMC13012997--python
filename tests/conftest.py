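import numpy as np
import pytest

from mrlink.simulate import TwoSampleSimConfig, simulate_two_sample
from mrlink.sumstats import InstrumentSet, SummaryStatRecord, harmonize, kept_pairs


def make_record(snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
                beta=0.1, se=0.02, pval=None, n=10_000):
    """One valid record; p recomputed from z unless given."""
    from scipy import stats as sps
    if pval is None:
        pval = float(2 * sps.norm.sf(abs(beta / se)))
    return SummaryStatRecord(snp_id, chrom, pos, ea, oa, eaf, beta, se,
                             max(pval, 5e-324), n)


def simulated_instruments(theta=0.2, k=50, seed=0, **kwargs) -> InstrumentSet:
    """Instrument set over all simulated SNPs (no p-value selection, so the
    estimator sees the generating model's full instrument panel)."""
    cfg = TwoSampleSimConfig(k=k, theta=theta, seed=seed, **kwargs)
    exp, out = simulate_two_sample(cfg)
    pairs = kept_pairs(harmonize(exp, out))
    return InstrumentSet(pairs, 1.0, 0.001, 10_000,
                         np.array([p.f_stat for p in pairs]))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def strong_instruments():
    return simulated_instruments(theta=0.2, k=50, seed=7)
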