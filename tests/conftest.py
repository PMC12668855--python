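import numpy as np
import pandas as pd
import pytest

from mrmediate import HarmonizedPairs, SimulationConfig, SummaryStatSet, simulate_chain


def make_pairs(bx, sx, by, sy, **kw) -> HarmonizedPairs:
    return HarmonizedPairs.from_arrays(bx, sx, by, sy, **kw)


def random_pairs(rng, j=20, beta=0.3, se_exp=0.01, se_out=0.02, gamma_sd=0.1):
    """Clean two-sample summary data with true causal effect ``beta``."""
    gamma = rng.normal(0, gamma_sd, j)
    bx = gamma + rng.normal(0, se_exp, j)
    by = beta * gamma + rng.normal(0, se_out, j)
    return make_pairs(bx, np.full(j, se_exp), by, np.full(j, se_out))


def sumstat_frame(n=5, seed=0, p=None):
    rng = np.random.default_rng(seed)
    alleles = [("A", "G"), ("T", "C"), ("C", "A"), ("G", "T"), ("A", "C")]
    rows = []
    for i in range(n):
        ea, oa = alleles[i % len(alleles)]
        rows.append(
            {
                "snp_id": f"rs{i}",
                "chrom": str(i % 22 + 1),
                "pos": 1000 + i * 500000,
                "effect_allele": ea,
                "other_allele": oa,
                "beta": rng.normal(0, 0.1),
                "se": rng.uniform(0.01, 0.05),
                "pvalue": rng.uniform(1e-10, 0.9) if p is None else p[i],
                "eaf": rng.uniform(0.1, 0.9),
                "n": 5000,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def toy_set():
    return SummaryStatSet(sumstat_frame(5, seed=1), trait_id="toy")


@pytest.fixture
def chain_study():
    return simulate_chain(SimulationConfig(seed=42))
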