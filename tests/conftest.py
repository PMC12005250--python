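import numpy as np
import pandas as pd
import pytest

from cma.datatypes import PhenotypeTable, SimulationConfig, SumStats
from cma import synthetic_data


def make_sumstats(label, n, ids, beta, se, chrom=None, a1="A", a2="G", freq=0.3):
    """Minimal SumStats builder for unit tests."""
    m = len(ids)
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    rec = pd.DataFrame(
        {
            "id": ids,
            "chrom": chrom if chrom is not None else np.ones(m, int),
            "pos": np.arange(1, m + 1),
            "a1": a1,
            "a2": a2,
            "freq": freq,
            "n": n,
            "beta": beta,
            "se": se,
            "z": beta / se,
            "p": np.full(m, 0.5),
        }
    )
    return SumStats(cohort_label=label, n_samples=n, records=rec)


def null_pheno(geno, y):
    return PhenotypeTable(geno.sample_ids, y, np.zeros((geno.n_samples, 0)), "quantitative")


@pytest.fixture(scope="session")
def small_cohort():
    """1,000 unrelated + 200 sib pairs, heritable trait; shared across tests."""
    config = SimulationConfig(
        n_unrelated=1000,
        n_sib_pairs=200,
        n_variants=600,
        n_causal=60,
        h2=0.3,
        seed=11,
        mac_min_causal=50,
    )
    geno, relmap, y, effects = synthetic_data.simulate_cohort(config)
    return config, geno, relmap, y, effects
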