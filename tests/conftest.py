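import numpy as np
import pytest

from pairsig.datamodel import SurvivalData
from pairsig.synthetic import SimConfig, generate_two_cohorts


@pytest.fixture
def toy_surv6():
    """Six subjects: events at 1, 3, 3, 5; censored at 2 and 4."""
    return SurvivalData([f"s{i}" for i in range(6)],
                        [1.0, 2.0, 3.0, 3.0, 4.0, 5.0],
                        [1, 0, 1, 1, 0, 1])


@pytest.fixture(scope="session")
def small_two_cohorts():
    """A reduced two-cohort simulation shared across tests (16 genes,
    8 planted pairs, 120/150 samples)."""
    cfg = SimConfig(seed=11, n_genes=16, n_planted_pairs=8,
                    pair_effect_betas=(float(np.log(3)),) * 8,
                    n_samples=(120, 150))
    return cfg, generate_two_cohorts(cfg)


def make_exponential_surv(rng, n, hazard, cens_upper=None, label="OS"):
    """Exponential event times with optional uniform censoring."""
    hazard = np.broadcast_to(np.asarray(hazard, float), (n,))
    t = rng.exponential(1.0 / hazard)
    if cens_upper is None:
        time, event = t, np.ones(n, dtype=int)
    else:
        c = rng.uniform(0, cens_upper, n)
        time, event = np.minimum(t, c), (t <= c).astype(int)
    return SurvivalData([f"s{i}" for i in range(n)], time, event, label)
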