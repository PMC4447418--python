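import numpy as np
import pandas as pd
import pytest

from nestedvar.synthgen import default_config, empty_model_config, sample_cohort


def balanced_cohort(n_countries, mothers_per_country, babies_per_mother,
                    variances, seed, mu=3500.0):
    """Minimal balanced nested cohort: ids and birthweight only."""
    rng = np.random.default_rng(seed)
    s2_c, s2_m, s2_b = variances
    rows = []
    for k in range(n_countries):
        v = rng.normal(0.0, np.sqrt(s2_c))
        for j in range(mothers_per_country):
            u = rng.normal(0.0, np.sqrt(s2_m))
            for _ in range(babies_per_mother):
                e = rng.normal(0.0, np.sqrt(s2_b))
                rows.append((f"C{k:03d}", f"M{k:03d}_{j:03d}", mu + v + u + e))
    df = pd.DataFrame(rows, columns=["country_id", "mother_id", "birthweight"])
    df.insert(0, "baby_id", [f"B{i:05d}" for i in range(len(df))])
    return df


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure cohort scaled down for fast covariate-model fits."""
    cfg = default_config().replace(n_countries=20, n_mothers=2500)
    return sample_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def small_empty_cohort():
    """Covariate-free cohort: level variances equal the marginal ones."""
    cfg = empty_model_config().replace(n_countries=25, n_mothers=4000)
    return sample_cohort(cfg, seed=13)
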