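import numpy as np
import pandas as pd
import pytest

import poolgwas as pg


@pytest.fixture(scope="session")
def small_null():
    """A modest shared Monte-Carlo null (uniform frequencies)."""
    return pg.simulate_null("1", 500, 40, seed=321)


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no planted effects, default noise."""
    cfg = pg.CohortConfig(n_snps=400, seed=11)
    return pg.generate_cohort(cfg)


@pytest.fixture(scope="session")
def effect_cohort():
    """A cohort with one strong and one moderate planted risk allele."""
    cfg = pg.CohortConfig(
        n_snps=300, seed=23,
        effect_snps=(
            pg.EffectSnp(7, ("OMA", "DIE"), 1000.0),
            pg.EffectSnp(50, ("OMA",), 2.5),
        ),
    )
    return pg.generate_cohort(cfg)


def pool_frequency_matrix(cohort) -> tuple[pd.DataFrame, np.ndarray]:
    """Estimated F_A per pool x SNP next to the true allele-A pool freqs."""
    intensities = pg.simulate_intensities(cohort)
    pf = pg.allelotype_table(intensities)
    wide = pf.pivot_table(index="pool_id", columns="snp_id", values="F_A")
    wide = wide.loc[cohort.pool_ids, cohort.snp_ids]
    true_a = 1.0 - cohort.true_pool_freqs
    return wide, true_a
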