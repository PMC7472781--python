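import numpy as np
import pandas as pd
import pytest

from twinpk.config import StudyConfig


def quick_cohort(n_mz: int, n_dz: int, seed: int = 0) -> pd.DataFrame:
    """Minimal twin cohort table (no genotypes) for latent-trait tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for zyg, n in (("MZ", n_mz), ("DZ", n_dz)):
        for i in range(n):
            pid = f"{zyg}{i:05d}"
            age = float(rng.uniform(18, 40))
            sex = "F" if rng.random() < 0.6 else "M"
            for t in (1, 2):
                rows.append({"subject_id": f"{pid}_{t}", "pair_id": pid,
                             "zygosity": zyg, "sex": sex, "age": age})
    return pd.DataFrame(rows)


@pytest.fixture
def small_config() -> StudyConfig:
    """A fast-to-simulate study: 8 MZ + 4 DZ pairs, 3 occasions."""
    return StudyConfig(n_mz_pairs=8, n_dz_pairs=4, seed=123)


@pytest.fixture
def paper_design_config() -> StudyConfig:
    """The analysed cohort size: 43 MZ + 14 DZ pairs."""
    return StudyConfig(n_mz_pairs=43, n_dz_pairs=14, seed=7)
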