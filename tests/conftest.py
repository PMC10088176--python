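import numpy as np
import pandas as pd
import pytest

from sirpower import ReferenceStandard, RegistryConfig, generate_registry


@pytest.fixture
def two_stratum_reference() -> ReferenceStandard:
    """Two strata with risks 0.1 and 0.5, one reference hospital at a 50/50 mix."""
    return ReferenceStandard(
        strata=("a", "b"),
        lam=[0.1, 0.5],
        hospital_mixes=[[0.5, 0.5]],
        pooled_mix=[0.5, 0.5],
    )


@pytest.fixture
def single_stratum_reference() -> ReferenceStandard:
    """One stratum with risk 0.5; the SIR reduces to a one-sample proportion."""
    return ReferenceStandard(
        strata=("s",), lam=[0.5], hospital_mixes=[[1.0]], pooled_mix=[1.0]
    )


@pytest.fixture
def toy_exam_table() -> pd.DataFrame:
    """Two hospitals, two strata: h1 has 10 exams in A (3 high) and 10 in B
    (5 high); h2 has 20 exams in A (7 high)."""
    rows = []
    for hosp, stratum, n, k in [("h1", "A", 10, 3), ("h1", "B", 10, 5), ("h2", "A", 20, 7)]:
        for i in range(n):
            rows.append({"hospital_id": hosp, "stratum_id": stratum, "high_dose": int(i < k)})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_registry_config() -> RegistryConfig:
    """Scaled-down registry for fast module tests."""
    return RegistryConfig(
        n_hospitals=24, n_reference=16, hospital_size_range=(300, 3000), seed=11
    )


@pytest.fixture(scope="session")
def small_registry(small_registry_config) -> pd.DataFrame:
    return generate_registry(small_registry_config)


def random_reference(rng: np.random.Generator, J: int) -> tuple[ReferenceStandard, np.ndarray, float]:
    """Random (Λ, p, q) configuration for property checks."""
    lam = rng.uniform(0.05, 0.95, size=J)
    p = rng.dirichlet(np.full(J, 1.0))
    m = float(lam @ p)
    q = rng.uniform(0.2, 0.9) * min(1.0, 2.0 * m)
    ref = ReferenceStandard(
        strata=tuple(range(J)), lam=lam, hospital_mixes=[p], pooled_mix=p
    )
    return ref, p, q
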