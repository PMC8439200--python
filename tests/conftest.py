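import numpy as np
import pandas as pd
import pytest

from synchrometab import ExpressionStudy, default_config, simulate_study


def make_study(values: dict[str, list[float]], groups: dict[str, list[str]],
               doses: dict[str, float] | None = None) -> ExpressionStudy:
    """Tiny study builder: values maps metabolite -> per-sample abundances,
    groups maps group label -> sample ids (in matrix column order)."""
    sample_ids = [s for g in groups.values() for s in g]
    vals = pd.DataFrame(values, index=sample_ids).T
    design = pd.DataFrame(
        {
            "group": [g for g, ss in groups.items() for _ in ss],
            "dose": [float((doses or {}).get(g, 0.0))
                     for g, ss in groups.items() for _ in ss],
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    return ExpressionStudy(values=vals, design=design)


@pytest.fixture(scope="session")
def default_sim():
    """One draw from the default study conditions (41 metabolites,
    10 samples per group, six groups, three planted modules)."""
    return simulate_study(default_config(), seed=1)


@pytest.fixture(scope="session")
def default_study(default_sim):
    return default_sim[0]


@pytest.fixture(scope="session")
def default_truth(default_sim):
    return default_sim[1]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
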