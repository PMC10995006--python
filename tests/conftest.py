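import numpy as np
import pandas as pd
import pytest

from n2oeeg.classifiers import ModelSpec
from n2oeeg.spectra import build_feature_table
from n2oeeg.synthgen import CohortConfig, EffectProfile, generate_cohort


@pytest.fixture(scope="session")
def binary_features() -> pd.DataFrame:
    """Feature table of a default binary cohort (12 participants, 0/40%)."""
    config = CohortConfig(conditions=(0, 40), seed=0)
    return build_feature_table(generate_cohort(config, EffectProfile()))


@pytest.fixture(scope="session")
def multiclass_features() -> pd.DataFrame:
    """Feature table of a reduced four-condition cohort (fewer epochs)."""
    config = CohortConfig(conditions=(0, 20, 30, 40), n_epochs=8, seed=1)
    return build_feature_table(generate_cohort(config, EffectProfile()))


def make_table(
    n_participants: int,
    conditions,
    n_features: int = 8,
    effect: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Hand-built feature table: Gaussian features with an optional additive
    per-condition shift on the first half of the columns."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        offset = rng.normal(0, 1, size=n_features)
        for cond in conditions:
            x = offset + rng.normal(0, 0.3, size=n_features)
            x[: n_features // 2] += effect * cond
            row = {"participant_id": pid, "condition_pct": cond}
            row.update({f"f{j}": x[j] for j in range(n_features)})
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture()
def binary_spec() -> ModelSpec:
    return ModelSpec("binary-svm")
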