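import numpy as np
import pandas as pd
import pytest

from bodycomp import adjust, synth_cohort as sc, tables


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-design cohort: 100 per stratum, 1,200 records."""
    return sc.simulate_cohort(seed=0)


@pytest.fixture(scope="session")
def midsize_cohort():
    """Larger cohort (2,000 per stratum, 12,000 per sex) for statistical checks."""
    return sc.simulate_cohort(sc.default_design(2000), seed=1)


@pytest.fixture(scope="session")
def adjusted_default(default_cohort):
    cols = [tables.COLUMN_FOR_LABEL[v] for v in tables.CORR_LABELS]
    out = adjust.residual_adjust(default_cohort, cols)
    for am in out.values():
        am.data.columns = tables.CORR_LABELS
        am.labels = list(tables.CORR_LABELS)
    return out


def make_adjusted(x: np.ndarray, labels: list[str]) -> adjust.AdjustedMatrix:
    """Wrap a raw (already centered) array as an AdjustedMatrix for model fits."""
    x = np.asarray(x, float)
    x = x - x.mean(axis=0)
    return adjust.AdjustedMatrix(
        labels=list(labels),
        data=pd.DataFrame(x, columns=labels),
        covariates=[],
        coefficients=pd.DataFrame(index=["intercept"]),
    )
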