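"""Sample-level regression engine.

Ordinary least squares of each MRI compartment on the three anthropometric
predictors (BMI, WC, HC), all residual-adjusted for age and height; type-II
partial correlations with Fisher-z confidence intervals; variance inflation
factors; and bootstrap optimism correction of R².

"Type II sum of squares" is realized as the SSE comparison between the full
model and each leave-one-predictor-out model: the squared partial correlation
of predictor j is (SSE_without_j − SSE_full)/SSE_without_j, signed by the
full-model coefficient — the standard equivalence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .adjust import AdjustedMatrix
from .corrstats import fisher_ci


@dataclass
class PartialCorr:
    predictor: str
    r: float
    ci_low: float
    ci_high: float
    vif: float


@dataclass
class ModelFit:
    """One outcome regressed on a predictor set."""

    outcome: str
    predictors: list[str]
    coefficients: np.ndarray         # intercept first
    r2: float
    partials: list[PartialCorr]
    n: int

    @property
    def vifs(self) -> dict[str, float]:
        return {p.predictor: p.vif for p in self.partials}

    def partial(self, predictor: str) -> PartialCorr:
        for p in self.partials:
            if p.predictor == predictor:
                return p
        raise KeyError(predictor)


@dataclass
class OptimismResult:
    """Bootstrap optimism correction of an apparent R²."""

    apparent_r2: float
    optimism: float
    corrected_r2: float
    b: int
    seed: int

    def __post_init__(self):
        assert abs(self.corrected_r2 - (self.apparent_r2 - self.optimism)) < 1e-12


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares coefficients (with intercept) and SSE."""
    design = np.column_stack([np.ones(len(y)), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return coef, float(resid @ resid)


def _extract(adjusted: AdjustedMatrix, outcome: str,
             predictors: list[str]) -> tuple[np.ndarray, np.ndarray]:
    y = adjusted.column(outcome)
    x = np.column_stack([adjusted.column(p) for p in predictors])
    return x, y


def fit_model(adjusted: AdjustedMatrix, outcome: str,
              predictors: list[str], alpha: float = 0.05,
              vif_limit: float = 1e6) -> ModelFit:
    """OLS of one adjusted outcome on adjusted predictors.

    Returns R², per-predictor signed type-II partial correlations with
    Fisher-z CIs (standard error 1/sqrt(n − k − 3) where k is the number of
    conditioned covariates), and per-predictor VIFs.
    """
    x, y = _extract(adjusted, outcome, predictors)
    n, p = x.shape
    if n <= p + 1:
        raise ValueError(f"n={n} too small for {p} predictors")

    coef, sse_full = _ols(x, y)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError(f"zero-variance outcome {outcome!r}")
    r2 = 1.0 - sse_full / sst

    k = p - 1                                    # conditioned covariates per partial
    n_eff = n - k
    partials = []
    for j, name in enumerate(predictors):
        others = [i for i in range(p) if i != j]
        _, sse_red = _ols(x[:, others], y)
        rj2 = (sse_red - sse_full) / sse_red if sse_red > 0 else 0.0
        rj = math.copysign(math.sqrt(max(rj2, 0.0)), coef[1 + j])
        lo, hi = fisher_ci(rj, n_eff, alpha)
        # VIF_j = 1/(1 − R² of x_j on the other predictors)
        _, sse_x = _ols(x[:, others], x[:, j])
        sst_x = float(((x[:, j] - x[:, j].mean()) ** 2).sum())
        r2x = 1.0 - sse_x / sst_x if sst_x > 0 else 1.0
        if 1.0 - r2x < 1.0 / vif_limit:
            raise ValueError(
                f"predictor {name!r} is collinear with the others (VIF > {vif_limit:g})"
            )
        partials.append(PartialCorr(name, rj, lo, hi, 1.0 / (1.0 - r2x)))

    return ModelFit(outcome, list(predictors), coef, r2, partials, n)


def sample_corr_partial(adjusted: AdjustedMatrix, outcome: str, predictor: str,
                        others: list[str]) -> float:
    """Partial correlation via the correlation-matrix route, for cross-checks.

    Computes the sample correlation matrix of {outcome, predictor, others}
    and applies :func:`bodycomp.corrstats.partial_corr_from_corr`; must agree
    with the type-II route of :func:`fit_model` to numerical precision.
    """
    from .corrstats import partial_corr_from_corr

    cols = [outcome, predictor] + list(others)
    x = np.column_stack([adjusted.column(c) for c in cols])
    c = np.corrcoef(x, rowvar=False)
    return partial_corr_from_corr(c, 0, 1, list(range(2, len(cols))))


def optimism_bootstrap(adjusted: AdjustedMatrix, outcome: str,
                       predictors: list[str], b: int = 100,
                       seed: int = 0, resampler=None) -> OptimismResult:
    """Bootstrap estimate of R² optimism (overfitting).

    For each of ``b`` bootstrap resamples (rows with replacement, same n):
    refit, and record the drop in R² when the refitted coefficients are
    evaluated on the original sample.  Optimism is the mean drop; the
    corrected R² subtracts it from the apparent R².

    ``resampler`` (callable rng, n -> index array) overrides the row
    resampling, e.g. for degenerate-bootstrap checks.
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    x, y = _extract(adjusted, outcome, predictors)
    n = len(y)
    coef, sse = _ols(x, y)
    sst = float(((y - y.mean()) ** 2).sum())
    apparent = 1.0 - sse / sst

    rng = np.random.default_rng(seed)
    design = np.column_stack([np.ones(n), x])
    diffs = np.empty(b)
    for rep in range(b):
        for attempt in range(10):
            idx = resampler(rng, n) if resampler is not None else rng.integers(0, n, n)
            yb = y[idx]
            sst_b = float(((yb - yb.mean()) ** 2).sum())
            if sst_b > 0:
                break
            warnings.warn("zero-variance bootstrap outcome; resampling")
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap sample")
        db = design[idx]
        coef_b, *_ = np.linalg.lstsq(db, yb, rcond=None)
        resid_b = yb - db @ coef_b
        r2_boot = 1.0 - float(resid_b @ resid_b) / sst_b
        resid_o = y - design @ coef_b
        r2_orig = 1.0 - float(resid_o @ resid_o) / sst
        diffs[rep] = r2_boot - r2_orig

    optimism = float(diffs.mean())
    return OptimismResult(apparent, optimism, apparent - optimism, b, seed)
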