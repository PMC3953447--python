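"""Synthetic cohort generator for the MRI body-composition validation design.

Emulates, at the level of per-subject tabular records, a two-center validation
sub-study: ~300 men and ~300 women per center, equal representation of three
10-year baseline age bands, whole-body MRI compartment volumes (TBV, TAT, VAT,
SAT, CAT, SMT) plus measured anthropometry (height, weight, BMI, waist and hip
circumference).  The generator is calibrated so that

* per sex × age-band means track the published marginals (``tables.MARGINALS``);
* the sex-specific correlation matrices of the age/height-adjusted variables
  converge to the published 9×9 targets (``tables.adjusted_corr_target``);
* volume additivity holds exactly for every record: TAT = VAT + SAT + CAT and
  TBV = TAT + SMT + rest, because TAT and TBV are computed sums, never sampled;
* all volumes are strictly positive by construction;
* the unadjusted within-sex correlation of BMI with height is ≈ 0.2.

Model
-----
Baseline age is uniform within its band; sub-study age adds a uniform 14–17 y
follow-up lag.  Height is linear in age plus truncated-Gaussian noise (±3 SD).
Every other variable is  ``mean-line(age) + slope_h · (height − height-line(age))
+ residual``.  The residual vector over the eight *basic* variables (BMI, WC,
HC, VAT, SAT, CAT, SMT, rest) follows a Gaussian copula with shifted-gamma
margins: each margin is bounded below at −m (which guarantees positive
volumes), right-skewed like real adiposity data, and moment-matched so that
the *linear* covariances — and hence the covariances of the derived sums TAT
and TBV — are exact.  The Gaussian-scale pair correlations are solved from the
target linear correlations by Gauss–Hermite quadrature.

Because the published correlation targets include the derived sums, the
component covariance cannot be read off the tables directly; it is fitted by
least squares so that the induced correlation matrix of the nine published
variables reproduces the printed one (max abs residual < 0.005 per sex).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import brentq, least_squares
from scipy.special import gammaincinv, ndtr
from scipy.stats import truncnorm

from . import tables
from .corrstats import nearest_psd

#: basic (directly sampled) variables, in residual-vector order
BASICS = ["BMI", "WC", "HC", "VAT", "SAT", "CAT", "SMT", "REST"]
#: the five positive volume components (gamma-bounded margins)
VOLUME_COMPONENTS = ["VAT", "SAT", "CAT", "SMT", "REST"]

_BASIC_COL = {
    "BMI": "bmi", "WC": "waist_cm", "HC": "hip_cm", "VAT": "vat_l",
    "SAT": "sat_l", "CAT": "cat_l", "SMT": "smt_l",
}

#: cohort CSV schema, in column order
CSV_COLUMNS = [
    "subject_id", "center", "sex", "age_baseline", "age_substudy",
    "height_cm", "weight_kg", "bmi", "waist_cm", "hip_cm",
    "tbv_l", "tat_l", "vat_l", "sat_l", "cat_l", "smt_l", "rest_l",
    "weight_change_kg", "mri_usable",
]

# map from the 8 basics to the 9 published variables (TAT, TBV are sums)
_A_INDUCE = np.zeros((9, 8))
for _i, _lab in enumerate(tables.CORR_LABELS):
    if _lab in BASICS:
        _A_INDUCE[_i, BASICS.index(_lab)] = 1.0
_A_INDUCE[tables.CORR_LABELS.index("TAT"),
          [BASICS.index(c) for c in ("VAT", "SAT", "CAT")]] = 1.0
_A_INDUCE[tables.CORR_LABELS.index("TBV"),
          [BASICS.index(c) for c in VOLUME_COMPONENTS]] = 1.0


# ---------------------------------------------------------------------------
# design / marginal specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StratumSpec:
    """One sampling stratum: sex × center × baseline age band."""

    sex: Literal["male", "female"]
    center: Literal["A", "B"]
    age_band: tuple[int, int]          # inclusive baseline ages, e.g. (35, 44)
    n_target: int

    def __post_init__(self):
        if self.n_target <= 0:
            raise ValueError("n_target must be positive")


@dataclass(frozen=True)
class MarginalSpec:
    """Published mean/min/max of one variable in one sex × age-band cell."""

    variable: str
    mean: float
    min: float
    max: float

    def __post_init__(self):
        if not (self.min < self.mean < self.max):
            raise ValueError(
                f"{self.variable}: need min < mean < max, got "
                f"({self.min}, {self.mean}, {self.max})"
            )


def derive_sd(marginal: MarginalSpec, rule: str = "range4") -> float:
    """Spread from a published range: (max − min)/4 or /6.

    The published tables print mean (min, max) only; for ~200 near-Gaussian
    observations the sample range spans roughly 4 standard deviations, hence
    the default ``range4`` rule.
    """
    if marginal.max == marginal.min:
        raise ValueError(f"{marginal.variable}: degenerate range (min == max)")
    div = {"range4": 4.0, "range6": 6.0}.get(rule)
    if div is None:
        raise ValueError(f"unknown sd rule {rule!r}")
    return (marginal.max - marginal.min) / div


def default_design(n_per_stratum: int = 100) -> list[StratumSpec]:
    """The 12-stratum rectangular design: 2 sexes × 2 centers × 3 age bands."""
    return [
        StratumSpec(sex, center, band, n_per_stratum)
        for sex in ("male", "female")
        for center in ("A", "B")
        for band in tables.BASELINE_AGE_BANDS
    ]


def default_marginals(sex: str) -> dict[str, list[MarginalSpec]]:
    """Published marginal specs per variable, one per age band."""
    return {
        var: [MarginalSpec(var, *m) for m in cells]
        for var, cells in tables.MARGINALS[sex].items()
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Tunable constants of the cohort generator.

    Slopes are per cm of height deviation; the BMI height slope is not listed
    because it is solved so that the unadjusted within-sex BMI–height
    correlation equals ``bmi_height_r``.
    """

    n_per_stratum: int = 100
    sd_rule: str = "range4"
    bmi_height_r: float = 0.2
    height_slopes: tuple[tuple[str, float], ...] = (
        ("WC", 0.15), ("HC", 0.20), ("VAT", 0.010), ("SAT", 0.050),
        ("CAT", 0.001), ("SMT", 0.180), ("REST", 0.200),
    )
    follow_up_lag: tuple[float, float] = (14.0, 17.0)
    trunc_z: float = 3.0               # height noise truncated at ±trunc_z SD
    circumference_noise_sd: float = 0.3  # per raw tape reading, cm
    positivity_margin: float = 0.9     # gamma bound at margin × worst-case mean
    anthro_margin_sds: float = 3.0     # gamma bound for anthro residuals
    corr_fit_reg: tuple[float, float] = (0.005, 0.01)
    truncate_to_range: bool = False    # clip to published min/max (display only)
    early_adult_bmi: tuple[tuple[str, float], ...] = (("male", 23.0), ("female", 21.5))
    early_bmi_tracking: float = 0.35
    early_bmi_sd: float = 1.5
    recall_noise_sd: float = 2.0
    weight_change_missing_rate: float = 97.0 / 1192.0

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

_GH_NODES, _GH_W = hermegauss(40)
_GH_W = _GH_W / _GH_W.sum()


def _std_gamma(k: float, z: np.ndarray) -> np.ndarray:
    """Standardized shifted-gamma quantile at Gaussian scores z.

    (Q_gamma(Φ(z); k) − k)/√k: mean 0, variance 1, bounded below at −√k.
    """
    u = np.clip(ndtr(z), 1e-300, 1 - 1e-16)
    return (gammaincinv(k, u) - k) / np.sqrt(k)


def _copula_rho(k1: float, k2: float, r_target: float) -> float:
    """Gaussian-scale correlation giving linear correlation r_target between
    two standardized shifted-gamma margins (Gauss–Hermite quadrature)."""
    if r_target == 0.0:
        return 0.0
    f1 = _std_gamma(k1, _GH_NODES)

    def lin(rho: float) -> float:
        zz = rho * _GH_NODES[:, None] + np.sqrt(max(1 - rho * rho, 0.0)) * _GH_NODES[None, :]
        return float(_GH_W @ (f1[:, None] * _std_gamma(k2, zz)) @ _GH_W)

    return brentq(lambda r: lin(r) - r_target, -0.9995, 0.9995, xtol=1e-10)


def _weighted_line(ages: np.ndarray, values: np.ndarray,
                   weights: np.ndarray) -> tuple[float, float]:
    """Weighted least-squares line through per-band means; (intercept, slope)."""
    slope, intercept = np.polyfit(ages, values, 1, w=np.sqrt(weights))
    return float(intercept), float(slope)


def fit_component_covariance(
    target: pd.DataFrame,
    sd_init: dict[str, float],
    reg: tuple[float, float] = (0.005, 0.01),
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit the 8-basic correlation matrix + component SDs so that the induced
    correlation matrix of the 9 published variables matches ``target``.

    The published matrix includes the derived sums TAT and TBV, so it
    over-determines the component covariance; the printed values came from
    data in which additivity held exactly, which is why a small-residual
    solution exists.  Returns (R_basis 8×8, sd 8-vector with anthro slots = 1,
    max abs fit residual).
    """
    T = target.to_numpy(float)
    iu8 = np.triu_indices(8, 1)
    pub = {lab: i for i, lab in enumerate(tables.CORR_LABELS)}

    def init_r(a: str, b: str) -> float:
        if a in pub and b in pub:
            return T[pub[a], pub[b]]
        other = a if b == "REST" else b           # one of the pair is REST
        if other == "SMT":
            return 0.35
        return 0.15 if other in ("BMI", "WC", "HC") else 0.10

    r0 = np.array([init_r(BASICS[i], BASICS[j]) for i, j in zip(*iu8)])
    ls0 = np.log([sd_init[c] for c in VOLUME_COMPONENTS])
    tiu = np.triu_indices(9, 1)
    tvals = T[tiu]
    wr, ws = reg

    def unpack(p):
        R = np.eye(8)
        R[iu8] = p[:28]
        R.T[iu8] = p[:28]
        sd = np.ones(8)
        for k, c in enumerate(VOLUME_COMPONENTS):
            sd[BASICS.index(c)] = np.exp(p[28 + k])
        return R, sd

    def resid(p):
        R, sd = unpack(p)
        S = R * np.outer(sd, sd)
        ind = _A_INDUCE @ S @ _A_INDUCE.T
        d = np.sqrt(np.diag(ind))
        C = ind / np.outer(d, d)
        ev = np.linalg.eigvalsh(R).min()
        return np.concatenate([
            C[tiu] - tvals,
            wr * (p[:28] - r0),
            ws * (p[28:] - ls0),
            [100.0 * max(0.0, 5e-3 - ev)],
        ])

    sol = least_squares(
        resid, np.concatenate([r0, ls0]),
        bounds=(np.concatenate([-0.98 * np.ones(28), ls0 - np.log(4)]),
                np.concatenate([0.98 * np.ones(28), ls0 + np.log(4)])),
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000,
    )
    R, sd = unpack(sol.x)
    S = R * np.outer(sd, sd)
    ind = _A_INDUCE @ S @ _A_INDUCE.T
    d = np.sqrt(np.diag(ind))
    fit_err = float(np.abs(ind / np.outer(d, d) - T)[tiu].max())
    return R, sd, fit_err


@dataclass
class SexCalibration:
    """Frozen per-sex generation parameters."""

    sex: str
    age_ref: float                          # centering age for the mean lines
    lines: dict[str, tuple[float, float]]   # variable -> (value at age_ref, slope/yr)
    height_sd: float                        # residual height SD (pre-truncation)
    height_slopes: dict[str, float]         # per-cm-of-height slopes incl. BMI
    resid_sd: np.ndarray                    # 8-vector, basic-variable order
    gamma_shape: np.ndarray                 # 8-vector
    chol: np.ndarray                        # Cholesky of Gaussian-scale corr
    fit_err: float
    copula_repaired: bool


_CALIB_CACHE: dict[tuple[str, str], SexCalibration] = {}


def _age_stats(config: GeneratorConfig) -> tuple[float, float, float]:
    """(overall age variance, within-band age variance, mean sub-study age)."""
    mids = np.array([(lo + hi + 1) / 2 for lo, hi in tables.BASELINE_AGE_BANDS])
    lag_lo, lag_hi = config.follow_up_lag
    within = 100.0 / 12.0 + (lag_hi - lag_lo) ** 2 / 12.0
    total = within + np.var(mids)
    mean_age = mids.mean() + (lag_lo + lag_hi) / 2
    return float(total), float(within), float(mean_age)


def calibrate(sex: str, config: GeneratorConfig | None = None) -> SexCalibration:
    """Build (and cache) all deterministic generation parameters for one sex."""
    config = config or GeneratorConfig()
    key = (sex, config.digest())
    if key in _CALIB_CACHE:
        return _CALIB_CACHE[key]

    marg = default_marginals(sex)
    counts = np.array(tables.BAND_COUNTS[sex], float)
    mids = np.array([(lo + hi + 1) / 2 for lo, hi in tables.BASELINE_AGE_BANDS])
    lag_mid = sum(config.follow_up_lag) / 2
    band_ages = mids + lag_mid
    v_age, v_age_within, age_ref = _age_stats(config)

    def band_sds(var: str) -> float:
        return float(np.mean([derive_sd(m, config.sd_rule) for m in marg[var]]))

    # mean lines (weighted by realized band counts), centered at age_ref
    lines: dict[str, tuple[float, float]] = {}
    for var in marg:
        b0, b1 = _weighted_line(band_ages - age_ref,
                                np.array([m.mean for m in marg[var]]), counts)
        lines[var] = (b0, b1)
    # rest closes the TBV identity band by band
    rest_means = (np.array([m.mean for m in marg["tbv_l"]])
                  - np.array([m.mean for m in marg["tat_l"]])
                  - np.array([m.mean for m in marg["smt_l"]]))
    lines["rest_l"] = _weighted_line(band_ages - age_ref, rest_means, counts)

    # height: residual SD net of the within-band age trend
    sd_h_range = band_sds("height_cm")
    slope_h = lines["height_cm"][1]
    height_sd = float(np.sqrt(max(sd_h_range ** 2 - slope_h ** 2 * v_age_within,
                                  (0.5 * sd_h_range) ** 2)))
    tz = config.trunc_z
    trunc_var = float(truncnorm.var(-tz, tz)) * height_sd ** 2

    # height slopes; BMI's solved for the target unadjusted BMI-height corr
    hslopes = dict(config.height_slopes)
    ba_bmi = lines["bmi"][1]
    var_bmi = band_sds("bmi") ** 2 + ba_bmi ** 2 * (v_age - v_age_within)
    var_h = slope_h ** 2 * v_age + trunc_var
    hslopes["BMI"] = float(
        (config.bmi_height_r * np.sqrt(var_bmi * var_h) - ba_bmi * slope_h * v_age)
        / trunc_var
    )

    # residual SDs: published within-band spread net of age and height terms
    def resid_sd_of(var: str, basic: str) -> float:
        tot = band_sds(var)
        b_age = lines[var][1]
        b_h = hslopes[basic]
        net = tot ** 2 - b_age ** 2 * v_age_within - b_h ** 2 * trunc_var
        return float(np.sqrt(max(net, (0.4 * tot) ** 2)))

    sd_init = {c: resid_sd_of(_BASIC_COL[c], c) for c in
               ("VAT", "SAT", "CAT", "SMT")}
    rest_tot = 0.08 * float(np.average(rest_means, weights=counts))
    sd_init["REST"] = float(np.sqrt(max(
        rest_tot ** 2 - lines["rest_l"][1] ** 2 * v_age_within
        - hslopes["REST"] ** 2 * trunc_var, (0.4 * rest_tot) ** 2)))

    R, sd, fit_err = fit_component_covariance(
        tables.adjusted_corr_target(sex), sd_init, config.corr_fit_reg)
    for k, lab in enumerate(("BMI", "WC", "HC")):
        sd[k] = resid_sd_of(_BASIC_COL[lab], lab)

    # gamma lower bounds: worst-case conditional mean for volumes, k·SD for anthro
    ages = np.linspace(band_ages[0] - 7, band_ages[-1] + 7, 50) - age_ref
    bound = np.empty(8)
    for k, lab in enumerate(BASICS):
        if lab in VOLUME_COMPONENTS:
            col = "rest_l" if lab == "REST" else _BASIC_COL[lab]
            b0, b1 = lines[col]
            mu_min = (b0 + b1 * ages).min() - abs(hslopes[lab]) * tz * height_sd
            if mu_min <= 0:
                raise ValueError(f"{sex}/{lab}: conditional mean can reach {mu_min:.3f}")
            bound[k] = config.positivity_margin * mu_min
        else:
            bound[k] = config.anthro_margin_sds * sd[k]
    shape = (bound / sd) ** 2

    # Gaussian-scale correlations via the copula distortion
    psi = np.eye(8)
    for i in range(8):
        for j in range(i):
            psi[i, j] = psi[j, i] = _copula_rho(shape[i], shape[j], R[i, j])
    repaired = bool(np.linalg.eigvalsh(psi).min() < 1e-8)
    if repaired:
        psi = nearest_psd(psi)
    chol = np.linalg.cholesky(psi + 1e-12 * np.eye(8))

    calib = SexCalibration(
        sex=sex, age_ref=age_ref, lines=lines, height_sd=height_sd,
        height_slopes=hslopes, resid_sd=sd, gamma_shape=shape, chol=chol,
        fit_err=fit_err, copula_repaired=repaired,
    )
    _CALIB_CACHE[key] = calib
    return calib


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def triple_measure(true_value, noise_sd: float, rng) -> np.ndarray:
    """Mean of three independent noisy tape readings of a circumference.

    Output variance is noise_sd²/3 around the true value.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    true_value = np.asarray(true_value, float)
    readings = true_value[..., None] + noise_sd * rng.standard_normal(true_value.shape + (3,))
    return readings.mean(axis=-1)


def simulate_cohort(
    design: list[StratumSpec] | None = None,
    config: GeneratorConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a synthetic cohort table.

    Deterministic given (design, config, seed); volume additivity identities
    hold exactly for every record and all volumes are positive.
    """
    config = config or GeneratorConfig()
    if design is None:
        design = default_design(config.n_per_stratum)
    rng = np.random.default_rng(seed)
    lag_lo, lag_hi = config.follow_up_lag
    early_bmi_ref = dict(config.early_adult_bmi)
    marg = {s: default_marginals(s) for s in ("male", "female")}

    frames = []
    offset = 0
    for stratum in design:
        cal = calibrate(stratum.sex, config)
        n = stratum.n_target
        lo, hi = stratum.age_band
        age_base = rng.uniform(lo, hi + 1, n)
        age_sub = age_base + rng.uniform(lag_lo, lag_hi, n)
        t = age_sub - cal.age_ref

        b0h, b1h = cal.lines["height_cm"]
        mu_h = b0h + b1h * t
        height = mu_h + cal.height_sd * truncnorm.rvs(
            -config.trunc_z, config.trunc_z, size=n, random_state=rng)
        dh = height - mu_h

        g = rng.standard_normal((n, 8)) @ cal.chol.T
        resid = np.empty_like(g)
        for k in range(8):
            resid[:, k] = cal.resid_sd[k] * _std_gamma(cal.gamma_shape[k], g[:, k])

        vals = {}
        for k, lab in enumerate(BASICS):
            col = "rest_l" if lab == "REST" else _BASIC_COL[lab]
            b0, b1 = cal.lines[col]
            vals[lab] = b0 + b1 * t + cal.height_slopes[lab] * dh + resid[:, k]

        for lab in VOLUME_COMPONENTS:
            if (vals[lab] <= 0).any():     # impossible by construction
                raise AssertionError(f"non-positive {lab} volume generated")

        bmi = vals["BMI"]
        weight = bmi * (height / 100.0) ** 2
        waist = triple_measure(vals["WC"], config.circumference_noise_sd, rng)
        hip = triple_measure(vals["HC"], config.circumference_noise_sd, rng)
        tat = vals["VAT"] + vals["SAT"] + vals["CAT"]
        tbv = tat + vals["SMT"] + vals["REST"]

        early_bmi = (early_bmi_ref[stratum.sex]
                     + config.early_bmi_tracking * (bmi - bmi.mean())
                     + config.early_bmi_sd * rng.standard_normal(n))
        weight_change = (weight - early_bmi * (height / 100.0) ** 2
                         + config.recall_noise_sd * rng.standard_normal(n))
        missing = rng.random(n) < config.weight_change_missing_rate
        weight_change = np.where(missing, np.nan, weight_change)

        df = pd.DataFrame({
            "subject_id": [f"S{offset + i + 1:06d}" for i in range(n)],
            "center": stratum.center,
            "sex": stratum.sex,
            "age_baseline": age_base,
            "age_substudy": age_sub,
            "height_cm": height,
            "weight_kg": weight,
            "bmi": bmi,
            "waist_cm": waist,
            "hip_cm": hip,
            "tbv_l": tbv,
            "tat_l": tat,
            "vat_l": vals["VAT"],
            "sat_l": vals["SAT"],
            "cat_l": vals["CAT"],
            "smt_l": vals["SMT"],
            "rest_l": vals["REST"],
            "weight_change_kg": weight_change,
            "mri_usable": True,
        })
        if config.truncate_to_range:
            band_idx = tables.BASELINE_AGE_BANDS.index(stratum.age_band)
            for var, cells in marg[stratum.sex].items():
                cell = cells[band_idx]
                df[var] = df[var].clip(cell.min, cell.max)
        frames.append(df)
        offset += n

    cohort = pd.concat(frames, ignore_index=True)
    cohort.attrs["seed"] = seed
    cohort.attrs["config_digest"] = config.digest()
    return cohort


def apply_exclusions(cohort: pd.DataFrame, mri_failure_rate: float,
                     seed: int = 0) -> pd.DataFrame:
    """Flag a deterministic count round(rate·n) of records as MRI failures
    (random identity) and return the usable subset."""
    if not 0 <= mri_failure_rate < 1:
        raise ValueError("mri_failure_rate must be in [0, 1)")
    n = len(cohort)
    k = int(np.floor(mri_failure_rate * n + 0.5))
    out = cohort.copy()
    if k > 0:
        rng = np.random.default_rng(seed)
        bad = rng.choice(n, size=k, replace=False)
        out.iloc[bad, out.columns.get_loc("mri_usable")] = False
    usable = out[out["mri_usable"]].copy()
    usable.attrs = dict(cohort.attrs)
    return usable


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write the cohort in the canonical CSV schema (empty field = missing)."""
    cohort.to_csv(path, index=False, columns=CSV_COLUMNS)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; raises on schema violations."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("cohort file has no data rows")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()[:5]
        raise ValueError(f"duplicate subject_id values: {dup}")
    bad_sex = set(df["sex"].unique()) - {"male", "female"}
    if bad_sex:
        raise ValueError(f"invalid sex values: {sorted(bad_sex)}")
    complete = [c for c in CSV_COLUMNS if c != "weight_change_kg"]
    na_cols = [c for c in complete if df[c].isna().any()]
    if na_cols:
        raise ValueError(f"missing values in required columns: {na_cols}")
    df["mri_usable"] = df["mri_usable"].astype(bool)
    return df
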