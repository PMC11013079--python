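"""Synthetic ACS cohort generator with known ground truth.

Emulates a prospective acute-coronary-syndrome cohort (default n = 309,
~10-year administrative follow-up, no dropout): Table-1-like clinical
covariates, 16 collinear log-normal plasma bile acids, and proportional-
hazards event generation for a composite cardiovascular endpoint (MACE =
myocardial infarction, heart-failure hospitalization, or all-cause death)
plus all-cause death itself. Because death is a component of the composite,
every generated subject satisfies event_death = 1 => event_mace = 1 and
time_mace <= time_death.

Event times are drawn from exponential proportional-hazards laws whose
linear predictor is covariate_beta . covariates + true_beta . Z, where Z is
the latent standard-normal metabolite matrix (the population analogue of the
inverse-normal-transformed concentrations). The hidden truth block (true
linear predictors, true standardized risk scores, pre-missingness
concentrations) is retained for synthetic cohorts only, giving every
downstream stage a parameter-recovery oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

BA_NAMES = [
    "CA", "CDCA", "DCA", "GCA", "GCDCA", "GUDCA", "GDCA", "HDCA",
    "LCA", "TCA", "TCDCA", "TDCA", "TUDCA", "UDCA", "GLCA", "TLCA",
]

# parent-bile-acid families drive the collinearity factor structure
_BA_FAMILY = {
    "CA": 0, "GCA": 0, "TCA": 0,
    "CDCA": 1, "GCDCA": 1, "TCDCA": 1,
    "DCA": 2, "GDCA": 2, "TDCA": 2,
    "UDCA": 3, "GUDCA": 3, "TUDCA": 3,
    "LCA": 4, "GLCA": 4, "TLCA": 4,
    "HDCA": 5,
}
_GLOBAL_LOADING = 0.30   # shared bile-acid pool level
_FAMILY_LOADING = 0.45   # conjugates of one parent move together

# typical plasma locations (log nmol/L) and log-scale spreads
_BA_LOG_MEAN = {
    "CA": 4.0, "CDCA": 4.6, "DCA": 5.5, "GCA": 5.0, "GCDCA": 6.2,
    "GUDCA": 4.7, "GDCA": 5.1, "HDCA": 3.3, "LCA": 2.8, "TCA": 3.4,
    "TCDCA": 4.8, "TDCA": 3.9, "TUDCA": 2.5, "UDCA": 4.2,
    "GLCA": 2.9, "TLCA": 2.2,
}
_BA_LOG_SD = 0.9

# signs follow the reported MACE / mortality coefficient signatures
_MACE_SIGNS = {
    "DCA": +1, "CDCA": +1, "GCA": +1, "GUDCA": +1,
    "CA": -1, "TDCA": -1, "GCDCA": -1, "HDCA": -1, "UDCA": -1, "LCA": -1,
}
_DEATH_SIGNS = {"DCA": +1, "GCA": +1, "CA": -1, "HDCA": -1}

# per-metabolite |log HR per SD|, calibrated by large-n simulation so the
# confounder-adjusted HR per 1 SD of the true standardized score is ~1.35
# for MACE and ~1.31 for all-cause death (see docs/methods.md)
_MACE_EFFECT = 0.1693
_DEATH_EFFECT = 0.1489

# baseline exponential rates (per year), calibrated so a 309-subject cohort
# yields on average ~131 composite events and ~90 deaths over 10 years
_RATE_MI = 0.0111
_RATE_HF = 0.0089
_RATE_DEATH = 0.0289

_COVARIATE_PREVALENCES = {
    "age": (64.9, 12.3),
    "men": 0.712,
    "bmi": (28.1, 4.0),
    "t2d": 0.372,
    "hypertension": 0.676,
    "dyslipidemia": 0.608,
    "smoking": (0.356, 0.339, 0.304),       # never / former / current
    "diagnosis": (0.159, 0.220, 0.620),     # UA / STEMI / NSTEMI (renormalized)
    "statin": 0.505,
    "beta_blocker": 0.304,
    "aspirin": 0.405,
    "diuretic": 0.252,
    "oad": 0.227,
    "insulin": 0.087,
    "egfr_median": 81.3,
}

# log hazard ratios for the clinical confounder design (see design_columns)
_COVARIATE_BETA = {
    "age": 0.040, "sex": 0.25, "bmi": 0.015,
    "smoke_former": 0.10, "smoke_current": 0.35,
    "hypertension": 0.25, "dyslipidemia": 0.10, "t2d": 0.35,
    "dx_stemi": 0.10, "dx_nstemi": 0.15,
    "statin": -0.25, "beta_blocker": -0.10, "aspirin": -0.10,
    "diuretic": 0.25, "oad": 0.0, "insulin": 0.30,
    "egfr": -0.012,
}
# centering constants so the baseline rate refers to an average subject
_COVARIATE_CENTER = {
    "age": 64.9, "sex": 0.712, "bmi": 28.1,
    "smoke_former": 0.339, "smoke_current": 0.304,
    "hypertension": 0.676, "dyslipidemia": 0.608, "t2d": 0.372,
    "dx_stemi": 0.220, "dx_nstemi": 0.620,
    "statin": 0.505, "beta_blocker": 0.304, "aspirin": 0.405,
    "diuretic": 0.252, "oad": 0.227, "insulin": 0.087,
    "egfr": 79.3,
}

CONFOUNDER_COLUMNS = list(_COVARIATE_BETA)

# fixed per-metabolite missingness; TUDCA sits above the 20% filter,
# the other 15 average ~1.9% (range 0-8.7%)
_MISSING_RATES = {
    "CA": 0.010, "CDCA": 0.000, "DCA": 0.032, "GCA": 0.000, "GCDCA": 0.013,
    "GUDCA": 0.049, "GDCA": 0.000, "HDCA": 0.087, "LCA": 0.026, "TCA": 0.000,
    "TCDCA": 0.010, "TDCA": 0.000, "TUDCA": 0.250, "UDCA": 0.016,
    "GLCA": 0.039, "TLCA": 0.007,
}


def default_ba_correlation() -> np.ndarray:
    """Factor-model correlation among log bile-acid concentrations (PSD by
    construction): one global factor plus one factor per parent family."""
    k = len(BA_NAMES)
    n_fam = max(_BA_FAMILY.values()) + 1
    load = np.zeros((k, 1 + n_fam))
    for i, name in enumerate(BA_NAMES):
        load[i, 0] = _GLOBAL_LOADING
        load[i, 1 + _BA_FAMILY[name]] = _FAMILY_LOADING
    corr = load @ load.T
    np.fill_diagonal(corr, 1.0)
    return corr


def _signed_effects(signs: dict, magnitude: float) -> np.ndarray:
    beta = np.zeros(len(BA_NAMES))
    for name, s in signs.items():
        beta[BA_NAMES.index(name)] = s * magnitude
    return beta


@dataclass
class CohortSpec:
    """Full parameterization of one synthetic cohort draw."""

    n_subjects: int = 309
    ba_names: list[str] = field(default_factory=lambda: list(BA_NAMES))
    ba_log_mean: np.ndarray = field(
        default_factory=lambda: np.array([_BA_LOG_MEAN[b] for b in BA_NAMES]))
    ba_log_cov: np.ndarray = field(
        default_factory=lambda: default_ba_correlation() * _BA_LOG_SD**2)
    covariate_prevalences: dict = field(
        default_factory=lambda: dict(_COVARIATE_PREVALENCES))
    true_beta_mace: np.ndarray = field(
        default_factory=lambda: _signed_effects(_MACE_SIGNS, _MACE_EFFECT))
    true_beta_death: np.ndarray = field(
        default_factory=lambda: _signed_effects(_DEATH_SIGNS, _DEATH_EFFECT))
    covariate_beta: dict = field(default_factory=lambda: dict(_COVARIATE_BETA))
    baseline_hazard: dict = field(default_factory=lambda: {
        "mi": _RATE_MI, "hf": _RATE_HF, "death": _RATE_DEATH})
    censor_horizon: float = 10.0
    missing_rates: dict = field(default_factory=lambda: dict(_MISSING_RATES))
    bmi_missing_rate: float = 0.02
    missing_mechanism: str = "mcar"      # or "mar_age"
    composite_mode: str = "latent"       # or "single"
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        cov = np.asarray(self.ba_log_cov, dtype=float)
        k = len(self.ba_names)
        if cov.shape != (k, k) or not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("ba_log_cov must be a symmetric (k, k) matrix")
        if np.linalg.eigvalsh(cov).min() < -1e-8:
            raise ValueError("ba_log_cov is not positive semi-definite")
        for name, rate in self.missing_rates.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"missing rate for {name} outside [0, 1]")
        if not 0 <= self.bmi_missing_rate <= 1:
            raise ValueError("bmi_missing_rate outside [0, 1]")
        for key, rate in self.baseline_hazard.items():
            if rate <= 0:
                raise ValueError(f"baseline hazard {key!r} must be > 0")
        if self.censor_horizon <= 0:
            raise ValueError("censor_horizon must be > 0")
        if self.missing_mechanism not in ("mcar", "mar_age"):
            raise ValueError("missing_mechanism must be 'mcar' or 'mar_age'")
        if self.composite_mode not in ("latent", "single"):
            raise ValueError("composite_mode must be 'latent' or 'single'")

    def with_(self, **changes) -> "CohortSpec":
        return replace(self, **changes)


@dataclass
class CohortTable:
    """Subjects x {outcomes, covariates, bile acids}; the pipeline currency.

    ``truth`` carries the hidden ground-truth block (linear predictors, true
    standardized scores, pre-missingness concentrations) and exists only for
    synthetic cohorts.
    """

    data: pd.DataFrame
    truth: pd.DataFrame | None = None
    provenance: str = "synthetic"

    def ba_columns(self) -> list[str]:
        return [c for c in self.data.columns if c in BA_NAMES]

    def copy(self) -> "CohortTable":
        return CohortTable(
            data=self.data.copy(),
            truth=None if self.truth is None else self.truth.copy(),
            provenance=self.provenance,
        )


def design_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Expand the cohort schema into the 17-column confounder design.

    Smoking (0 never / 1 former / 2 current) becomes two dummies and the
    exhaustive discharge-diagnosis dummies are reduced to STEMI/NSTEMI with
    unstable angina as reference, keeping the design full-rank in a model
    without intercept.
    """
    out = pd.DataFrame(index=df.index)
    out["age"] = df["age"]
    out["sex"] = df["sex"]
    out["bmi"] = df["bmi"]
    out["smoke_former"] = (df["smoking"] == 1).astype(float)
    out["smoke_current"] = (df["smoking"] == 2).astype(float)
    for c in ("hypertension", "dyslipidemia", "t2d", "dx_stemi", "dx_nstemi",
              "statin", "beta_blocker", "aspirin", "diuretic", "oad",
              "insulin", "egfr"):
        out[c] = df[c].astype(float)
    return out


def _draw_covariates(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_subjects
    prev = spec.covariate_prevalences
    df = pd.DataFrame(index=range(n))
    mu_age, sd_age = prev["age"]
    df["age"] = rng.normal(mu_age, sd_age, n)
    df["sex"] = (rng.uniform(size=n) < prev["men"]).astype(int)
    mu_bmi, sd_bmi = prev["bmi"]
    df["bmi"] = np.clip(rng.normal(mu_bmi, sd_bmi, n), 15.0, None)
    p_smoke = np.asarray(prev["smoking"], dtype=float)
    df["smoking"] = rng.choice(3, size=n, p=p_smoke / p_smoke.sum())
    df["hypertension"] = (rng.uniform(size=n) < prev["hypertension"]).astype(int)
    df["dyslipidemia"] = (rng.uniform(size=n) < prev["dyslipidemia"]).astype(int)
    df["t2d"] = (rng.uniform(size=n) < prev["t2d"]).astype(int)
    p_dx = np.asarray(prev["diagnosis"], dtype=float)
    dx = rng.choice(3, size=n, p=p_dx / p_dx.sum())
    df["dx_ua"] = (dx == 0).astype(int)
    df["dx_stemi"] = (dx == 1).astype(int)
    df["dx_nstemi"] = (dx == 2).astype(int)
    for med in ("statin", "beta_blocker", "aspirin", "diuretic"):
        key = med if med in prev else med
        df[med] = (rng.uniform(size=n) < prev[key]).astype(int)
    # glucose-lowering drugs only among diabetics, preserving the marginals
    p_t2d = prev["t2d"]
    df["oad"] = ((df["t2d"] == 1)
                 & (rng.uniform(size=n) < prev["oad"] / p_t2d)).astype(int)
    df["insulin"] = ((df["t2d"] == 1)
                     & (rng.uniform(size=n) < prev["insulin"] / p_t2d)).astype(int)
    # renal function declines with age; clip to a physiological range
    df["egfr"] = np.clip(
        130.0 - 0.78 * df["age"] + rng.normal(0, 20.0, n), 10.0, 160.0)
    return df


def _covariate_lp(df: pd.DataFrame, beta: dict) -> np.ndarray:
    design = design_columns(df)
    lp = np.zeros(len(df))
    for name, b in beta.items():
        lp += b * (design[name].to_numpy() - _COVARIATE_CENTER[name])
    return lp


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw one complete synthetic cohort (before missingness injection)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    cov_df = _draw_covariates(spec, rng)

    # latent standard-normal metabolite matrix with the prescribed correlation
    cov = np.asarray(spec.ba_log_cov, dtype=float)
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    # eigen factorization tolerates semi-definite covariances
    evals, evecs = np.linalg.eigh(corr)
    evals = np.clip(evals, 0.0, None)
    Z = rng.standard_normal((n, len(spec.ba_names))) @ (
        evecs * np.sqrt(evals)) @ evecs.T
    log_conc = np.asarray(spec.ba_log_mean) + Z * sd
    conc = np.exp(log_conc)

    lp_cov = _covariate_lp(cov_df, spec.covariate_beta)
    bm = np.asarray(spec.true_beta_mace, dtype=float)
    bd = np.asarray(spec.true_beta_death, dtype=float)
    lp_mace = Z @ bm
    lp_death = Z @ bd

    haz = spec.baseline_hazard
    if spec.composite_mode == "latent":
        t_mi = rng.exponential(1.0 / (haz["mi"] * np.exp(lp_cov + lp_mace)))
        t_hf = rng.exponential(1.0 / (haz["hf"] * np.exp(lp_cov + lp_mace)))
        t_de = rng.exponential(1.0 / (haz["death"] * np.exp(lp_cov + lp_death)))
        t_mace = np.minimum(np.minimum(t_mi, t_hf), t_de)
    else:
        # single-process composite: one clock carries the whole MACE hazard
        rate = haz["mi"] + haz["hf"] + haz["death"]
        t_mace = rng.exponential(1.0 / (rate * np.exp(lp_cov + lp_mace)))
        t_de = np.maximum(
            t_mace,
            rng.exponential(1.0 / (haz["death"] * np.exp(lp_cov + lp_death))),
        )

    horizon = spec.censor_horizon
    event_mace = (t_mace <= horizon).astype(int)
    event_death = (t_de <= horizon).astype(int)
    time_mace = np.minimum(t_mace, horizon)
    time_death = np.minimum(t_de, horizon)

    df = pd.DataFrame({"subject_id": [f"S{i:04d}" for i in range(n)]})
    df["time_mace"] = time_mace
    df["event_mace"] = event_mace
    df["time_death"] = time_death
    df["event_death"] = event_death
    for c in cov_df.columns:
        df[c] = cov_df[c]
    for j, name in enumerate(spec.ba_names):
        df[name] = conc[:, j]

    sd_mace = float(np.sqrt(bm @ corr @ bm)) if np.any(bm != 0) else 1.0
    sd_death = float(np.sqrt(bd @ corr @ bd)) if np.any(bd != 0) else 1.0
    truth = pd.DataFrame({
        "lp_covariates": lp_cov,
        "lp_mace_metab": lp_mace,
        "lp_death_metab": lp_death,
        "true_score_mace": lp_mace / sd_mace,
        "true_score_death": lp_death / sd_death,
    })
    return CohortTable(data=df, truth=truth, provenance="synthetic")


def inject_missingness(table: CohortTable, spec: CohortSpec) -> CohortTable:
    """Blank metabolite (and BMI) cells at the spec's per-column rates.

    MCAR by default; the 'mar_age' mechanism doubles the odds of missingness
    for subjects above the median age while preserving each column's mean
    rate. Original values are copied into the truth block for later
    imputation-error scoring.
    """
    spec.validate()
    for name in spec.missing_rates:
        if name not in table.data.columns:
            raise ValueError(f"missing-rate column {name!r} not in table")
        if table.data[name].isna().any():
            raise ValueError("metabolite columns must be complete before injection")
    rng = np.random.default_rng(spec.seed + 1_000_003)
    out = table.copy()
    n = len(out.data)
    if spec.missing_mechanism == "mar_age":
        older = (out.data["age"] > out.data["age"].median()).to_numpy()
        weight = np.where(older, 4 / 3, 2 / 3)
    else:
        weight = np.ones(n)
    truth = out.truth if out.truth is not None else pd.DataFrame(index=out.data.index)
    for name, rate in spec.missing_rates.items():
        truth[f"true_{name}"] = out.data[name].to_numpy().copy()
        mask = rng.uniform(size=n) < np.clip(rate * weight, 0, 1)
        col = out.data[name].to_numpy(dtype=float)
        col[mask] = np.nan
        out.data[name] = col
    truth["true_bmi"] = out.data["bmi"].to_numpy().copy()
    bmi_mask = rng.uniform(size=n) < spec.bmi_missing_rate
    bmi = out.data["bmi"].to_numpy(dtype=float)
    bmi[bmi_mask] = np.nan
    out.data["bmi"] = bmi
    out.truth = truth
    return out


def simulate_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> CohortTable:
    """Generate a cohort and inject missingness in one call."""
    spec = spec or CohortSpec()
    if seed is not None:
        spec = spec.with_(seed=seed)
    return inject_missingness(generate_cohort(spec), spec)
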