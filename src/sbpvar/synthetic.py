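"""Synthetic diabetes-cohort generator with known ground truth.

Emulates the data structure of a primary-care type-2-diabetes cohort in
which each subject contributes a short series of clinic systolic blood
pressure (SBP) readings (a first reading plus quarterly repeats over two
years, at most nine readings) followed by roughly a decade of
event/censoring follow-up.  Each subject carries a latent "usual" SBP
level ``alpha_i`` (mm Hg), a linear drift ``beta_i`` (mm Hg/year) and a
subject-specific visit-to-visit standard deviation ``sigma_i`` (mm Hg);
observed readings are ``y_ij = alpha_i + beta_i * t_ij + eps_ij`` with
``eps_ij ~ N(0, sigma_i^2)``.  Outcomes are drawn from proportional
hazards that depend log-linearly on ``sigma_i``, so the hazard ratio the
downstream survival analysis estimates is a generator parameter and
parameter recovery can be tested exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MONTHS_PER_YEAR = 12.0

#: default per-covariate log hazard ratios (centered covariates; see
#: _hazard_linear_predictor for the centering constants)
DEFAULT_HAZARD_COEFS: dict[str, float] = {
    "age": 0.05,        # per year above 65
    "male": 0.25,
    "smoking": 0.30,
    "charlson": 0.10,   # per point above 3
    "usual_sbp": 0.01,  # per mm Hg above 137
}

#: outcome labels and their share of the composite baseline hazard
DEFAULT_OUTCOME_SHARES: dict[str, float] = {"cvd": 0.56, "death": 0.44}

#: marginal moments/proportions used for baseline covariates
_COVARIATE_MOMENTS = {
    "smoking": 0.103,
    "bmi": (25.6, 4.9),
    "hba1c": (7.4, 1.4),
    "ldl_c": (3.2, 1.1),
    "charlson": (3.0, 1.3),
    "oral_antidiabetic": 0.810,
    "insulin": 0.010,
    "acei_arb": 0.305,
    "beta_blocker": 0.298,
    "ccb": 0.384,
    "diuretic": 0.138,
    "other_antihypertensive": 0.108,
    "lipid_lowering": 0.098,
}

DRUG_FLAGS = (
    "oral_antidiabetic",
    "insulin",
    "acei_arb",
    "beta_blocker",
    "ccb",
    "diuretic",
    "other_antihypertensive",
    "lipid_lowering",
)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions the analysis targets:
    usual SBP 137.1 (SD 10.7) mm Hg, usual variability 12.7 (SD 2.3)
    mm Hg, ages 45-84 (mean 63.9, SD 10.0), ~45% male, mean ~4.5
    readings per subject (minimum 4, maximum 9 at 3-month spacing), and
    ~9.7 years median follow-up under administrative censoring at 10
    years with a small staggered-entry offset.
    """

    n_subjects: int = 1000
    visit_schedule: tuple[float, ...] = (0, 3, 6, 9, 12, 15, 18, 21, 24)  # months
    retention_prob: float = 0.28
    min_readings: int = 4
    mean_usual_sbp: float = 137.1
    sd_usual_sbp: float = 10.7
    mean_usual_var: float = 12.7
    sd_usual_var: float = 2.3
    slope_mean: float = 0.0
    slope_sd: float = 2.0
    intercept_slope_corr: float = 0.0
    age_range: tuple[float, float] = (45.0, 84.0)
    age_mean: float = 63.9
    age_sd: float = 10.0
    male_fraction: float = 0.452
    log_hr_per_5mmhg_sd: float = 0.0
    #: optional age modification of the variability effect:
    #: log HR per 5 mm Hg at age a is log_hr_per_5mmhg_sd +
    #: log_hr_per_5_age_slope * (a - 65) / 10
    log_hr_per_5_age_slope: float = 0.0
    other_hazard_coefs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAZARD_COEFS)
    )
    baseline_hazard_rate: float = 0.025  # composite events per person-year
    outcome_shares: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_SHARES)
    )
    admin_censor_years: float = 10.0
    #: mean of the exponential staggered-entry offset subtracted from the
    #: administrative horizon (truncated at 3 y); 0 disables staggering
    entry_spread_years: float = 0.35
    covariate_missing_rates: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not (0.0 <= self.retention_prob <= 1.0):
            raise ValueError("retention_prob must lie in [0, 1]")
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ValueError("male_fraction must lie in [0, 1]")
        if self.sd_usual_sbp <= 0 or self.slope_sd < 0:
            raise ValueError("scale parameters must be positive")
        if self.sd_usual_var < 0 or self.mean_usual_var <= 0:
            raise ValueError("usual-variability parameters must be positive")
        if self.min_readings < 2:
            raise ValueError("min_readings must be >= 2")
        if self.min_readings > len(self.visit_schedule):
            raise ValueError("min_readings exceeds the visit schedule length")
        if not (-1.0 < self.intercept_slope_corr < 1.0):
            raise ValueError("intercept_slope_corr must lie in (-1, 1)")
        if self.admin_censor_years <= 0:
            raise ValueError("admin_censor_years must be positive")
        if self.baseline_hazard_rate <= 0:
            raise ValueError("baseline_hazard_rate must be positive")
        for name, rate in self.covariate_missing_rates.items():
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"missing rate for {name!r} outside [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["visit_schedule"] = list(self.visit_schedule)
        d["age_range"] = list(self.age_range)
        return d


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of a lognormal with given natural-scale moments."""
    if sd == 0:
        return np.log(mean), 0.0
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - 0.5 * s2, np.sqrt(s2)


def compute_egfr(creatinine_umol_l, age_years, female):
    """Estimated GFR (mL/min per 1.73 m^2) by the abbreviated MDRD formula
    recalibrated for a Chinese population.

    ``186 * (creatinine_mg_dl)^-1.154 * age^-0.203 * (0.742 if female)
    * 1.233`` with creatinine converted as mg/dL = umol/L * 0.011.
    Accepts scalars or arrays.
    """
    cr = np.asarray(creatinine_umol_l, dtype=float)
    age = np.asarray(age_years, dtype=float)
    fem = np.asarray(female, dtype=bool)
    if np.any(cr <= 0) or np.any(age <= 0):
        raise ValueError("creatinine and age must be positive")
    out = 186.0 * (cr * 0.011) ** -1.154 * age ** -0.203 * 1.233
    out = np.where(fem, out * 0.742, out)
    return float(out) if out.ndim == 0 else out


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal (bounds are mild here)."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def draw_subject_truth(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the latent per-subject truth table.

    ``(alpha_i, beta_i)`` are bivariate normal with the configured
    moments and correlation; ``sigma_i`` is lognormal parameterized by
    its natural-scale mean/SD.  Baseline covariates are drawn from
    simple parametric families calibrated to the target cohort's
    marginal moments.  Deterministic under a fixed config seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    rho = config.intercept_slope_corr
    z = rng.standard_normal((n, 2))
    alpha = config.mean_usual_sbp + config.sd_usual_sbp * z[:, 0]
    beta = config.slope_mean + config.slope_sd * (
        rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
    )
    mu_log, sd_log = _lognormal_params(config.mean_usual_var, config.sd_usual_var)
    sigma = np.exp(mu_log + sd_log * rng.standard_normal(n))

    lo, hi = config.age_range
    age = _truncated_normal(rng, config.age_mean, config.age_sd, lo, hi, n)
    male = rng.random(n) < config.male_fraction
    smoking = rng.random(n) < _COVARIATE_MOMENTS["smoking"]
    bmi = _truncated_normal(rng, *_COVARIATE_MOMENTS["bmi"], 14.0, 60.0, n)
    hba1c = _truncated_normal(rng, *_COVARIATE_MOMENTS["hba1c"], 4.0, 18.0, n)
    ldl_c = _truncated_normal(rng, *_COVARIATE_MOMENTS["ldl_c"], 0.5, 10.0, n)
    m, s = _COVARIATE_MOMENTS["charlson"]
    charlson = np.clip(np.rint(rng.normal(m, s, n)), 0, None).astype(int)
    # creatinine lognormal around ~75 umol/L; eGFR then follows MDRD
    creatinine = np.exp(rng.normal(np.log(75.0), 0.25, n))
    egfr = compute_egfr(creatinine, age, ~male)

    df = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "alpha_i": alpha,
            "beta_i": beta,
            "sigma_i": sigma,
            "age": age,
            "male": male.astype(int),
            "smoking": smoking.astype(int),
            "bmi": bmi,
            "hba1c": hba1c,
            "ldl_c": ldl_c,
            "creatinine": creatinine,
            "egfr": egfr,
            "charlson": charlson,
        }
    )
    for flag in DRUG_FLAGS:
        df[flag] = (rng.random(n) < _COVARIATE_MOMENTS[flag]).astype(int)
    # baseline (single-visit) SBP/DBP: one noisy reading around the usual level
    df["sbp"] = alpha + sigma * rng.standard_normal(n)
    df["dbp"] = rng.normal(75.3, 10.2, n)
    return df


def simulate_bp_series(truths: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Simulate the longitudinal SBP table (subject_id, t_years, sbp).

    The first scheduled visit is always observed; each later visit is
    retained i.i.d. with ``retention_prob``.  Retention patterns leaving
    a subject below ``min_readings`` are redrawn (rejection sampling),
    so every subject meets the eligibility floor while the cohort mean
    number of readings stays near its calibrated target.
    """
    if len(truths) == 0:
        raise ValueError("truths table is empty")
    if len(config.visit_schedule) == 0:
        raise ValueError("visit schedule is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    schedule = np.asarray(config.visit_schedule, dtype=float) / MONTHS_PER_YEAR
    n = len(truths)
    n_later = len(schedule) - 1

    keep = np.ones((n, len(schedule)), dtype=bool)
    if n_later:
        keep[:, 1:] = rng.random((n, n_later)) < config.retention_prob
        short = keep.sum(axis=1) < config.min_readings
        while short.any():
            k = int(short.sum())
            keep[short, 1:] = rng.random((k, n_later)) < config.retention_prob
            short = keep.sum(axis=1) < config.min_readings

    counts = keep.sum(axis=1)
    sid = np.repeat(truths["subject_id"].to_numpy(), counts)
    t = np.tile(schedule, n)[keep.ravel()]
    alpha = np.repeat(truths["alpha_i"].to_numpy(), counts)
    beta = np.repeat(truths["beta_i"].to_numpy(), counts)
    sigma = np.repeat(truths["sigma_i"].to_numpy(), counts)
    y = alpha + beta * t + sigma * rng.standard_normal(t.size)
    return pd.DataFrame({"subject_id": sid, "t_years": t, "sbp": y})


def _hazard_linear_predictor(truths: pd.DataFrame, config: GeneratorConfig) -> np.ndarray:
    sigma = truths["sigma_i"].to_numpy()
    age = truths["age"].to_numpy()
    eff5 = config.log_hr_per_5mmhg_sd + config.log_hr_per_5_age_slope * (age - 65.0) / 10.0
    lp = eff5 * (sigma - config.mean_usual_var) / 5.0
    centers = {"age": 65.0, "charlson": 3.0, "usual_sbp": 137.0, "bmi": 25.6}
    for name, coef in config.other_hazard_coefs.items():
        if not np.isfinite(coef):
            raise ValueError(f"hazard coefficient for {name!r} is not finite")
        col = "alpha_i" if name == "usual_sbp" else name
        x = truths[col].to_numpy(dtype=float) - centers.get(name, 0.0)
        lp = lp + coef * x
    return lp


def simulate_outcomes(truths: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Fill event fields: per-outcome exponential event times under
    proportional hazards, with administrative censoring.

    The composite baseline rate is split across outcome labels by
    ``outcome_shares``; outcome types are conditionally independent
    given covariates, each sharing the same log-linear predictor in
    ``sigma_i`` and the configured covariates.  Administrative censoring
    occurs at ``admin_censor_years`` minus a truncated-exponential
    staggered-entry offset.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = len(truths)
    lp = _hazard_linear_predictor(truths, config)
    hazard_scale = np.exp(lp)

    out = truths.copy()
    if config.entry_spread_years > 0:
        offset = np.minimum(rng.exponential(config.entry_spread_years, n), 3.0)
    else:
        offset = np.zeros(n)
    censor = config.admin_censor_years - offset
    out["censor_time"] = censor

    shares = config.outcome_shares
    total = sum(shares.values())
    event_times = {}
    for outcome, share in shares.items():
        lam = config.baseline_hazard_rate * (share / total) * hazard_scale
        event_times[outcome] = rng.exponential(1.0 / lam)

    death = event_times.get("death")
    for outcome, t_ev in event_times.items():
        # death censors non-fatal outcomes
        horizon = censor if (death is None or outcome == "death") else np.minimum(censor, death)
        observed = t_ev <= horizon
        out[f"time_{outcome}"] = np.where(observed, t_ev, horizon)
        out[f"event_{outcome}"] = observed.astype(int)
    ev_cols = [f"time_{o}" for o in shares]
    flag_cols = [f"event_{o}" for o in shares]
    out["time_composite"] = out[ev_cols].min(axis=1)
    out["event_composite"] = (out[flag_cols].sum(axis=1) > 0).astype(int)
    if death is not None:
        out["followup_years"] = out["time_death"]
    else:
        out["followup_years"] = censor
    return out


def inject_missing_covariates(
    table: pd.DataFrame,
    rates: dict[str, float],
    mechanism: str = "mcar",
    seed: int = 0,
) -> pd.DataFrame:
    """Delete covariate cells to emulate incomplete baseline records.

    ``mcar`` deletes each cell i.i.d. at the requested rate.  ``mar_age``
    deletes with probability depending logistically on age (older
    subjects more often missing), with the intercept solved so the
    marginal rate matches the request.
    """
    if mechanism not in {"mcar", "mar_age"}:
        raise ValueError(f"unknown missingness mechanism {mechanism!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    out = table.copy()
    n = len(table)
    for col, rate in rates.items():
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"missing rate for {col!r} outside [0, 1]")
        if rate == 0 or n == 0:
            continue
        if mechanism == "mcar":
            drop = rng.random(n) < rate
        else:
            zage = (table["age"].to_numpy() - table["age"].mean()) / max(
                table["age"].std(), 1e-9
            )
            slope = 0.8
            # solve intercept so mean deletion probability == rate
            from scipy.optimize import brentq
            from scipy.special import expit

            f = lambda b0: expit(b0 + slope * zage).mean() - rate
            b0 = brentq(f, -30.0, 30.0)
            drop = rng.random(n) < expit(b0 + slope * zage)
        out.loc[drop, col] = np.nan
    return out


def write_cohort(
    truths: pd.DataFrame,
    longitudinal: pd.DataFrame,
    outdir,
    config: GeneratorConfig | None = None,
) -> dict[str, str]:
    """Write longitudinal.csv, baseline.csv, outcomes.csv (6 sig. digits)."""
    import pathlib

    import yaml

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    fmt = "%.6g"
    long_cols = ["subject_id", "t_years", "sbp"]
    paths["longitudinal"] = str(outdir / "longitudinal.csv")
    longitudinal[long_cols].to_csv(paths["longitudinal"], index=False, float_format=fmt)

    base_cols = [
        c
        for c in truths.columns
        if not c.startswith(("time_", "event_")) and c not in ("censor_time", "followup_years")
    ]
    paths["baseline"] = str(outdir / "baseline.csv")
    truths[base_cols].to_csv(paths["baseline"], index=False, float_format=fmt)

    outcome_names = sorted(
        c[len("time_"):] for c in truths.columns if c.startswith("time_")
    )
    rows = []
    for o in outcome_names:
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": truths["subject_id"],
                    "outcome": o,
                    "time_years": truths[f"time_{o}"],
                    "event": truths[f"event_{o}"],
                }
            )
        )
    paths["outcomes"] = str(outdir / "outcomes.csv")
    pd.concat(rows).to_csv(paths["outcomes"], index=False, float_format=fmt)
    if config is not None:
        paths["config"] = str(outdir / "generator_config.yaml")
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(config.to_dict(), fh)
    return paths


def generate_cohort(
    config: GeneratorConfig, missing_mechanism: str = "mcar"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience: truths (with outcomes) and the longitudinal table.

    If ``covariate_missing_rates`` is set, baseline covariate cells are
    deleted accordingly (the latent truth columns are never masked).
    """
    truths = draw_subject_truth(config)
    longitudinal = simulate_bp_series(truths, config)
    truths = simulate_outcomes(truths, config)
    if config.covariate_missing_rates:
        truths = inject_missing_covariates(
            truths,
            config.covariate_missing_rates,
            mechanism=missing_mechanism,
            seed=config.seed,
        )
    return truths, longitudinal
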