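"""End-to-end pipeline: simulate -> filter -> variability fit -> impute ->
Lexis split -> Cox fits -> incidence -> pooled report.

The pipeline consumes either the three delimited inputs
(``longitudinal.csv``, ``baseline.csv``, ``outcomes.csv``) or a
:class:`~sbpvar.synthetic.GeneratorConfig`, and emits the study-shaped
outputs: per-subject usual SBP/variability estimates, counting-process
episodes, hazard-ratio tables (grouped with floated CIs, per-5
continuous, spline, decade-level, subgroups), an incidence table with
exact Poisson CIs, and a JSON run manifest.  All randomness flows from
one global seed.

:func:`recovery_study` packages the replicated parameter-recovery
experiment used to validate the regression-dilution correction: cohorts
are generated with a known hazard ratio per 5 mm Hg of the true
subject-level SD, and the per-5 HR is re-estimated from the model-based
(usual), naive and Rosner-corrected exposure routes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import sys
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import epi, imputation, survival, synthetic, variability

logger = logging.getLogger("sbpvar")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[sbpvar %(levelname)s] %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

#: baseline covariates entering every Cox model (age enters through the
#: attained-age bands plus a linear baseline-age term)
DEFAULT_COVARIATES = [
    "sbp",
    "dbp",
    "male",
    "smoking",
    "bmi",
    "hba1c",
    "ldl_c",
    "egfr",
    "charlson",
    *synthetic.DRUG_FLAGS,
]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    generator: synthetic.GeneratorConfig | None = None
    input_dir: str | None = None  # directory holding the three CSVs
    output_dir: str = "sbpvar_output"
    seed: int = 0
    min_readings: int = 4
    mcmc: variability.MCMCConfig | None = None
    model_spec: variability.MixedModelSpec | None = None
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    #: include baseline SBP alongside usual SBP in the adjustment set
    adjust_baseline_sbp: bool = True
    outcomes: list[str] | None = None  # default: all outcomes present
    subgroups: dict[str, str] = field(default_factory=lambda: {"sex": "male"})
    n_imputations: int = 5
    n_cycles: int = 5
    ties: str = "efron"

    def __post_init__(self) -> None:
        if self.generator is None and self.input_dir is None:
            raise ValueError("either a generator config or an input directory is required")


def _manifest_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _add_dummies(
    df: pd.DataFrame, col: str, categories, prefix: str
) -> tuple[list[str], str]:
    """Reference-coded indicator columns (first present category is the
    reference); returns the created column names and the reference label."""
    present = [c for c in categories if (df[col] == c).any()]
    cols = []
    for c in present[1:]:
        name = f"{prefix}{c}"
        df[name] = (df[col] == c).astype(float)
        cols.append(name)
    return cols, present[0]


def build_outcome_frame(
    baseline: pd.DataFrame, outcomes: pd.DataFrame, outcome: str
) -> pd.DataFrame:
    """One row per subject with follow-up time and event for ``outcome``."""
    sub = outcomes[outcomes["outcome"] == outcome]
    df = baseline.merge(
        sub[["subject_id", "time_years", "event"]], on="subject_id", how="inner"
    )
    return df.rename(columns={"time_years": "time"})


def make_episodes(subjects: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Lexis-split subjects and attach age-band indicator columns."""
    episodes = survival.lexis_split(subjects)
    band_cols, _ = _add_dummies(episodes, "age_band", survival.AGE_BANDS, "band_")
    return episodes, band_cols


def _pool_vector(fits: list[survival.CoxFit], names: list[str]):
    """Rubin's rules for a coefficient vector: pooled estimate and total
    covariance T = Wbar + (1 + 1/m) B."""
    m = len(fits)
    Q = np.vstack([f.params[names].to_numpy() for f in fits])
    W = np.mean([f.cov.loc[names, names].to_numpy() for f in fits], axis=0)
    q_bar = Q.mean(axis=0)
    if m > 1:
        dev = Q - q_bar
        B = dev.T @ dev / (m - 1)
        T = W + (1.0 + 1.0 / m) * B
    else:
        T = W
    return q_bar, T


class _PooledFit:
    """Minimal CoxFit-alike carrying pooled params/cov for downstream
    helpers (per5_continuous_hr, floated_absolute_risks)."""

    def __init__(self, params: pd.Series, cov: pd.DataFrame):
        self.params = params
        self.cov = cov


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the report bundle as a dict of
    DataFrames plus the manifest, and writes everything to
    ``config.output_dir``."""
    t_start = time.time()
    outdir = pathlib.Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_times: dict[str, float] = {}
    manifest_payload = {
        "seed": config.seed,
        "generator": config.generator.to_dict() if config.generator else None,
        "input_dir": config.input_dir,
        "min_readings": config.min_readings,
        "covariates": config.covariates,
        "n_imputations": config.n_imputations,
        "ties": config.ties,
    }
    mhash = _manifest_hash(manifest_payload)

    def _stage(name):
        logger.info("stage %s", name)
        stage_times[name] = time.time()
        return name

    def _done(name):
        stage_times[name] = round(time.time() - stage_times[name], 3)

    try:
        # ---- simulate or load -------------------------------------------
        s = _stage("simulate")
        if config.generator is not None:
            gen = dataclasses.replace(config.generator, seed=config.seed)
            truths, longitudinal = synthetic.generate_cohort(gen)
            synthetic.write_cohort(truths, longitudinal, outdir, gen)
            baseline = truths
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
            outcomes_long = pd.concat(rows, ignore_index=True)
        else:
            indir = pathlib.Path(config.input_dir)
            longitudinal = pd.read_csv(indir / "longitudinal.csv", comment="#")
            baseline = pd.read_csv(indir / "baseline.csv", comment="#")
            outcomes_long = pd.read_csv(indir / "outcomes.csv", comment="#")
        _done(s)

        # ---- filter ------------------------------------------------------
        s = _stage("filter")
        longitudinal, filter_report = variability.filter_min_records(
            longitudinal, config.min_readings
        )
        keep = set(longitudinal["subject_id"])
        baseline = baseline[baseline["subject_id"].isin(keep)].reset_index(drop=True)
        outcomes_long = outcomes_long[outcomes_long["subject_id"].isin(keep)]
        _done(s)

        # ---- variability fit --------------------------------------------
        s = _stage("variability_fit")
        mcmc = config.mcmc or variability.MCMCConfig(seed=config.seed)
        mcmc = dataclasses.replace(mcmc, seed=config.seed)
        summary = variability.fit_heteroscedastic_mixed_model(
            longitudinal, config.model_spec, mcmc
        )
        usual = summary.subjects
        usual["manifest_hash"] = mhash
        usual.to_csv(outdir / "usual.csv", index=False, float_format="%.6g")
        with open(outdir / "diagnostics.json", "w") as fh:
            json.dump(
                {
                    "rhat_ess": summary.diagnostics,
                    "hyper_mean": summary.hyper_mean,
                    "n_draws": summary.n_draws,
                    "mcmc": dataclasses.asdict(mcmc),
                    "filter": {k: v for k, v in filter_report.items() if k != "excluded_ids"},
                },
                fh,
                indent=1,
            )
        _done(s)

        # ---- assemble analysis table ------------------------------------
        merged = baseline.merge(
            usual[["subject_id", "usual_sbp", "usual_sd"]], on="subject_id"
        )
        merged["vgroup"] = survival.assign_variability_group(merged["usual_sd"])

        # ---- imputation --------------------------------------------------
        s = _stage("impute")
        covs = list(config.covariates)
        if not config.adjust_baseline_sbp and "sbp" in covs:
            covs.remove("sbp")
        covs = [c for c in covs if c in merged.columns]
        imputable = [c for c in covs if merged[c].isna().any() and c not in ("sbp", "dbp")]
        if imputable:
            comp = outcomes_long[outcomes_long["outcome"] == outcomes_long["outcome"].iloc[0]]
            aux = merged.merge(comp[["subject_id", "time_years", "event"]], on="subject_id")
            aux["log_fup"] = np.log(np.clip(aux["time_years"], 1e-6, None))
            predictors = [c for c in covs if c not in ("sbp", "dbp")] + [
                "usual_sbp",
                "usual_sd",
                "event",
                "log_fup",
            ]
            completed = imputation.mice_impute(
                aux,
                m=config.n_imputations,
                n_cycles=config.n_cycles,
                predictors=predictors,
                impute_columns=imputable,
                seed=config.seed,
            )
            tables = []
            for k, t in enumerate(completed):
                t = t.drop(columns=["time_years", "event", "log_fup"])
                t.to_csv(outdir / f"baseline_imp_{k + 1}.csv", index=False, float_format="%.6g")
                tables.append(t)
        else:
            tables = [merged]
        _done(s)

        # ---- survival analyses ------------------------------------------
        s = _stage("cox")
        outcome_names = config.outcomes or sorted(outcomes_long["outcome"].unique())
        hr_rows = []
        episodes_out = None
        for outcome in outcome_names:
            per_imp_linear, per_imp_group, group_names = [], [], None
            for t in tables:
                subjects = build_outcome_frame(t, outcomes_long, outcome)
                episodes, band_cols = make_episodes(subjects)
                grp_cols, grp_ref = _add_dummies(
                    episodes, "vgroup", survival.VARIABILITY_GROUPS, "grp_"
                )
                adj = [c for c in covs if episodes[c].std() > 0] + band_cols + ["usual_sbp"]
                fit_lin = survival.fit_cox(
                    episodes, ["usual_sd"] + adj, ties=config.ties
                )
                per_imp_linear.append(fit_lin)
                fit_grp = survival.fit_cox(episodes, grp_cols + adj, ties=config.ties)
                per_imp_group.append(fit_grp)
                group_names = grp_cols
                if episodes_out is None:
                    episodes_out = episodes.copy()

            # pooled per-5 continuous HR
            q, T = _pool_vector(per_imp_linear, ["usual_sd"] + adj)
            pooled = _PooledFit(
                pd.Series(q, index=["usual_sd"] + adj),
                pd.DataFrame(T, index=["usual_sd"] + adj, columns=["usual_sd"] + adj),
            )
            res = survival.per5_continuous_hr(pooled, "usual_sd")
            hr_rows.append(
                {
                    "outcome": outcome,
                    "analysis": "per5",
                    "term": "usual_sd_per5",
                    "hr": res["hr"],
                    "hr_lo": res["hr_lo"],
                    "hr_hi": res["hr_hi"],
                    "floated": 0,
                }
            )
            # pooled grouped HRs with floated CIs
            qg, Tg = _pool_vector(per_imp_group, group_names + adj)
            pooled_g = _PooledFit(
                pd.Series(qg, index=group_names + adj),
                pd.DataFrame(Tg, index=group_names + adj, columns=group_names + adj),
            )
            floated = survival.floated_absolute_risks(
                pooled_g, group_names, reference=grp_ref
            )
            for _, r in floated.table.iterrows():
                hr_rows.append(
                    {
                        "outcome": outcome,
                        "analysis": "group",
                        "term": str(r["group"]).replace("grp_", ""),
                        "hr": r["hr"],
                        "hr_lo": r["hr_lo"],
                        "hr_hi": r["hr_hi"],
                        "floated": 1,
                    }
                )
        hr_table = pd.DataFrame(hr_rows)
        hr_table["manifest_hash"] = mhash
        hr_table.to_csv(outdir / "hr_table.csv", index=False, float_format="%.6g")
        episodes_out["manifest_hash"] = mhash
        episodes_out.to_csv(outdir / "episodes.csv", index=False, float_format="%.6g")
        _done(s)

        # ---- subgroups (first imputation; per-5 exposure) ----------------
        s = _stage("subgroups")
        subjects = build_outcome_frame(tables[0], outcomes_long, outcome_names[0])
        episodes, band_cols = make_episodes(subjects)
        adj = [c for c in covs if episodes[c].std() > 0] + band_cols + ["usual_sbp"]
        sub_table = survival.run_subgroup_analyses(
            episodes,
            ["usual_sd"] + adj,
            config.subgroups,
            exposure="usual_sd",
            ties=config.ties,
        )
        forest = sub_table.rename(
            columns={"hr_per5": "HR", "hr_lo": "lo", "hr_hi": "hi"}
        )
        forest["manifest_hash"] = mhash
        forest.to_csv(outdir / "forest.csv", index=False, float_format="%.6g")
        if len(forest):
            plot_forest(forest, outdir / "forest.png")
        _done(s)

        # ---- incidence ---------------------------------------------------
        s = _stage("incidence")
        groups = merged.set_index("subject_id")["vgroup"]
        inc = epi.incidence_table(outcomes_long, groups)
        inc["manifest_hash"] = mhash
        inc.to_csv(outdir / "incidence_table.csv", index=False, float_format="%.6g")
        _done(s)
    except Exception as err:
        stage = next((k for k, v in stage_times.items() if not isinstance(v, float)), "?")
        logger.error("pipeline failed in stage %r: %s", stage, err)
        raise

    import scipy

    manifest = {
        "manifest_hash": mhash,
        "config": manifest_payload,
        "stage_seconds": stage_times,
        "total_seconds": round(time.time() - t_start, 3),
        "rhat": {k: v["rhat"] for k, v in summary.diagnostics.items()},
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return {
        "usual": usual,
        "hr_table": hr_table,
        "incidence": inc,
        "forest": forest,
        "episodes": episodes_out,
        "manifest": manifest,
    }


def plot_forest(forest: pd.DataFrame, path) -> None:
    """Basic forest plot of per-subgroup per-5 mm Hg hazard ratios."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [f"{r['subgroup']}: {r['level']}" for _, r in forest.iterrows()]
    y = np.arange(len(forest))[::-1]
    fig, ax = plt.subplots(figsize=(6, 1 + 0.4 * len(forest)))
    ax.errorbar(
        forest["HR"],
        y,
        xerr=[forest["HR"] - forest["lo"], forest["hi"] - forest["HR"]],
        fmt="s",
        color="k",
        ecolor="gray",
        capsize=2,
    )
    ax.axvline(1.0, color="r", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(labels)
    ax.set_xscale("log")
    ax.set_xlabel("HR per 5 mm Hg usual SBP variability (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# replicated parameter-recovery study
# ---------------------------------------------------------------------------

def _recovery_config(n_subjects: int, true_hr_per5: float, seed: int):
    return synthetic.GeneratorConfig(
        n_subjects=n_subjects,
        log_hr_per_5mmhg_sd=float(np.log(true_hr_per5)),
        seed=seed,
    )


def recovery_replicate(
    n_subjects: int,
    true_hr_per5: float,
    seed: int,
    mcmc_iterations: int = 900,
    mcmc_burn_in: int = 300,
) -> dict:
    """One replicate: generate, fit all exposure routes, estimate per-5 HRs.

    Routes: true sigma_i (oracle), model-based usual_sd, naive detrended
    SD, and the Rosner first-window estimate with its dilution-ratio
    correction.  All Cox fits share the adjustment set (usual/true SBP
    level, sex, smoking, Charlson, baseline age, attained-age bands).
    """
    cfg = _recovery_config(n_subjects, true_hr_per5, seed)
    truths, longitudinal = synthetic.generate_cohort(cfg)
    longitudinal, _ = variability.filter_min_records(longitudinal, cfg.min_readings)

    mcmc = variability.MCMCConfig(
        iterations=mcmc_iterations, burn_in=mcmc_burn_in, seed=seed
    )
    try:
        summary = variability.fit_heteroscedastic_mixed_model(longitudinal, mcmc=mcmc)
    except variability.ConvergenceError:
        # the documented remedy: extend the chains once and refit
        mcmc = variability.MCMCConfig(
            iterations=2 * mcmc_iterations, burn_in=2 * mcmc_burn_in, seed=seed
        )
        summary = variability.fit_heteroscedastic_mixed_model(longitudinal, mcmc=mcmc)
    naive = variability.naive_subject_stats(longitudinal)
    windows = variability.rosner_window_estimates(longitudinal)

    df = truths.merge(
        summary.subjects[["subject_id", "usual_sbp", "usual_sd"]], on="subject_id"
    ).merge(naive[["subject_id", "naive_sd"]], on="subject_id")
    df = df.merge(windows[["subject_id", "sd_window1"]], on="subject_id", how="left")
    df["time"] = df["time_composite"]
    df["event"] = df["event_composite"]

    adj_common = ["male", "smoking", "charlson", "age"]
    episodes, band_cols = make_episodes(df)

    def per5(exposure: str, level: str, subset=None):
        epi_df = episodes if subset is None else episodes[subset(episodes)]
        fit = survival.fit_cox(epi_df, [exposure, level] + adj_common + band_cols)
        return survival.per5_continuous_hr(fit, exposure)

    res_true = per5("sigma_i", "alpha_i")
    res_usual = per5("usual_sd", "usual_sbp")
    res_naive = per5("naive_sd", "usual_sbp")
    res_w1 = per5(
        "sd_window1", "usual_sbp", subset=lambda e: e["sd_window1"].notna()
    )
    corr = variability.rosner_dilution_ratio(
        windows["sd_window1"], windows["sd_window2"]
    )
    log_rosner = corr.correct(res_w1["log_hr"])

    truth = float(np.log(true_hr_per5))
    rmse_usual = float(np.sqrt(np.mean((df["usual_sd"] - df["sigma_i"]) ** 2)))
    rmse_naive = float(np.sqrt(np.mean((df["naive_sd"] - df["sigma_i"]) ** 2)))
    return {
        "seed": seed,
        "n_events": int(df["event"].sum()),
        "mean_readings": float(longitudinal.groupby("subject_id").size().mean()),
        "median_followup": float(truths["followup_years"].median()),
        "usual_sbp_mean": float(summary.subjects["usual_sbp"].mean()),
        "usual_sd_mean": float(summary.subjects["usual_sd"].mean()),
        "log_hr_true_exposure": res_true["log_hr"],
        "true_exposure_covered": int(
            res_true["hr_lo"] <= true_hr_per5 <= res_true["hr_hi"]
        ),
        "log_hr_usual": res_usual["log_hr"],
        "usual_covered": int(res_usual["hr_lo"] <= true_hr_per5 <= res_usual["hr_hi"]),
        "log_hr_naive": res_naive["log_hr"],
        "log_hr_rosner": log_rosner,
        "rosner_lambda": corr.dilution_ratio,
        "rmse_usual": rmse_usual,
        "rmse_naive": rmse_naive,
        "abs_err_usual": abs(res_usual["log_hr"] - truth),
        "abs_err_naive": abs(res_naive["log_hr"] - truth),
        "abs_err_rosner": abs(log_rosner - truth),
        "max_rhat": summary.max_rhat(),
    }


def recovery_study(
    n_subjects: int = 3000,
    n_replicates: int = 20,
    true_hr_per5: float = 1.30,
    seed: int = 0,
    mcmc_iterations: int = 900,
    mcmc_burn_in: int = 300,
) -> pd.DataFrame:
    """Run the replicated recovery experiment; one row per replicate."""
    child = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    rows = []
    for r in range(n_replicates):
        logger.info("recovery replicate %d/%d", r + 1, n_replicates)
        rows.append(
            recovery_replicate(
                n_subjects,
                true_hr_per5,
                int(child[r]),
                mcmc_iterations=mcmc_iterations,
                mcmc_burn_in=mcmc_burn_in,
            )
        )
    return pd.DataFrame(rows)


def rubin_coverage_study(
    n_replicates: int = 200,
    n_subjects: int = 150,
    missing_rate: float = 0.30,
    m: int = 5,
    seed: int = 0,
) -> float:
    """Pooled-CI coverage of the null on scaled-down replicates.

    Cohorts are generated with zero variability effect; BMI and LDL-C
    are deleted MCAR at ``missing_rate``, imputed ``m`` times, and the
    per-5 log HR of the composite outcome on the true subject SD is
    pooled by Rubin's rules.  Returns the fraction of replicates whose
    pooled CI covers 0.
    """
    child = np.random.SeedSequence([seed, 17]).generate_state(n_replicates) % (2**31)
    covered = 0
    adj = ["male", "smoking", "charlson", "age", "bmi"]
    for r in range(n_replicates):
        cfg = synthetic.GeneratorConfig(
            n_subjects=n_subjects,
            log_hr_per_5mmhg_sd=0.0,
            baseline_hazard_rate=0.05,
            seed=int(child[r]),
        )
        truths, _ = synthetic.generate_cohort(cfg)
        truths = synthetic.inject_missing_covariates(
            truths, {"bmi": missing_rate, "ldl_c": missing_rate}, seed=int(child[r])
        )
        truths["time"] = truths["time_composite"]
        truths["event"] = truths["event_composite"]
        completed = imputation.mice_impute(
            truths,
            m=m,
            n_cycles=5,
            predictors=["sigma_i", "age", "male", "smoking", "charlson", "bmi",
                        "ldl_c", "event"],
            impute_columns=["bmi", "ldl_c"],
            seed=int(child[r]),
        )
        ests, vars_ = [], []
        for t in completed:
            episodes, band_cols = make_episodes(t)
            fit = survival.fit_cox(episodes, ["sigma_i"] + adj + band_cols)
            res = survival.per5_continuous_hr(fit, "sigma_i")
            ests.append(res["log_hr"])
            vars_.append(res["se"] ** 2)
        pooled = imputation.rubin_pool(ests, vars_)
        covered += int(pooled.ci_low <= 0.0 <= pooled.ci_high)
    return covered / n_replicates
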