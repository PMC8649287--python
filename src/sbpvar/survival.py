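"""Cox models relating usual SBP variability to outcomes.

Follow-up is analysed in counting-process form on the time-on-study
scale, with attained-age bands (from a Lexis split of each subject's
follow-up at 5-year age boundaries) entering as time-varying
categorical covariates.  Exposure enters either as the five study
variability groups (<10, 10-11.9, 12-13.9, 14-15.9, >=16 mm Hg) with
reference-free floated confidence intervals, per 5 mm Hg as a
continuous term, or through a restricted cubic spline.  Decade-level
hazard ratios are the geometric means of the two half-decade HRs.

The partial likelihood is maximized by Newton-Raphson with either
Efron (default) or Breslow handling of ties; the covariance matrix is
the inverse observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "VARIABILITY_GROUPS",
    "AGE_BANDS",
    "HALF_DECADES",
    "assign_variability_group",
    "lexis_split",
    "CoxFit",
    "fit_cox",
    "per5_continuous_hr",
    "decade_hr_geometric",
    "FloatedRisk",
    "floated_absolute_risks",
    "rcs_basis",
    "run_subgroup_analyses",
]

VARIABILITY_GROUPS = ("<10", "10-11.9", "12-13.9", "14-15.9", ">=16")
_GROUP_EDGES = (10.0, 12.0, 14.0, 16.0)
AGE_BANDS = ("45-54", "55-64", "65-74", "75-84")
HALF_DECADES = ("45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75-79", "80-84")
_AGE_CUTS = np.arange(50.0, 84.9, 5.0)  # interior 5-year boundaries; >84 stays in top band


def assign_variability_group(usual_sd):
    """Map usual SBP variability (mm Hg) to the five study groups.

    Half-open intervals [10, 12), [12, 14), [14, 16); below 10 and >=16
    are open-ended.  Accepts scalars or arrays; input must be positive.
    """
    x = np.asarray(usual_sd, dtype=float)
    if np.any(~(x > 0)):
        raise ValueError("usual_sd must be positive")
    idx = np.searchsorted(_GROUP_EDGES, x, side="right")
    out = np.asarray(VARIABILITY_GROUPS, dtype=object)[idx]
    return out if isinstance(out, np.ndarray) else str(out)


def _band_label(age: np.ndarray) -> np.ndarray:
    i = np.clip(((age - 45.0) // 10).astype(int), 0, len(AGE_BANDS) - 1)
    return np.asarray(AGE_BANDS, dtype=object)[i]


def _half_decade_label(age: np.ndarray) -> np.ndarray:
    i = np.clip(((age - 45.0) // 5).astype(int), 0, len(HALF_DECADES) - 1)
    return np.asarray(HALF_DECADES, dtype=object)[i]


def lexis_split(
    subjects: pd.DataFrame,
    age_col: str = "age",
    time_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Split each subject's follow-up at attained-age 5-year boundaries.

    ``subjects`` holds one row per subject with baseline age, follow-up
    duration and the event flag.  Returns counting-process episodes
    (``entry``/``exit`` on the time-on-study scale, ``entry_age``/
    ``exit_age`` attained ages) labelled with the 10-year age-at-risk
    band and the 5-year half-decade band; all other columns are carried
    through.  Person-time and event counts are conserved exactly; the
    event sits in the subject's final episode.
    """
    age0 = subjects[age_col].to_numpy(dtype=float)
    fup = subjects[time_col].to_numpy(dtype=float)
    if np.any(fup < 0):
        raise ValueError("negative follow-up time")
    ev = subjects[event_col].to_numpy()

    rows_entry, rows_exit, rows_idx = [], [], []
    for i in range(len(subjects)):
        lo, hi = age0[i], age0[i] + fup[i]
        cuts = _AGE_CUTS[(_AGE_CUTS > lo) & (_AGE_CUTS < hi)]
        edges = np.concatenate(([lo], cuts, [hi]))
        rows_entry.append(edges[:-1])
        rows_exit.append(edges[1:])
        rows_idx.append(np.full(edges.size - 1, i))
    entry_age = np.concatenate(rows_entry)
    exit_age = np.concatenate(rows_exit)
    idx = np.concatenate(rows_idx)

    out = subjects.iloc[idx].reset_index(drop=True).copy()
    out["entry_age"] = entry_age
    out["exit_age"] = exit_age
    out["entry"] = entry_age - age0[idx]
    out["exit"] = exit_age - age0[idx]
    # event only in the last episode of each subject
    last = np.r_[idx[1:] != idx[:-1], True]
    out[event_col] = np.where(last, ev[idx], 0)
    out["age_band"] = _band_label(entry_age)
    out["half_decade"] = _half_decade_label(entry_age)
    return out


# ---------------------------------------------------------------------------
# Cox partial likelihood (counting process, Efron/Breslow ties)
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Result of a counting-process Cox fit."""

    params: pd.Series            # log hazard ratios
    cov: pd.DataFrame            # inverse observed information
    loglik: float
    ties: str
    n_events: int
    n_episodes: int
    gradient_norm: float
    converged: bool
    warnings: list[str] = field(default_factory=list)

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    def hr_table(self, z: float = 1.959963984540054) -> pd.DataFrame:
        se = self.se()
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": se,
                "hr": np.exp(self.params),
                "hr_lo": np.exp(self.params - z * se),
                "hr_hi": np.exp(self.params + z * se),
            }
        )


def _cox_loglik_grad_info(beta, X, entry, exit_, event, ties):
    """Log partial likelihood, gradient and observed information.

    Risk set at an event time t is {i: entry_i < t <= exit_i}.  All
    per-event sums are assembled from suffix cumulative sums over rows
    sorted by exit/entry time, so one evaluation is O(n p^2).
    """
    n, p = X.shape
    w = np.exp(X @ beta)
    xw = X * w[:, None]
    xxw = X[:, :, None] * X[:, None, :] * w[:, None, None]

    order_exit = np.argsort(exit_, kind="stable")
    order_entry = np.argsort(entry, kind="stable")
    exit_sorted = exit_[order_exit]
    entry_sorted = entry[order_entry]

    def suffix(arr, order):
        a = arr[order]
        c = np.cumsum(a[::-1], axis=0)[::-1]
        return c

    sw_exit = suffix(w, order_exit)
    sw_entry = suffix(w, order_entry)
    sxw_exit = suffix(xw, order_exit)
    sxw_entry = suffix(xw, order_entry)
    sxxw_exit = suffix(xxw, order_exit)
    sxxw_entry = suffix(xxw, order_entry)

    ev_mask = event.astype(bool)
    ev_times = exit_[ev_mask]
    uniq, inv, d_count = np.unique(ev_times, return_inverse=True, return_counts=True)
    ie = np.searchsorted(exit_sorted, uniq, side="left")
    ia = np.searchsorted(entry_sorted, uniq, side="left")

    def gather(sfx, idxs):
        """Suffix sum starting at sorted index (0 past the end)."""
        out = np.zeros((idxs.size,) + sfx.shape[1:])
        ok = idxs < n
        out[ok] = sfx[idxs[ok]]
        return out

    # risk set {entry < t <= exit} = {exit >= t} minus {entry >= t}
    S0 = gather(sw_exit, ie) - gather(sw_entry, ia)
    S1 = gather(sxw_exit, ie) - gather(sxw_entry, ia)
    S2 = gather(sxxw_exit, ie) - gather(sxxw_entry, ia)

    # tied-event sums per unique event time
    E = uniq.size
    S0d = np.zeros(E)
    S1d = np.zeros((E, p))
    S2d = np.zeros((E, p, p))
    np.add.at(S0d, inv, w[ev_mask])
    np.add.at(S1d, inv, xw[ev_mask])
    np.add.at(S2d, inv, xxw[ev_mask])
    s_sum = X[ev_mask].sum(axis=0)
    lp_events = (X[ev_mask] @ beta).sum()

    # expand one row per event with its within-tie rank l (0..d-1)
    ranks = np.concatenate([np.arange(d) for d in d_count])
    grp = np.repeat(np.arange(E), d_count)
    if ties == "breslow":
        frac = np.zeros(ranks.size)
    elif ties == "efron":
        frac = ranks / np.repeat(d_count, d_count)
    else:
        raise ValueError(f"unknown ties method {ties!r}")

    D = S0[grp] - frac * S0d[grp]
    N1 = S1[grp] - frac[:, None] * S1d[grp]
    N2 = S2[grp] - frac[:, None, None] * S2d[grp]
    mu = N1 / D[:, None]

    loglik = lp_events - np.log(D).sum()
    grad = s_sum - mu.sum(axis=0)
    info = (N2 / D[:, None, None]).sum(axis=0) - np.einsum("li,lj->ij", mu, mu)
    return loglik, grad, info


def fit_cox(
    episodes: pd.DataFrame,
    covariates: list[str],
    ties: str = "efron",
    entry_col: str = "entry",
    exit_col: str = "exit",
    event_col: str = "event",
    tol: float = 1e-9,
    max_iter: int = 50,
) -> CoxFit:
    """Fit a Cox model to counting-process episodes.

    Maximizes the partial likelihood (Efron default, Breslow optional)
    by Newton iteration with step-halving, to an infinity-norm gradient
    below ``tol``; the covariance is the inverse observed information.
    Constant covariates are rejected; monotone likelihood (separation)
    is reported through ``CoxFit.warnings``.
    """
    X = episodes[covariates].to_numpy(dtype=float)
    entry = episodes[entry_col].to_numpy(dtype=float)
    exit_ = episodes[exit_col].to_numpy(dtype=float)
    event = episodes[event_col].to_numpy(dtype=int)
    if event.sum() < 1:
        raise ValueError("at least one event is required")
    if np.any(entry >= exit_):
        raise ValueError("each episode needs entry < exit")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = [c for c, s in zip(covariates, sds) if s == 0]
        raise ValueError(f"constant covariates cannot enter the model: {bad}")

    center = X.mean(axis=0)
    Xc = X - center
    p = X.shape[1]
    beta = np.zeros(p)
    msgs: list[str] = []
    ll, grad, info = _cox_loglik_grad_info(beta, Xc, entry, exit_, event, ties)
    converged = False
    for _ in range(max_iter):
        gnorm = np.max(np.abs(grad))
        if gnorm < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
            msgs.append("singular information matrix; pseudo-inverse step used")
        # step-halving safeguard
        for _h in range(30):
            cand = beta + step
            ll_new, grad_new, info_new = _cox_loglik_grad_info(
                cand, Xc, entry, exit_, event, ties
            )
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
    gnorm = float(np.max(np.abs(grad)))
    if not converged and gnorm >= tol:
        msgs.append(f"Newton iteration stopped at gradient norm {gnorm:.2e}")
    if np.any(np.abs(beta * sds) > 20):
        msgs.append("extreme coefficient: possible monotone likelihood (separation)")
    for m in msgs:
        warnings.warn(m, stacklevel=2)
    cov = np.linalg.inv(info)
    return CoxFit(
        params=pd.Series(beta, index=covariates),
        cov=pd.DataFrame(cov, index=covariates, columns=covariates),
        loglik=float(ll),
        ties=ties,
        n_events=int(event.sum()),
        n_episodes=len(episodes),
        gradient_norm=gnorm,
        converged=converged or gnorm < tol,
        warnings=msgs,
    )


def per5_continuous_hr(fit: CoxFit, covariate: str = "usual_sd", scale: float = 5.0):
    """HR per ``scale`` mm Hg for a linear exposure term, with 95% CI."""
    if covariate not in fit.params.index:
        raise KeyError(f"{covariate!r} not in the fitted model")
    b = scale * fit.params[covariate]
    se = scale * np.sqrt(fit.cov.loc[covariate, covariate])
    z = sps.norm.ppf(0.975)
    with np.errstate(over="ignore"):  # an enormous SE gives an infinite bound
        return {
            "log_hr": float(b),
            "se": float(se),
            "hr": float(np.exp(b)),
            "hr_lo": float(np.exp(b - z * se)),
            "hr_hi": float(np.exp(b + z * se)),
        }


def decade_hr_geometric(b1: float, b2: float, v1: float, v2: float, c12: float = 0.0):
    """Decade-level HR as the geometric mean of two half-decade HRs.

    log HR = (b1 + b2) / 2; Var = (v1 + v2 + 2 c12) / 4 by the delta
    method; the HR and its 95% CI are exponentiated.
    """
    if v1 < 0 or v2 < 0:
        raise ValueError("variances must be non-negative")
    b = 0.5 * (b1 + b2)
    var = 0.25 * (v1 + v2 + 2.0 * c12)
    if var < -1e-12:
        raise ValueError("negative combined variance")
    var = max(var, 0.0)
    se = np.sqrt(var)
    z = sps.norm.ppf(0.975)
    return {
        "log_hr": float(b),
        "var": float(var),
        "hr": float(np.exp(b)),
        "hr_lo": float(np.exp(b - z * se)),
        "hr_hi": float(np.exp(b + z * se)),
    }


@dataclass
class FloatedRisk:
    """Reference-free per-group variances for exposure-category log HRs."""

    table: pd.DataFrame  # group, log_hr, floated_var, hr, hr_lo, hr_hi
    max_pair_residual: float
    mean_pair_variance: float

    @property
    def relative_residual(self) -> float:
        return self.max_pair_residual / self.mean_pair_variance


def floated_absolute_risks(
    fit: CoxFit, group_coefs: list[str], reference: str = VARIABILITY_GROUPS[0]
) -> FloatedRisk:
    """Floated (reference-free) CIs for exposure-group log HRs.

    The reference group is augmented with log HR 0; pairwise contrast
    variances Var(b_k - b_l) from the fitted covariance are decomposed
    into per-group variances v_k by non-negative least squares over all
    pairs, so every group (reference included) carries its own CI while
    pairwise contrasts keep approximately the correct variance.  The
    worst pairwise reproduction residual is reported.
    """
    if len(group_coefs) + 1 < 3:
        raise ValueError("floating absolute risk needs >= 3 groups including the reference")
    K = len(group_coefs) + 1
    b = np.concatenate(([0.0], fit.params[group_coefs].to_numpy()))
    C = np.zeros((K, K))
    C[1:, 1:] = fit.cov.loc[group_coefs, group_coefs].to_numpy()

    pairs = [(k, l) for k in range(K) for l in range(k + 1, K)]
    V = np.array([C[k, k] + C[l, l] - 2.0 * C[k, l] for k, l in pairs])
    A = np.zeros((len(pairs), K))
    for r, (k, l) in enumerate(pairs):
        A[r, k] = 1.0
        A[r, l] = 1.0
    from scipy.optimize import nnls

    v, _ = nnls(A, V)
    resid = np.abs(V - A @ v)
    z = sps.norm.ppf(0.975)
    se = np.sqrt(v)
    with np.errstate(over="ignore"):  # an enormous SE gives an infinite bound
        table = pd.DataFrame(
            {
                "group": [reference] + list(group_coefs),
                "log_hr": b,
                "floated_var": v,
                "hr": np.exp(b),
                "hr_lo": np.exp(b - z * se),
                "hr_hi": np.exp(b + z * se),
            }
        )
    return FloatedRisk(
        table=table,
        max_pair_residual=float(resid.max()),
        mean_pair_variance=float(V.mean()),
    )


def rcs_basis(x, knots=None, n_knots: int = 3, data=None) -> np.ndarray:
    """Restricted (natural) cubic spline basis columns.

    Returns ``len(knots) - 1`` columns: the linear term plus the
    truncated-power nonlinear terms, normalized by the squared span of
    the boundary knots; the function is linear beyond the boundary
    knots, so extrapolation never errors.  If ``knots`` is omitted they
    are placed at the 10th/50th/90th percentiles (for 3 knots) of
    ``data`` (or of ``x``).
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        src = np.asarray(data if data is not None else x, dtype=float)
        qs = np.linspace(0.10, 0.90, n_knots)
        knots = np.quantile(src, qs)
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or len(knots) < 3:
        raise ValueError("at least 3 knots are required")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    k = len(knots)
    t1, tk1, tk = knots[0], knots[-2], knots[-1]
    norm = (tk - t1) ** 2

    def cube(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        term = (
            cube(x - tj)
            - cube(x - tk1) * (tk - tj) / (tk - tk1)
            + cube(x - tk) * (tk1 - tj) / (tk - tk1)
        ) / norm
        cols.append(term)
    return np.column_stack(cols)


def run_subgroup_analyses(
    episodes: pd.DataFrame,
    covariates: list[str],
    subgroups: dict[str, str],
    exposure: str = "usual_sd",
    ties: str = "efron",
) -> pd.DataFrame:
    """Per-5 mm Hg exposure HRs within each level of each stratifier.

    For each subgroup variable, the Cox model is refitted within every
    stratum with the same covariate specification minus the stratifier
    (and any covariate constant within the stratum); strata without
    events are skipped with a warning.  Returns a long-format table.
    """
    rows = []
    for name, col in subgroups.items():
        for level in pd.unique(episodes[col]):
            sub = episodes[episodes[col] == level]
            if len(sub) == 0 or sub["event"].sum() == 0:
                warnings.warn(f"subgroup {name}={level!r} has no events; skipped")
                continue
            covs = [
                c
                for c in covariates
                if c != col and sub[c].std() > 0
            ]
            fit = fit_cox(sub, covs, ties=ties)
            res = per5_continuous_hr(fit, exposure)
            rows.append(
                {
                    "subgroup": name,
                    "level": level,
                    "n_events": fit.n_events,
                    "hr_per5": res["hr"],
                    "hr_lo": res["hr_lo"],
                    "hr_hi": res["hr_hi"],
                }
            )
    return pd.DataFrame(rows)
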