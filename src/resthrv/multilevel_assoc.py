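"""Within- and between-person association estimation for intensive longitudinal data.

Repeated daily observations nested in people conflate two distinct
associations: the correlation of day-level fluctuations around each person's
own mean (within-person) and the correlation of the persons' long-run means
(between-person).  The default estimator fits a bivariate two-level
random-intercept model by maximum likelihood,

    (x_ij, y_ij) = mu + b_i + w_ij,   b_i ~ N(0, S_b),  w_ij ~ N(0, S_w),

so the between-person correlation refers to the *latent* person means b_i
(free of the sampling noise that attenuates correlations of observed person
averages).  Each 2x2 covariance is parametrized as (log sd_x, log sd_y,
atanh r), which keeps it positive definite and yields Wald tests on the
Fisher-z scale.  Person-level covariates (age, gender) can enter the
between-level mean, making the reported between correlation a partial
correlation given those covariates; the within level is untouched.

A method-of-moments estimator (person-centred values for within, observed
person means for between) is available for transparency; its between-level
estimate is attenuated when persons contribute few days.

The intraclass correlation ICC = Var(BP) / (Var(BP) + Var(WP)) is estimated
by one-way random-effects REML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats, optimize
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.numdiff import approx_hess

from .synthetic_data import PanelDataset

logger = logging.getLogger("resthrv")

LAG_SPECS = ("same_day", "health_day_to_next_night", "prior_day_to_morning")

#: |r| thresholds for the small / medium / large effect-size convention.
EFFECT_THRESHOLDS = (0.10, 0.30, 0.50)


class EstimationError(ValueError):
    """Raised when an estimate is undefined for the given data."""


@dataclass
class CorrelationEstimate:
    """Within- and between-person correlations for one variable pair."""

    pair: tuple
    within_r: float = np.nan
    between_r: float = np.nan
    within_se: float = np.nan
    between_se: float = np.nan
    within_p: float = np.nan
    between_p: float = np.nan
    estimator: str = "ml_latent"
    type: str = "pearson"
    n_persons: int = 0
    n_obs: int = 0
    adjusted_for: tuple = ()
    flags: list = field(default_factory=list)


@dataclass
class VarianceDecomposition:
    """Between- and within-person variance components and their ICC."""

    var_bp: float
    var_wp: float
    icc: float
    n_persons: int = 0
    n_obs: int = 0
    variable: str = ""


# ---------------------------------------------------------------------------
# Panel preparation
# ---------------------------------------------------------------------------

def daily_average(panel: PanelDataset, variable: str) -> PanelDataset:
    """Collapse multiple same-day administrations of a variable to their mean.

    Other variables pass through untouched; days with no administrations stay
    missing.  Needed for EMA items delivered several times per day before
    they enter correlational analyses.
    """
    data = panel.data
    sub = data[data["variable"] == variable]
    rest = data[data["variable"] != variable]
    if sub.empty:
        return panel
    agg = (
        sub.groupby(["person_id", "day_index"], as_index=False)["value"]
        .mean()
    )
    agg["variable"] = variable
    agg = agg[["person_id", "day_index", "variable", "value"]]
    out = pd.concat([rest, agg], ignore_index=True)
    return PanelDataset(data=out, persons=panel.persons, flags=list(panel.flags))


def align_lag(panel: PanelDataset, pair: tuple, lag_spec: str = "same_day"
              ) -> pd.DataFrame:
    """Join a (HRV, health) variable pair into paired observations.

    ``pair`` is ``(hrv_variable, health_variable)``.  Under
    ``health_day_to_next_night`` (and equivalently ``prior_day_to_morning``)
    the health measure reported on day *t* is paired with the HRV recorded
    the following night / morning, i.e. HRV with day index *t + 1*.
    Unmatched days are dropped and the count logged.
    """
    if lag_spec not in LAG_SPECS:
        raise EstimationError(
            f"unknown lag spec {lag_spec!r}; expected one of {LAG_SPECS}"
        )
    hrv_var, health_var = pair
    data = panel.data
    hrv = data[data["variable"] == hrv_var][["person_id", "day_index", "value"]]
    health = data[data["variable"] == health_var][
        ["person_id", "day_index", "value"]]
    hrv = hrv.rename(columns={"value": hrv_var})
    health = health.rename(columns={"value": health_var})
    if lag_spec != "same_day":
        hrv = hrv.assign(day_index=hrv["day_index"] - 1)
    merged = health.merge(hrv, on=["person_id", "day_index"], how="inner")
    n_dropped = len(health) + len(hrv) - 2 * len(merged)
    if n_dropped:
        logger.info("align_lag(%s, %s): %d unmatched observations dropped",
                    pair, lag_spec, n_dropped)
    return merged.dropna(subset=[hrv_var, health_var])


# ---------------------------------------------------------------------------
# Bivariate two-level maximum-likelihood core
# ---------------------------------------------------------------------------

def _cov2(log_sx: float, log_sy: float, z: float) -> np.ndarray:
    sx, sy, r = np.exp(log_sx), np.exp(log_sy), np.tanh(z)
    return np.array([[sx * sx, r * sx * sy], [r * sx * sy, sy * sy]])


def _inv2(m: np.ndarray):
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    inv = np.array([[m[1, 1], -m[0, 1]], [-m[1, 0], m[0, 0]]]) / det
    return inv, det


class _BivariateML:
    """Profile negative log-likelihood of the bivariate random-intercept model.

    The between-level mean (intercept plus optional person-level covariates)
    is profiled out by GLS at every evaluation, leaving six covariance
    parameters: (log sd, log sd, atanh r) for the within and the between
    level.  Sufficient statistics — person means, the pooled within-person
    scatter, and person groups by cluster size — are precomputed, so one
    evaluation is O(#distinct cluster sizes).
    """

    def __init__(self, person_codes, x, y, C):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        codes = np.asarray(person_codes)
        m = codes.max() + 1
        n_i = np.bincount(codes, minlength=m)
        xbar = np.bincount(codes, weights=x, minlength=m) / n_i
        ybar = np.bincount(codes, weights=y, minlength=m) / n_i
        dx, dy = x - xbar[codes], y - ybar[codes]
        self.S = np.array([
            [np.dot(dx, dx), np.dot(dx, dy)],
            [np.dot(dx, dy), np.dot(dy, dy)],
        ])
        self.N, self.m = x.size, int(m)
        self.C = np.asarray(C, float)
        self.p = self.C.shape[1]
        self.groups = []
        for n in np.unique(n_i):
            sel = n_i == n
            self.groups.append((
                int(n), int(sel.sum()),
                np.column_stack([xbar[sel], ybar[sel]]),
                self.C[sel],
            ))

    def nll(self, theta: np.ndarray) -> float:
        Sw = _cov2(*theta[:3])
        Sb = _cov2(*theta[3:])
        iSw, detSw = _inv2(Sw)
        val = (self.N - self.m) * np.log(detSw) + np.trace(iSw @ self.S)
        twop = 2 * self.p
        A = np.zeros((twop, twop))
        rhs = np.zeros(twop)
        cache = []
        for n, g, Yg, Cg in self.groups:
            V = Sb + Sw / n
            iV, detV = _inv2(V)
            if detV <= 0:
                return 1e12
            val += g * np.log(detV)
            A += np.kron(Cg.T @ Cg, iV)
            rhs += (Cg.T @ (Yg @ iV)).reshape(twop)
            cache.append((iV, Yg, Cg))
        try:
            beta = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            return 1e12
        B = beta.reshape(self.p, 2)
        for (iV, Yg, Cg) in cache:
            R = Yg - Cg @ B
            val += float(np.sum((R @ iV) * R))
        return 0.5 * val

    def start(self) -> np.ndarray:
        Sw0 = self.S / max(self.N - self.m, 1)
        ybars = np.vstack([g[2] for g in self.groups])
        Cs = np.vstack([g[3] for g in self.groups])
        resid = ybars - Cs @ np.linalg.lstsq(Cs, ybars, rcond=None)[0]
        inv_n = np.concatenate([[1.0 / g[0]] * g[1] for g in self.groups])
        Sb0 = np.cov(resid.T) - Sw0 * inv_n.mean()

        def pack(S):
            vx = max(S[0, 0], 1e-4)
            vy = max(S[1, 1], 1e-4)
            r = np.clip(S[0, 1] / np.sqrt(vx * vy), -0.9, 0.9)
            return [0.5 * np.log(vx), 0.5 * np.log(vy), np.arctanh(r)]

        if Sw0[0, 0] <= 0 or Sw0[1, 1] <= 0:
            Sw0 = np.eye(2) * 0.5
        return np.array(pack(Sw0) + pack(np.atleast_2d(Sb0)))


def _fit_bivariate(person_codes, x, y, C):
    """Fit the bivariate model; returns a dict of estimates on the z-scale."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise EstimationError("a variable is constant; correlations undefined")
    model = _BivariateML(person_codes, x / sx, y / sy, C)
    bounds = [(-6.0, 3.0), (-6.0, 3.0), (-7.5, 7.5)] * 2
    res = optimize.minimize(
        model.nll, model.start(), method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 200, "ftol": 1e-11},
    )
    theta = res.x
    try:
        H = approx_hess(theta, model.nll)
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(6, np.nan)
    at_bound = np.array([
        np.isclose(theta[i], b, atol=1e-6)
        for i, bb in enumerate(bounds) for b in bb
    ]).reshape(6, 2).any(axis=1)
    out = {
        "z_within": theta[2], "z_between": theta[5],
        "se_z_within": se[2], "se_z_between": se[5],
        "var_w": (np.exp(2 * theta[0]) * sx ** 2,
                  np.exp(2 * theta[1]) * sy ** 2),
        "var_b": (np.exp(2 * theta[3]) * sx ** 2,
                  np.exp(2 * theta[4]) * sy ** 2),
        "converged": bool(res.success),
        "boundary": bool(at_bound[[0, 1, 3, 4]].any()),
    }
    return out


# ---------------------------------------------------------------------------
# Public estimators
# ---------------------------------------------------------------------------

def _covariate_design(persons: pd.DataFrame, person_ids, covariates):
    """Intercept + standardized covariate columns for the between-level mean."""
    idx = persons.set_index("person_id").loc[list(person_ids)]
    cols = [np.ones(len(idx))]
    used = []
    for name in covariates:
        v = idx[name].to_numpy(dtype=float)
        if np.nanstd(v) == 0:
            logger.warning("covariate %r is constant; dropped from adjustment",
                           name)
            continue
        cols.append((v - np.nanmean(v)) / np.nanstd(v))
        used.append(name)
    return np.column_stack(cols), tuple(used)


def multilevel_corr(panel: PanelDataset, pair: tuple, covariates=(),
                    estimator: str = "ml_latent",
                    lag_spec: str = "same_day") -> CorrelationEstimate:
    """Estimate the within- and between-person correlation of a variable pair.

    ``covariates`` names person-level columns (e.g. ``("age", "gender")``)
    used to adjust the between-level estimate; the within level is never
    adjusted.  ``estimator`` is ``"ml_latent"`` (default) or
    ``"moments_observed"``.
    """
    for name in pair:
        if name in panel.persons.columns and name not in ("age", "gender"):
            vals = panel.persons[name].dropna().unique()
            if set(vals) <= {0, 1}:
                raise EstimationError(
                    f"{name!r} is a person-level binary; use biserial_corr"
                )
    paired = align_lag(panel, pair, lag_spec)
    if paired.empty:
        raise EstimationError("no paired observations")
    xvar, yvar = pair
    codes, uniques = pd.factorize(paired["person_id"])
    x = paired[xvar].to_numpy(float)
    y = paired[yvar].to_numpy(float)
    m = len(uniques)
    counts = np.bincount(codes)
    est = CorrelationEstimate(pair=pair, estimator=estimator,
                              n_persons=m, n_obs=x.size)
    if m < 2 or (counts >= 2).sum() < 2:
        raise EstimationError(
            "need >= 2 persons with >= 2 paired observations for within_r"
        )
    C, used = _covariate_design(panel.persons, uniques, covariates)
    est.adjusted_for = used

    if estimator == "ml_latent":
        fit = _fit_bivariate(codes, x, y, C)
        est.within_r = float(np.tanh(fit["z_within"]))
        est.between_r = float(np.tanh(fit["z_between"]))
        est.within_se = float((1 - est.within_r ** 2) * fit["se_z_within"])
        est.between_se = float((1 - est.between_r ** 2) * fit["se_z_between"])
        # Wald test on the correlation itself with its delta-method SE;
        # t reference with cluster-based df
        df_w = x.size - m - 1
        df_b = m - 1 - (C.shape[1] - 1)
        est.within_p = _wald_p(est.within_r, est.within_se, df_w)
        est.between_p = _wald_p(est.between_r, est.between_se, df_b)
        if not fit["converged"]:
            est.flags.append("non_convergence")
        if fit["boundary"]:
            est.flags.append("variance_at_boundary")
        if min(fit["var_w"]) < 1e-8:
            est.flags.append("zero_within_variance")
            est.within_r = np.nan
    elif estimator == "moments_observed":
        _moments_fit(est, codes, x, y, C, counts)
        est.flags.append("between_attenuated_small_clusters")
    else:
        raise EstimationError(f"unknown estimator {estimator!r}")
    if m < 3:
        est.between_r = np.nan
        est.flags.append("too_few_persons_for_between")
    return est


def _wald_p(estimate: float, se: float, df: float = np.inf) -> float:
    """Two-sided Wald p-value with a t reference on ``df`` degrees of freedom.

    Cluster-based df (persons minus estimated between-level means for the
    between level, observations minus persons for the within level) give the
    standard finite-sample correction for multilevel Wald tests; ``df=inf``
    reduces to the normal reference.
    """
    if not np.isfinite(se) or se <= 0:
        return np.nan
    t = abs(estimate) / se
    if np.isinf(df):
        return float(2.0 * stats.norm.sf(t))
    return float(2.0 * stats.t.sf(t, max(df, 1.0)))


def _moments_fit(est, codes, x, y, C, counts):
    """Person-centred / person-mean method-of-moments correlations."""
    m = counts.size
    xbar = np.bincount(codes, weights=x) / counts
    ybar = np.bincount(codes, weights=y) / counts
    multi = counts[codes] >= 2
    dx = (x - xbar[codes])[multi]
    dy = (y - ybar[codes])[multi]
    if dx.std() > 0 and dy.std() > 0:
        r_w = float(np.corrcoef(dx, dy)[0, 1])
        df_w = max(int(multi.sum()) - int((counts >= 2).sum()) - 1, 2)
        se_w = (1 - r_w ** 2) / np.sqrt(df_w)
        est.within_r, est.within_se = r_w, se_w
        est.within_p = _wald_p(r_w, se_w, df_w)
    else:
        est.flags.append("zero_within_variance")
    rx = xbar - C @ np.linalg.lstsq(C, xbar, rcond=None)[0]
    ry = ybar - C @ np.linalg.lstsq(C, ybar, rcond=None)[0]
    if rx.std() > 0 and ry.std() > 0:
        r_b = float(np.corrcoef(rx, ry)[0, 1])
        df_b = max(m - 3 - (C.shape[1] - 1), 2)
        se_b = (1 - r_b ** 2) / np.sqrt(df_b)
        est.between_r, est.between_se = r_b, se_b
        est.between_p = _wald_p(r_b, se_b, df_b)


def adjust_between(values: pd.Series, persons: pd.DataFrame,
                   covariates=("age", "gender")) -> pd.Series:
    """Residualize person-level values on covariates (OLS).

    ``values`` is indexed by person_id.  Persons with missing covariates are
    dropped listwise (logged).  Constant covariates are dropped with a
    warning.  The residuals feed a between-level partial correlation.
    """
    idx = persons.set_index("person_id").reindex(values.index)
    mask = values.notna()
    for name in covariates:
        mask &= idx[name].notna()
    n_drop = int((~mask).sum())
    if n_drop:
        logger.info("adjust_between: %d person(s) dropped listwise", n_drop)
    v = values[mask]
    C, _ = _covariate_design(persons, v.index, covariates)
    resid = v.to_numpy(float) - C @ np.linalg.lstsq(
        C, v.to_numpy(float), rcond=None)[0]
    return pd.Series(resid, index=v.index, name=values.name)


def variance_components(panel: PanelDataset, variable: str
                        ) -> VarianceDecomposition:
    """One-way random-effects decomposition of a variable by REML.

    Returns Var(BP), Var(WP) and ICC = Var(BP) / (Var(BP) + Var(WP)).
    Negative component estimates are truncated at zero.
    """
    sub = panel.data[panel.data["variable"] == variable].dropna(subset=["value"])
    if sub.empty:
        raise EstimationError(f"variable {variable!r} not present in the panel")
    counts = sub.groupby("person_id").size()
    if len(counts) < 2:
        raise EstimationError("need >= 2 persons")
    if (counts < 2).all():
        raise EstimationError(
            "within-person variance inestimable: all persons have a single "
            "observation"
        )
    y = sub["value"].to_numpy(float)
    groups = sub["person_id"].to_numpy()
    model = MixedLM(y, np.ones((y.size, 1)), groups=groups)
    fit = None
    for method in ("lbfgs", "bfgs", "powell"):
        try:
            with np.errstate(all="ignore"):
                fit = model.fit(reml=True, method=method)
            break
        except np.linalg.LinAlgError:
            continue
    if fit is None:
        raise EstimationError("REML variance decomposition failed to converge")
    var_bp = max(float(np.asarray(fit.cov_re)[0, 0]), 0.0)
    var_wp = max(float(fit.scale), 0.0)
    denom = var_bp + var_wp
    icc = var_bp / denom if denom > 0 else np.nan
    return VarianceDecomposition(var_bp=var_bp, var_wp=var_wp, icc=icc,
                                 n_persons=int(len(counts)),
                                 n_obs=int(y.size), variable=variable)


def biserial_corr(continuous, binary) -> CorrelationEstimate:
    """Biserial correlation of a continuous variable with a dichotomized one.

    Estimates the latent-normal correlation as
    ``r_b = (M1 - M0) / s_y * p (1 - p) / phi(Phi^-1(p))`` with ``M1, M0``
    the class means, ``s_y`` the overall standard deviation, and ``p`` the
    proportion of ones.  Small-sample estimates outside [-1, 1] are clipped
    and flagged.  The p-value uses the approximate null standard error
    ``sqrt(p q) / phi / sqrt(n - 1)``.
    """
    y = np.asarray(continuous, float)
    g = np.asarray(binary, float)
    ok = np.isfinite(y) & np.isfinite(g)
    y, g = y[ok], g[ok]
    if set(np.unique(g)) != {0.0, 1.0}:
        raise EstimationError("degenerate dichotomy: need both classes present")
    n = y.size
    p = g.mean()
    phi = stats.norm.pdf(stats.norm.ppf(p))
    s_y = y.std(ddof=1)
    if s_y == 0:
        raise EstimationError("continuous variable is constant")
    r_b = (y[g == 1].mean() - y[g == 0].mean()) / s_y * p * (1 - p) / phi
    est = CorrelationEstimate(pair=("continuous", "binary"), type="biserial",
                              estimator="moments_observed",
                              n_persons=n, n_obs=n)
    if abs(r_b) > 1:
        est.flags.append("clipped")
        r_b = float(np.clip(r_b, -1.0, 1.0))
    se = np.sqrt(p * (1 - p)) / phi / np.sqrt(max(n - 1, 1))
    est.between_r = float(r_b)
    est.between_se = float(se)
    est.between_p = float(2.0 * stats.norm.sf(abs(r_b) / se)) if se > 0 else np.nan
    return est


def label_effect(r: float) -> str:
    """Effect-size label for |r|: small 0.10, medium 0.30, large 0.50."""
    if not np.isfinite(r) or abs(r) > 1:
        raise EstimationError(f"correlation {r!r} outside [-1, 1]")
    a = abs(r)
    small, medium, large = EFFECT_THRESHOLDS
    if a >= large:
        return "large"
    if a >= medium:
        return "medium"
    if a >= small:
        return "small"
    return "below_small"


def correlation_report(estimates: list[CorrelationEstimate]) -> pd.DataFrame:
    """Tidy long table with one row per estimate per level."""
    rows = []
    for e in estimates:
        for level, r, se, pval in (
            ("within", e.within_r, e.within_se, e.within_p),
            ("between", e.between_r, e.between_se, e.between_p),
        ):
            if e.type == "biserial" and level == "within":
                continue
            rows.append({
                "variable_x": e.pair[0], "variable_y": e.pair[1],
                "level": level, "r": r, "se": se, "p": pval,
                "type": e.type, "estimator": e.estimator,
                "n_persons": e.n_persons, "n_obs": e.n_obs,
                "adjusted_for": "+".join(e.adjusted_for) if level == "between"
                                else "",
                "effect": label_effect(r) if np.isfinite(r) else "",
                "flags": ";".join(e.flags),
            })
    cols = ["variable_x", "variable_y", "level", "r", "se", "p", "type",
            "estimator", "n_persons", "n_obs", "adjusted_for", "effect",
            "flags"]
    return pd.DataFrame(rows, columns=cols)
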