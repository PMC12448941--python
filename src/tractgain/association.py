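"""Structure-function association: filtering, collinearity screen, mixed model.

The statistical chain applied to the joined per-pathway table:

1. Per-subject outlier removal — keep rows whose outcome features lie
   within ``mean ± 3 SD`` (single pass), and drop rows whose peak-gain
   frequency falls below 1.5 Hz, where the 1 Hz high-pass distorts the
   spectrum.
2. Collinearity screen via variance inflation factors.  FA and axial
   diffusivity are strongly positively correlated (Ad = λ1 enters the FA
   formula), so the replication policy drops Ad and keeps FA.
3. A linear mixed-effects model per outcome (PF ratio, maximum gain) with
   fixed effects FA, N, L and a random intercept per subject, fitted by
   REML; coefficient t-tests use Satterthwaite degrees of freedom and
   p-values are Bonferroni-adjusted.

The mixed model is solved by profiling the REML likelihood over the single
variance ratio θ = σ_b²/σ_ε² — for the random-intercept model every other
quantity (GLS coefficients, residual variance, block inverses) has a closed
form, which makes the fit fast and numerically robust.  Satterthwaite df
are computed exactly from the expected REML information of (σ_b², σ_ε²).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ConfigurationError, DataError

__all__ = [
    "filter_observations",
    "compute_vif",
    "drop_collinear",
    "RandomInterceptLME",
    "LMEResult",
    "fit_lme",
    "bonferroni_adjust",
    "report",
]

DEFAULT_OUTCOMES = ("pf_ratio", "peak_gain")
DEFAULT_PREDICTORS = ("fa", "n_per_area", "length")


# ---------------------------------------------------------------------------
# observation filters

def filter_observations(
    rows: pd.DataFrame,
    sd_mult: float = 3.0,
    min_peak_freq: float = 1.5,
    features: tuple[str, ...] = DEFAULT_OUTCOMES,
    subject_col: str = "subject",
    peak_freq_col: str = "omega_p",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass per-subject outlier and low-peak-frequency exclusion.

    Per subject, the mean and SD of each outcome feature are computed once
    on the incoming table; rows deviating by more than ``sd_mult`` SD in any
    feature are removed, as are rows whose peak-gain frequency is below
    ``min_peak_freq`` Hz.  Returns the filtered table and an audit log with
    one row per removal (index, subject, reason, value).
    """
    if rows.empty:
        warnings.warn("filter_observations received an empty table")
        return rows.copy(), pd.DataFrame(columns=["index", "subject", "reason", "value"])

    drop = pd.Series(False, index=rows.index)
    audit: list[dict] = []

    if peak_freq_col in rows.columns:
        low = rows[peak_freq_col] < min_peak_freq
        for idx in rows.index[low]:
            audit.append({
                "index": idx, "subject": rows.at[idx, subject_col],
                "reason": "low_peak_freq", "value": float(rows.at[idx, peak_freq_col]),
            })
        drop |= low

    for feat in features:
        if feat not in rows.columns:
            continue
        grp = rows.groupby(subject_col)[feat]
        mean = grp.transform("mean")
        sd = grp.transform("std").fillna(0.0)
        out = (rows[feat] - mean).abs() > sd_mult * sd
        for idx in rows.index[out & ~drop]:
            audit.append({
                "index": idx, "subject": rows.at[idx, subject_col],
                "reason": f"outlier:{feat}", "value": float(rows.at[idx, feat]),
            })
        drop |= out

    audit_df = pd.DataFrame(audit, columns=["index", "subject", "reason", "value"])
    return rows.loc[~drop].copy(), audit_df


# ---------------------------------------------------------------------------
# collinearity

def compute_vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor of each predictor.

    VIF_j = 1 / (1 − R²_j) from regressing predictor j on the remaining
    predictors plus an intercept.  A perfectly collinear predictor reports
    ``inf`` rather than raising.
    """
    cols = list(design.columns)
    if len(cols) < 2:
        raise ConfigurationError("VIF needs at least 2 predictors")
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise DataError(f"need more rows ({n}) than predictors ({p}) for VIF")
    vifs = {}
    for j, col in enumerate(cols):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        tss = float(np.sum((yj - yj.mean()) ** 2))
        rss = float(resid @ resid)
        if tss == 0:
            vifs[col] = np.inf  # constant column: undefined, flag as collinear
            continue
        r2 = 1.0 - rss / tss
        vifs[col] = np.inf if 1.0 - r2 < 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(vifs, name="vif")


def drop_collinear(
    design: pd.DataFrame,
    vifs: pd.Series | None = None,
    threshold: float = 5.0,
    policy: str = "replication",
) -> tuple[pd.DataFrame, list[str]]:
    """Remove collinear predictors until all VIFs fall below ``threshold``.

    ``policy="replication"`` mirrors the analysis chain this package
    implements: when FA and Ad are jointly flagged, Ad is dropped and FA
    retained (their collinearity is
    structural — λ1 enters the FA formula).  The generic policy iteratively
    drops the predictor with the largest VIF.
    """
    if policy not in ("replication", "generic"):
        raise ConfigurationError(f"unknown policy {policy!r}")
    reduced = design.copy()
    dropped: list[str] = []
    if vifs is None:
        vifs = compute_vif(reduced)

    if policy == "replication" and {"fa", "ad"} <= set(reduced.columns):
        if vifs.get("fa", 0) > threshold or vifs.get("ad", 0) > threshold:
            reduced = reduced.drop(columns=["ad"])
            dropped.append("ad")
            if reduced.shape[1] < 2:
                return reduced, dropped
            vifs = compute_vif(reduced)

    while float(vifs.max()) > threshold and reduced.shape[1] > 2:
        worst = str(vifs.idxmax())
        reduced = reduced.drop(columns=[worst])
        dropped.append(worst)
        vifs = compute_vif(reduced)
    if float(vifs.max()) > threshold and reduced.shape[1] == 2:
        worst = str(vifs.idxmax())
        reduced = reduced.drop(columns=[worst])
        dropped.append(worst)
    return reduced, dropped


# ---------------------------------------------------------------------------
# random-intercept linear mixed model

class RandomInterceptLME(BaseEstimator, RegressorMixin):
    """REML linear mixed model with one random intercept per group.

    Parameters
    ----------
    df_method : {"satterthwaite", "residual"}
        Degrees of freedom for coefficient t-tests.  ``satterthwaite``
        computes the exact Satterthwaite approximation from the expected
        REML information; ``residual`` uses n − p.
    alpha : float
        Two-sided confidence level is ``1 − alpha``.

    Fitted attributes (sklearn convention, trailing underscore):
    ``coef_``, ``intercept_``, ``params_``, ``bse_``, ``tvalues_``,
    ``df_``, ``pvalues_``, ``conf_int_``, ``sigma_b2_``, ``sigma_e2_``,
    ``random_effects_``, ``marginal_r2_``, ``boundary_``.
    """

    def __init__(self, df_method: str = "satterthwaite", alpha: float = 0.05):
        self.df_method = df_method
        self.alpha = alpha

    # -- core REML machinery -------------------------------------------------

    @staticmethod
    def _profile(theta: float, Xg, yg):
        """Profiled REML pieces at variance ratio theta = sigma_b2/sigma_e2."""
        p = Xg[0].shape[1]
        n = sum(len(y) for y in yg)
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        logdetV = 0.0
        for Xi, yi in zip(Xg, yg):
            ni = len(yi)
            c = theta / (1.0 + ni * theta)
            sx = Xi.sum(axis=0)
            XtVX += Xi.T @ Xi - c * np.outer(sx, sx)
            XtVy += Xi.T @ yi - c * sx * yi.sum()
            logdetV += np.log1p(ni * theta)
        beta = np.linalg.solve(XtVX, XtVy)
        Q = 0.0
        for Xi, yi in zip(Xg, yg):
            ni = len(yi)
            c = theta / (1.0 + ni * theta)
            ri = yi - Xi @ beta
            Q += ri @ ri - c * ri.sum() ** 2
        sigma_e2 = Q / (n - p)
        _, logdetXtVX = np.linalg.slogdet(XtVX)
        loglik = -0.5 * ((n - p) * np.log(sigma_e2) + logdetV + logdetXtVX)
        return loglik, beta, sigma_e2, XtVX

    def _satterthwaite(self, Xg, sigma_b2, sigma_e2, Cn):
        """Satterthwaite df per coefficient from the expected REML information.

        With V_i = σ_e² I + σ_b² J the information of θ = (σ_b², σ_e²) is
        I_jk = ½ tr(P V_j P V_k); the df of coefficient contrast c is
        2 (c'Cc)² / (g' I⁻¹ g) with g_j = c'C (X'V⁻¹V_jV⁻¹X) C c.
        """
        p = Xg[0].shape[1]
        M = [np.zeros((p, p)), np.zeros((p, p))]
        T1 = np.zeros((2, 2))
        T2 = [[np.zeros((p, p)) for _ in range(2)] for _ in range(2)]
        for Xi in Xg:
            ni = Xi.shape[0]
            Vi = sigma_e2 * np.eye(ni) + sigma_b2 * np.ones((ni, ni))
            Di = np.linalg.inv(Vi)
            Ui = Di @ Xi
            B = [np.ones((ni, ni)), np.eye(ni)]
            for j in range(2):
                M[j] += Ui.T @ B[j] @ Ui
                for k in range(2):
                    T1[j, k] += np.trace(Di @ B[j] @ Di @ B[k])
                    T2[j][k] += Ui.T @ B[k] @ Di @ B[j] @ Ui
        info = np.zeros((2, 2))
        for j in range(2):
            for k in range(2):
                info[j, k] = 0.5 * (
                    T1[j, k]
                    - 2.0 * np.trace(Cn @ T2[j][k])
                    + np.trace(Cn @ M[j] @ Cn @ M[k])
                )
        A = np.linalg.pinv(info)
        dfs = np.empty(p)
        for i in range(p):
            c = np.zeros(p)
            c[i] = 1.0
            f = c @ Cn @ c
            g = np.array([c @ Cn @ M[j] @ Cn @ c for j in range(2)])
            denom = float(g @ A @ g)
            dfs[i] = 2.0 * f**2 / denom if denom > 0 else np.inf
        return dfs

    # -- sklearn API ----------------------------------------------------------

    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise DataError("X must be 2-D with one row per observation")
        if groups is None:
            raise ConfigurationError("groups (subject identifiers) are required")
        codes, uniq = pd.factorize(np.asarray(groups))
        n, k = X.shape
        Xd = np.column_stack([np.ones(n), X])
        p = k + 1
        if n <= p:
            raise DataError("more coefficients than observations")

        self.n_obs_ = n
        self.n_groups_ = len(uniq)
        self.groups_ = list(uniq)

        if self.n_groups_ == 1:
            warnings.warn("single group: falling back to ordinary least squares")
            return self._fit_ols(Xd, y, codes, uniq)

        Xg = [Xd[codes == g] for g in range(len(uniq))]
        yg = [y[codes == g] for g in range(len(uniq))]

        neg = lambda lt: -self._profile(np.exp(lt), Xg, yg)[0]
        res = optimize.minimize_scalar(neg, bounds=(-14.0, 14.0), method="bounded",
                                       options={"xatol": 1e-10})
        theta = float(np.exp(res.x))
        ll_hat = -res.fun
        ll_zero = self._profile(0.0, Xg, yg)[0]
        boundary = ll_zero >= ll_hat - 1e-10
        if boundary:
            theta = 0.0
            warnings.warn("random-intercept variance estimated at the zero boundary")
        loglik, beta, sigma_e2, XtVX = self._profile(theta, Xg, yg)

        sigma_b2 = theta * sigma_e2
        Cn = np.linalg.inv(XtVX) * sigma_e2  # cov(beta) on the data scale

        self.theta_ = theta
        self.boundary_ = bool(boundary)
        self.sigma_b2_ = float(sigma_b2)
        self.sigma_e2_ = float(sigma_e2)
        self.params_ = beta
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.cov_params_ = Cn
        self.bse_ = np.sqrt(np.diag(Cn))
        self.loglik_ = float(loglik)

        if self.df_method == "satterthwaite":
            self.df_ = self._satterthwaite(Xg, sigma_b2, sigma_e2, Cn)
        elif self.df_method == "residual":
            self.df_ = np.full(p, float(n - p))
        else:
            raise ConfigurationError(f"unknown df_method {self.df_method!r}")

        self._finish_inference(Xd, y)
        # BLUPs of the subject intercepts
        self.random_effects_ = {}
        for g, name in enumerate(uniq):
            ri = yg[g] - Xg[g] @ beta
            ni = len(ri)
            self.random_effects_[name] = float(
                sigma_b2 * ri.sum() / (sigma_e2 + ni * sigma_b2)
            ) if sigma_b2 > 0 else 0.0
        return self

    def _fit_ols(self, Xd, y, codes, uniq):
        n, p = Xd.shape
        beta, _, _, _ = np.linalg.lstsq(Xd, y, rcond=None)
        resid = y - Xd @ beta
        sigma_e2 = float(resid @ resid / (n - p))
        Cn = sigma_e2 * np.linalg.inv(Xd.T @ Xd)
        self.theta_ = 0.0
        self.boundary_ = True
        self.sigma_b2_ = 0.0
        self.sigma_e2_ = sigma_e2
        self.params_ = beta
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.cov_params_ = Cn
        self.bse_ = np.sqrt(np.diag(Cn))
        self.df_ = np.full(p, float(n - p))
        self.loglik_ = float("nan")
        self._finish_inference(Xd, y)
        self.random_effects_ = {name: 0.0 for name in uniq}
        return self

    def _finish_inference(self, Xd, y):
        self.tvalues_ = self.params_ / self.bse_
        self.pvalues_ = 2.0 * stats.t.sf(np.abs(self.tvalues_), self.df_)
        tcrit = stats.t.ppf(1.0 - self.alpha / 2.0, self.df_)
        self.conf_int_ = np.column_stack(
            [self.params_ - tcrit * self.bse_, self.params_ + tcrit * self.bse_]
        )
        fixed = Xd @ self.params_
        var_fixed = float(np.var(fixed))
        denom = var_fixed + self.sigma_b2_ + self.sigma_e2_
        self.marginal_r2_ = var_fixed / denom if denom > 0 else float("nan")

    def predict(self, X, groups=None):
        X = np.asarray(X, dtype=float)
        pred = self.intercept_ + X @ self.coef_
        if groups is not None:
            pred = pred + np.array([self.random_effects_.get(g, 0.0) for g in groups])
        return pred


@dataclass
class LMEResult:
    """Inference summary for one outcome of the mixed-effects stage."""

    outcome: str
    terms: list[str]
    params: np.ndarray
    bse: np.ndarray
    conf_int: np.ndarray
    tvalues: np.ndarray
    df: np.ndarray
    pvalues: np.ndarray
    pvalues_adj: np.ndarray
    sigma_b2: float
    sigma_e2: float
    marginal_r2: float
    n_obs: int
    n_subjects: int
    boundary: bool = False
    alpha: float = 0.05

    def to_dict(self) -> dict:
        coef = {}
        for i, term in enumerate(self.terms):
            coef[term] = {
                "estimate": float(self.params[i]),
                "se": float(self.bse[i]),
                "ci": [float(self.conf_int[i, 0]), float(self.conf_int[i, 1])],
                "t": float(self.tvalues[i]),
                "df": float(self.df[i]),
                "p": float(self.pvalues[i]),
                "p_adj": float(self.pvalues_adj[i]),
                "significant": bool(self.pvalues_adj[i] < self.alpha),
            }
        return {
            "outcome": self.outcome,
            "coefficients": coef,
            "random_intercept_var": float(self.sigma_b2),
            "residual_var": float(self.sigma_e2),
            "marginal_r2": float(self.marginal_r2),
            "n_obs": int(self.n_obs),
            "n_subjects": int(self.n_subjects),
            "boundary": bool(self.boundary),
        }


def bonferroni_adjust(pvals, m: int | None = None):
    """Bonferroni adjustment ``p_adj = min(1, m p)`` (m defaults to len(p))."""
    p = np.asarray(pvals, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    adj = np.minimum(1.0, m * p)
    return float(adj[0]) if scalar else adj


def fit_lme(
    rows: pd.DataFrame,
    outcome: str,
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
    subject_col: str = "subject",
    m_tests: int | None = None,
    alpha: float = 0.05,
    df_method: str = "satterthwaite",
) -> LMEResult:
    """REML random-intercept fit of one outcome on the predictor set.

    The Bonferroni multiplicity ``m_tests`` defaults to the number of
    non-intercept predictors; the intercept p-value is adjusted with the
    same factor for consistency of the reported table.
    """
    missing = [c for c in (outcome, subject_col, *predictors) if c not in rows.columns]
    if missing:
        raise DataError(f"missing columns: {missing}")
    if rows[subject_col].nunique() < 1 or len(rows) == 0:
        raise DataError("no observations to fit")
    model = RandomInterceptLME(df_method=df_method, alpha=alpha)
    X = rows[list(predictors)].to_numpy(dtype=float)
    model.fit(X, rows[outcome].to_numpy(dtype=float), groups=rows[subject_col].to_numpy())
    m = m_tests if m_tests is not None else len(predictors)
    return LMEResult(
        outcome=outcome,
        terms=["intercept", *predictors],
        params=model.params_,
        bse=model.bse_,
        conf_int=model.conf_int_,
        tvalues=model.tvalues_,
        df=model.df_,
        pvalues=model.pvalues_,
        pvalues_adj=bonferroni_adjust(model.pvalues_, m),
        sigma_b2=model.sigma_b2_,
        sigma_e2=model.sigma_e2_,
        marginal_r2=model.marginal_r2_,
        n_obs=model.n_obs_,
        n_subjects=model.n_groups_,
        boundary=model.boundary_,
        alpha=alpha,
    )


def report(
    results: dict[str, LMEResult],
    filter_audit: pd.DataFrame | None = None,
    vifs: pd.Series | None = None,
    dropped: list[str] | None = None,
) -> dict:
    """Machine-readable analysis report of the full statistical chain.

    One entry per outcome with coefficient estimates, 95 % CIs, Satterthwaite
    t-tests, adjusted p-values, marginal R², n_obs and subject count, plus
    the filter audit and collinearity screen.
    """
    rep: dict = {"outcomes": {name: res.to_dict() for name, res in sorted(results.items())}}
    if vifs is not None:
        rep["vif"] = {str(k): (None if np.isinf(v) else float(v)) for k, v in vifs.items()}
    if dropped is not None:
        rep["dropped_predictors"] = list(dropped)
    if filter_audit is not None:
        rep["filter_audit"] = {
            "n_removed": int(len(filter_audit)),
            "reasons": filter_audit["reason"].value_counts().to_dict()
            if len(filter_audit)
            else {},
        }
    return rep


def results_table(results: dict[str, LMEResult]) -> pd.DataFrame:
    """Human-readable table: one row per outcome, columns per predictor."""
    rows = []
    for name, res in sorted(results.items()):
        row = {"outcome": name}
        for i, term in enumerate(res.terms):
            lo, hi = res.conf_int[i]
            star = "*" if res.pvalues_adj[i] < res.alpha else ""
            row[term] = f"{res.params[i]:.2f}{star} [{lo:.2f}, {hi:.2f}]"
        row["R2"] = f"{res.marginal_r2:.2f}"
        row["n_obs"] = res.n_obs
        row["N_pid"] = res.n_subjects
        rows.append(row)
    return pd.DataFrame(rows)
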