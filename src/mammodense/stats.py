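"""Case-case statistics for interval versus screen-detected cancer.

The inference stage mirrors the analysis plan of the motivating study:

1. each feature sample is Box-Cox transformed and standardized, so effect
   sizes are per standard deviation of a near-normal score;
2. a battery of 3 x 32 logistic models (one per thresholding method and
   feature) tests each feature against IC-vs-SC status, adjusted for
   continuous percent density, with two-sided Wald p-values;
3. a global permutation test counts how many of the 96 tests fall below 5%
   and compares that count with its permutation distribution under random
   relabelling of IC/SC status (correlation between features is respected
   because labels are permuted jointly);
4. forward selection by AIC builds a multivariate model on the base
   covariates (PD, age, BMI, HRT);
5. the final logistic model reports per-SD odds ratios with 95% CIs, with an
   optional time-to-diagnosis sensitivity covariate;
6. univariate linear models relate each feature to square-root tumor size,
   overall and within detection-mode strata.

The module is organised statsmodels-style: :class:`CaseCaseModel` is built
from a cohort table plus feature tables, ``fit_final`` returns a
:class:`CaseCaseResults` carrying estimates, uncertainties and a
``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sp_stats
import statsmodels.api as sm

from .features import FEATURE_NAMES

Z95 = sp_stats.norm.ppf(0.975)


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass
class AssociationResult:
    """One fitted term: estimate with uncertainty on the reported scale.

    ``estimate`` is the log-odds or linear slope per SD of the covariate;
    ``effect`` is the odds ratio (logistic) or beta (linear); confidence
    limits are 95% Wald intervals transformed consistently.
    """

    term: str
    estimate: float
    se: float
    effect: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    kind: str = "or"            # "or" (odds ratio) or "beta"
    converged: bool = True

    @classmethod
    def from_fit(cls, term: str, est: float, se: float, n: int,
                 kind: str = "or", converged: bool = True
                 ) -> "AssociationResult":
        z = est / se if se > 0 else np.nan
        p = float(2.0 * sp_stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
        lo, hi = est - Z95 * se, est + Z95 * se
        if kind == "or":
            eff, lo, hi = math.exp(est), math.exp(lo), math.exp(hi)
        else:
            eff = est
        return cls(term, float(est), float(se), float(eff), float(lo),
                   float(hi), p, n, kind, converged)

    def format_row(self) -> str:
        return f"{self.term:<28s} {self.effect:5.2f} ({self.ci_low:.2f} to {self.ci_high:.2f})"


@dataclass
class GlobalTestResult:
    """Observed count of sub-5% tests and its permutation p-value."""

    statistic: int
    n_perm: int
    p_value: float
    seed: Optional[int]
    alpha: float = 0.05
    n_tests: int = 0
    n_excluded: int = 0


@dataclass
class TransformSpec:
    """Replayable Box-Cox + standardization transform for one feature."""

    shift: float
    lam: float
    mean: float
    sd: float

    def apply(self, x: np.ndarray) -> np.ndarray:
        y = _boxcox(np.asarray(x, float) + self.shift, self.lam)
        return (y - self.mean) / self.sd


# --------------------------------------------------------------------------
# Box-Cox standardization
# --------------------------------------------------------------------------

def _boxcox(x: np.ndarray, lam: float) -> np.ndarray:
    if abs(lam) < 1e-12:
        return np.log(x)
    return (x ** lam - 1.0) / lam


def box_cox_standardize(values: np.ndarray, lam_range: tuple[float, float] = (-3.0, 3.0)
                        ) -> tuple[np.ndarray, TransformSpec]:
    """Box-Cox transform with profile-ML lambda, then center/scale.

    The sample is shifted by ``max(0, 1 - min)`` so values are >= 1 before
    the power transform; lambda maximizes the Box-Cox profile likelihood on
    ``lam_range``; the transformed sample is standardized to mean 0, SD 1.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError("need at least 10 non-missing values")
    shift = max(0.0, 1.0 - float(x.min()))
    xs = x + shift
    if xs.max() <= xs.min():
        raise ValueError("constant sample: zero variance")
    res = optimize.minimize_scalar(
        lambda lam: -sp_stats.boxcox_llf(lam, xs),
        bounds=lam_range, method="bounded",
        options={"xatol": 1e-4})
    lam = float(res.x)
    y = _boxcox(xs, lam)
    mu, sd = float(y.mean()), float(y.std())
    if sd <= 0:
        raise ValueError("constant sample after transform")
    spec = TransformSpec(shift=shift, lam=lam, mean=mu, sd=sd)
    return (y - mu) / sd, spec


# --------------------------------------------------------------------------
# fast logistic fitting (Newton), used for the test battery and permutations
# --------------------------------------------------------------------------

def _logit_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 50,
               tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Newton-Raphson logistic fit.

    Returns (beta, covariance, log-likelihood, converged).  Convergence
    fails on separation (runaway coefficients) or a singular Hessian.
    """
    n, k = X.shape
    beta = np.zeros(k)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(y @ eta - np.log1p(np.exp(eta)).sum())
        grad = X.T @ (y - mu)
        w = mu * (1.0 - mu)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, np.full((k, k), np.nan), ll, False
        # step-halving keeps the likelihood monotone
        for _ in range(20):
            cand = beta + step
            eta_c = np.clip(X @ cand, -35, 35)
            ll_c = float(y @ eta_c - np.log1p(np.exp(eta_c)).sum())
            if ll_c >= ll - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        if abs(ll_c - ll_old) < tol and np.abs(grad).max() < 1e-6:
            converged = True
            break
        ll_old = ll_c
    if np.abs(beta).max() > 30:
        converged = False
    eta = np.clip(X @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        converged = False
    ll = float(y @ eta - np.log1p(np.exp(eta)).sum())
    return beta, cov, ll, converged


def _batch_hessian(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """X' W X for a batch of diagonal weight vectors w (P, n)."""
    Xw = w[:, :, None] * X[None, :, :]          # (P, n, k)
    return Xw.transpose(0, 2, 1) @ X            # (P, k, k)


def _logit_wald_batch(X: np.ndarray, Y: np.ndarray, coef_index: int = 1,
                      max_iter: int = 12, tol: float = 1e-7) -> np.ndarray:
    """Wald p-values for one coefficient across many outcome vectors.

    ``X`` is (n, k); ``Y`` is (P, n), one permuted outcome per row.  Newton
    iterations run batched over permutations until every step is small;
    p-values that fail to stay finite come back as NaN.
    """
    P, n = Y.shape
    k = X.shape[1]
    beta = np.zeros((P, k))
    eye = 1e-10 * np.eye(k)
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = (Y - mu) @ X
        H = _batch_hessian(X, w) + eye
        try:
            step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            H = H + 1e-6 * np.eye(k)
            step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        beta = beta + step
        np.clip(beta, -30, 30, out=beta)
        if np.abs(step).max() < tol:
            break
    eta = np.clip(beta @ X.T, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = _batch_hessian(X, w)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = np.linalg.inv(H)
        se = np.sqrt(cov[:, coef_index, coef_index])
        z = beta[:, coef_index] / se
    p = 2.0 * sp_stats.norm.sf(np.abs(z))
    p[~np.isfinite(z)] = np.nan
    return p


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - np.nanmean(x)) / np.nanstd(x)


# --------------------------------------------------------------------------
# the model object
# --------------------------------------------------------------------------

class CaseCaseModel:
    """Case-case analysis of a cohort with per-method feature tables.

    Parameters
    ----------
    cohort
        One row per woman; must contain ``outcome`` ("IC"/"SC") and ``pd``;
        other covariates as available (see the cohort column dictionary).
    feature_tables
        Mapping method name -> DataFrame of raw feature values aligned row
        by row with the cohort.  Columns ``<name>_undef`` mark undefined
        values, which are treated as missing.
    """

    BASE_COVARIATES = ("pd", "bmi", "hrt", "age_dx")

    def __init__(self, cohort: pd.DataFrame,
                 feature_tables: dict[str, pd.DataFrame]):
        if "outcome" not in cohort.columns:
            raise ValueError("cohort must have an 'outcome' column")
        if cohort["outcome"].isna().any():
            raise ValueError("outcome must be non-missing")
        self.cohort = cohort.reset_index(drop=True)
        self.y = (self.cohort["outcome"] == "IC").to_numpy(dtype=float)
        if self.y.min() == self.y.max():
            raise ValueError("both outcome classes must be present")
        self.feature_tables = {}
        for method, table in feature_tables.items():
            t = table.reset_index(drop=True)
            if len(t) != len(self.cohort):
                raise ValueError("feature table length differs from cohort")
            self.feature_tables[method] = t
        self._transformed: dict[str, pd.DataFrame] = {}
        self.transform_specs: dict[tuple[str, str], TransformSpec] = {}

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame,
                    feature_columns: dict[str, str] | None = None,
                    method: str = "latent") -> "CaseCaseModel":
        """Build a single-method model from feature columns of the cohort
        itself (e.g. a simulated cohort carrying latent f40/f21 scores)."""
        feature_columns = feature_columns or {"F40": "f40", "F21": "f21"}
        table = pd.DataFrame({k: cohort[v].to_numpy()
                              for k, v in feature_columns.items()})
        return cls(cohort, {method: table})

    # -- transformation ----------------------------------------------------

    def transformed_features(self, method: str) -> pd.DataFrame:
        """Box-Cox standardized feature matrix (NaN where missing/undefined)."""
        if method not in self._transformed:
            table = self.feature_tables[method]
            cols = [c for c in table.columns if not c.endswith("_undef")
                    and c not in ("image_id", "method")]
            out_cols: dict[str, np.ndarray] = {}
            for c in cols:
                x = table[c].to_numpy(dtype=float).copy()
                flag_col = f"{c}_undef"
                if flag_col in table.columns:
                    x[table[flag_col].to_numpy(dtype=bool)] = np.nan
                ok = np.isfinite(x)
                z = np.full(x.shape, np.nan)
                try:
                    z[ok], spec = box_cox_standardize(x[ok])
                    self.transform_specs[(method, c)] = spec
                except ValueError:
                    pass        # constant or too-small sample: stays NaN
                out_cols[c] = z
            self._transformed[method] = pd.DataFrame(out_cols,
                                                     index=table.index)
        return self._transformed[method]

    # -- the 3 x 32 test battery -------------------------------------------

    def per_feature_tests(self, alpha: float = 0.05) -> pd.DataFrame:
        """Logistic Wald tests of each feature, adjusted for continuous PD.

        One model per (method, feature) on its complete cases:
        ``IC ~ feature + PD``.  Non-convergent or degenerate fits are
        flagged with missing p-values.
        """
        rows = []
        pd_vals = self.cohort["pd"].to_numpy(dtype=float)
        for method in self.feature_tables:
            zt = self.transformed_features(method)
            for feat in zt.columns:
                z = zt[feat].to_numpy()
                ok = np.isfinite(z) & np.isfinite(pd_vals)
                res = {"method": method, "feature": feat, "n": int(ok.sum())}
                if ok.sum() < 10 or np.nanstd(z[ok]) == 0:
                    res.update(estimate=np.nan, se=np.nan, p=np.nan,
                               converged=False)
                else:
                    X = np.column_stack([np.ones(ok.sum()), z[ok],
                                         _zscore(pd_vals[ok])])
                    beta, cov, _, conv = _logit_fit(X, self.y[ok])
                    se = float(np.sqrt(cov[1, 1])) if np.isfinite(cov[1, 1]) else np.nan
                    est = float(beta[1])
                    p = (2.0 * sp_stats.norm.sf(abs(est / se))
                         if conv and se > 0 else np.nan)
                    res.update(estimate=est, se=se, p=p, converged=conv)
                res["significant"] = bool(res["p"] < alpha) if np.isfinite(
                    res.get("p", np.nan)) else False
                rows.append(res)
        return pd.DataFrame(rows)

    # -- global permutation test -------------------------------------------

    def global_test(self, n_perm: int = 10000, alpha: float = 0.05,
                    seed: Optional[int] = None, add_one: bool = False
                    ) -> GlobalTestResult:
        """Permutation test of the global null that no feature is associated.

        The statistic is the number of the per-feature tests with p below
        ``alpha``.  IC/SC labels are permuted jointly across the cohort
        (covariates and features stay attached to the woman), preserving the
        correlation structure of the features; the empirical p-value is the
        fraction of permuted statistics strictly larger than the observed
        one (``add_one`` applies the (b+1)/(m+1) correction instead).
        """
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        obs_table = self.per_feature_tests(alpha=alpha)
        valid = obs_table["p"].notna()
        observed = int((obs_table.loc[valid, "p"] < alpha).sum())
        n_excluded = int((~valid).sum())

        rng = np.random.default_rng(seed)
        n = len(self.cohort)
        perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
        y_perm = self.y[perm_idx]              # (P, n)

        pd_vals = self.cohort["pd"].to_numpy(dtype=float)
        perm_counts = np.zeros(n_perm, dtype=int)
        for method in self.feature_tables:
            zt = self.transformed_features(method)
            for feat in zt.columns:
                z = zt[feat].to_numpy()
                ok = np.isfinite(z) & np.isfinite(pd_vals)
                if ok.sum() < 10 or np.nanstd(z[ok]) == 0:
                    continue
                X = np.column_stack([np.ones(ok.sum()), z[ok],
                                     _zscore(pd_vals[ok])])
                p = _logit_wald_batch(X, y_perm[:, ok])
                perm_counts += (p < alpha) & np.isfinite(p)

        exceed = int((perm_counts > observed).sum())
        if add_one:
            p_emp = (exceed + 1) / (n_perm + 1)
        else:
            p_emp = exceed / n_perm
        return GlobalTestResult(statistic=observed, n_perm=n_perm,
                                p_value=float(p_emp), seed=seed, alpha=alpha,
                                n_tests=int(valid.sum()),
                                n_excluded=n_excluded)

    # -- forward selection --------------------------------------------------

    def _base_matrix(self, rows: np.ndarray) -> tuple[np.ndarray, list[str]]:
        cols = [np.ones(rows.sum())]
        names = ["intercept"]
        c = self.cohort.loc[rows]
        cols.append(_zscore(c["pd"].to_numpy(dtype=float)))
        names.append("pd")
        cols.append(_zscore(c["age_dx"].to_numpy(dtype=float)))
        names.append("age_dx")
        cols.append(_zscore(c["bmi"].to_numpy(dtype=float)))
        names.append("bmi")
        cols.append((c["hrt"] == "yes").to_numpy(dtype=float))
        names.append("hrt")
        return np.column_stack(cols), names

    def forward_select(self, method: str = "otsu",
                       candidates: Sequence[str] | None = None
                       ) -> "ForwardSelectionResult":
        """Greedy AIC forward selection of features over the base model.

        The base model is ``IC ~ PD + age + BMI + HRT``.  The complete-case
        set (rows with no missing base covariate or candidate feature) is
        fixed at the start so AICs are comparable; at each step the
        candidate lowering AIC the most is added, ties broken by canonical
        feature order; selection stops when no candidate lowers AIC.
        """
        zt = self.transformed_features(method)
        if candidates is None:
            candidates = [c for c in FEATURE_NAMES if c in zt.columns]
        else:
            candidates = list(candidates)
        need = ["pd", "age_dx", "bmi", "hrt"]
        ok = np.ones(len(self.cohort), dtype=bool)
        for c in need:
            col = self.cohort[c]
            ok &= col.notna().to_numpy()
        for c in candidates:
            ok &= np.isfinite(zt[c].to_numpy())
        if ok.sum() < 20:
            raise ValueError("too few complete cases for forward selection")
        X_base, names = self._base_matrix(ok)
        y = self.y[ok]

        def aic(X: np.ndarray) -> float:
            beta, _, ll, conv = _logit_fit(X, y)
            return 2 * X.shape[1] - 2 * ll if conv else np.inf

        current_X, current_names = X_base, list(names)
        current_aic = aic(current_X)
        base_aic = current_aic
        remaining = list(candidates)
        selected: list[str] = []
        trace = [("<base>", current_aic)]
        while remaining:
            best = None
            for feat in remaining:        # canonical order breaks ties
                Xc = np.column_stack([current_X, zt[feat].to_numpy()[ok]])
                a = aic(Xc)
                if best is None or a < best[1] - 1e-12:
                    best = (feat, a, Xc)
            if best is None or best[1] >= current_aic - 1e-9:
                break
            feat, current_aic, current_X = best
            current_names.append(feat)
            selected.append(feat)
            remaining.remove(feat)
            trace.append((feat, current_aic))
        beta, cov, ll, conv = _logit_fit(current_X, y)
        results = [AssociationResult.from_fit(nm, float(beta[i]),
                                              float(np.sqrt(cov[i, i])),
                                              int(ok.sum()), "or", conv)
                   for i, nm in enumerate(current_names) if nm != "intercept"]
        return ForwardSelectionResult(selected=selected, aic=current_aic,
                                      base_aic=base_aic, trace=trace,
                                      results=results, n=int(ok.sum()),
                                      method=method)

    # -- the final multivariate model ---------------------------------------

    def fit_final(self, features: Sequence[str] = ("F40", "F21"),
                  method: str | None = None,
                  include_time: bool = False) -> "CaseCaseResults":
        """Fit the final per-SD odds-ratio model.

        ``IC ~ PD + BMI + HRT + age + features...`` with Box-Cox
        standardized features; ``include_time`` adds months from mammogram
        to diagnosis as a sensitivity covariate.
        """
        if method is None:
            method = next(iter(self.feature_tables))
        zt = self.transformed_features(method)
        ok = np.ones(len(self.cohort), dtype=bool)
        for c in ("pd", "age_dx", "bmi", "hrt"):
            ok &= self.cohort[c].notna().to_numpy()
        for f in features:
            ok &= np.isfinite(zt[f].to_numpy())
        if include_time:
            ok &= self.cohort["months_to_dx"].notna().to_numpy()
        y = self.y[ok]
        if y.min() == y.max():
            raise ValueError("complete cases contain a single outcome class")
        X, names = self._base_matrix(ok)
        for f in features:
            X = np.column_stack([X, zt[f].to_numpy()[ok]])
            names.append(f)
        if include_time:
            X = np.column_stack(
                [X, _zscore(self.cohort.loc[ok, "months_to_dx"].to_numpy(float))])
            names.append("months_to_dx")
        fit = sm.Logit(y, X).fit(disp=0)
        results = [AssociationResult.from_fit(nm, float(fit.params[i]),
                                              float(fit.bse[i]), int(ok.sum()),
                                              "or", bool(fit.mle_retvals["converged"]))
                   for i, nm in enumerate(names) if nm != "intercept"]
        return CaseCaseResults(results=results, n=int(ok.sum()), method=method,
                               loglik=float(fit.llf), statsmodels_fit=fit)


@dataclass
class ForwardSelectionResult:
    """Selection path and the final model it produced."""

    selected: list[str]
    aic: float
    base_aic: float
    trace: list[tuple[str, float]]
    results: list[AssociationResult]
    n: int
    method: str


@dataclass
class CaseCaseResults:
    """Per-SD odds ratios of the final multivariate model."""

    results: list[AssociationResult]
    n: int
    method: str
    loglik: float
    statsmodels_fit: object = None

    def __getitem__(self, term: str) -> AssociationResult:
        for r in self.results:
            if r.term == term:
                return r
        raise KeyError(term)

    def summary(self) -> str:
        lines = [
            f"Case-case logistic model (IC vs SC), n = {self.n}, "
            f"features from {self.method}",
            f"{'covariate':<28s} OR (95% CI) per SD",
            "-" * 54,
        ]
        lines += [r.format_row() for r in self.results]
        return "\n".join(lines)


# --------------------------------------------------------------------------
# tumor-size and risk-factor models, cohort summary
# --------------------------------------------------------------------------

def tumor_size_regression(cohort: pd.DataFrame, feature: np.ndarray | pd.Series,
                          stratum: str = "all") -> AssociationResult:
    """Linear model of square-root tumor size on one standardized feature.

    Tumor size (mm) is left-skewed, so the square root is modelled; the
    feature sample is Box-Cox standardized on the analyzed rows, giving a
    per-SD slope.  ``stratum`` restricts to screen-detected ("SC"),
    interval ("IC") cancers or uses everyone ("all").
    """
    feat = np.asarray(feature, dtype=float)
    if stratum not in ("all", "SC", "IC"):
        raise ValueError("stratum must be 'all', 'SC' or 'IC'")
    rows = np.ones(len(cohort), dtype=bool)
    if stratum != "all":
        rows &= (cohort["outcome"] == stratum).to_numpy()
    if not rows.any():
        raise ValueError(f"stratum {stratum!r} is empty")
    size = cohort["tumor_size"].to_numpy(dtype=float)
    present = rows & np.isfinite(size) & np.isfinite(feat)
    if (size[present] <= 0).any():
        raise ValueError("tumor size must be positive")
    if present.sum() < 10:
        raise ValueError("too few complete cases")
    z, _ = box_cox_standardize(feat[present])
    y = np.sqrt(size[present])
    X = sm.add_constant(z)
    fit = sm.OLS(y, X).fit()
    return AssociationResult.from_fit(f"feature[{stratum}]",
                                      float(fit.params[1]), float(fit.bse[1]),
                                      int(present.sum()), kind="beta")


def feature_risk_factor_models(cohort: pd.DataFrame,
                               feature: np.ndarray | pd.Series,
                               risk_factor: str) -> list[AssociationResult]:
    """Linear model of a standardized feature on one risk factor.

    Continuous risk factors enter as-is; categorical ones are
    indicator-coded against the first level.  Returns one result per
    non-intercept term.
    """
    feat = np.asarray(feature, dtype=float)
    col = cohort[risk_factor]
    ok = np.isfinite(feat) & col.notna().to_numpy()
    if ok.sum() < 10:
        raise ValueError("too few complete cases")
    z, _ = box_cox_standardize(feat[ok])
    sub = col[ok]
    if sub.dtype.kind in "ifu":
        x = sub.to_numpy(dtype=float)
        if np.std(x) == 0:
            raise ValueError(f"risk factor {risk_factor!r} is constant")
        design = pd.DataFrame({risk_factor: x})
    else:
        levels = sorted(sub.astype(str).unique())
        if len(levels) < 2:
            raise ValueError(f"risk factor {risk_factor!r} has a single level")
        design = pd.get_dummies(sub.astype(str), prefix=risk_factor,
                                drop_first=True).astype(float)
    X = sm.add_constant(design.to_numpy())
    fit = sm.OLS(z, X).fit()
    out = []
    for i, name in enumerate(design.columns, start=1):
        out.append(AssociationResult.from_fit(str(name), float(fit.params[i]),
                                              float(fit.bse[i]),
                                              int(ok.sum()), kind="beta"))
    return out


# -- cohort summary ---------------------------------------------------------

#: (column, kind, statistic) descriptors for the cohort characteristics table.
SUMMARY_VARIABLES = [
    ("age_dx", "continuous", "mean"),
    ("menopausal", "categorical", None),
    ("bmi", "continuous", "mean"),
    ("hrt", "categorical", None),
    ("oc_use", "categorical", None),
    ("parity_status", "categorical", None),
    ("births", "continuous", "mean"),
    ("age_first_birth", "continuous", "mean"),
    ("family_history", "categorical", None),
    ("months_to_dx", "continuous", "median"),
    ("pd", "continuous", "median"),
    ("tumor_size", "continuous", "mean"),
    ("lymph_node", "categorical", None),
    ("grade", "categorical", None),
    ("er", "categorical", None),
    ("pr", "categorical", None),
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def summarize_counts(level_counts: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Within-group percentages and a chi-square p from printed counts.

    ``level_counts`` maps level name -> (IC count, SC count).  Percentages
    are percent of the group total over the listed levels, rounded to the
    nearest integer (half up) as in published characteristics tables.
    """
    levels = list(level_counts)
    ic = np.array([level_counts[l][0] for l in levels], dtype=float)
    sc = np.array([level_counts[l][1] for l in levels], dtype=float)
    if ic.sum() == 0 or sc.sum() == 0:
        raise ValueError("each group needs a positive total")
    table = np.stack([ic, sc])
    chi2, p, _, _ = sp_stats.chi2_contingency(table, correction=False)
    return pd.DataFrame({
        "level": levels,
        "ic_count": ic.astype(int),
        "ic_pct": [_round_half_up(100 * c / ic.sum()) for c in ic],
        "sc_count": sc.astype(int),
        "sc_pct": [_round_half_up(100 * c / sc.sum()) for c in sc],
        "p": p,
    })


def cohort_summary(cohort: pd.DataFrame,
                   variables: list[tuple] | None = None) -> pd.DataFrame:
    """Characteristics table by detection mode.

    Continuous variables: group means (or medians where conventional) and a
    two-sided Welch t-test.  Categorical variables: within-group counts and
    percentages of non-missing values (rounded to the nearest integer) and
    a Pearson chi-square test.  Percent missing is reported overall.
    """
    if variables is None:
        variables = [v for v in SUMMARY_VARIABLES if v[0] in cohort.columns]
    ic = cohort[cohort["outcome"] == "IC"]
    sc = cohort[cohort["outcome"] == "SC"]
    if len(ic) == 0 or len(sc) == 0:
        raise ValueError("both outcome groups must be nonempty")
    rows = []
    for name, kind, stat in variables:
        col = cohort[name]
        pct_missing = 100.0 * col.isna().mean()
        if kind == "continuous":
            a = ic[name].dropna().to_numpy(dtype=float)
            b = sc[name].dropna().to_numpy(dtype=float)
            if a.size == 0 or b.size == 0:
                raise ValueError(f"variable {name!r} all-missing in one group")
            _, p = sp_stats.ttest_ind(a, b, equal_var=False)
            f = np.median if stat == "median" else np.mean
            rows.append({"variable": name, "level": stat, "ic": float(f(a)),
                         "sc": float(f(b)), "p": float(p),
                         "pct_missing": pct_missing})
        else:
            a = ic[name].dropna().astype(str)
            b = sc[name].dropna().astype(str)
            if a.size == 0 or b.size == 0:
                raise ValueError(f"variable {name!r} all-missing in one group")
            levels = sorted(set(a) | set(b))
            tab = np.array([[int((a == l).sum()) for l in levels],
                            [int((b == l).sum()) for l in levels]], dtype=float)
            if tab.shape[1] >= 2:
                _, p, _, _ = sp_stats.chi2_contingency(tab, correction=False)
            else:
                p = np.nan
            for j, lvl in enumerate(levels):
                rows.append({
                    "variable": name, "level": lvl,
                    "ic": f"{int(tab[0, j])} ({_round_half_up(100 * tab[0, j] / a.size)} %)",
                    "sc": f"{int(tab[1, j])} ({_round_half_up(100 * tab[1, j] / b.size)} %)",
                    "p": float(p), "pct_missing": pct_missing,
                })
    return pd.DataFrame(rows)
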