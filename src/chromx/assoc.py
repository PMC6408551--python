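"""Sex-stratified additive association under X-inactivation dosage models.

Two codings for an X-linked additive model:

* ``escape`` -- the locus escapes X-inactivation, so each female allele is
  expressed: females dose 0/1/2, hemizygous males 0/1;
* ``xci`` -- random X-inactivation makes a heterozygous female dosage-
  equivalent to a hemizygous male, so males are treated as homozygous:
  females 0/1/2, males 0/2.

Single-SNP linear and logistic fits, the stratified 1-df score test that pools
the sexes under random XCI (Clayton-style), conditional joint multi-SNP
models, and a noncentral-F power calculation for small Cohen-f2 effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genodata import MISSING, GenotypeDataset

ESCAPE = "escape"
XCI = "xci"

_MALE_MAP = {ESCAPE: {0: 0.0, 1: 1.0}, XCI: {0: 0.0, 1: 2.0}}


@dataclass(frozen=True)
class AssocResult:
    variant: str
    stratum: str
    model: str
    beta: float
    ci_low: float
    ci_high: float
    p: float
    se: float
    n_used: int
    covariates: str = "none"
    converged: bool = True

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class JointAssocResult:
    """One multi-SNP conditional fit: per-variant beta/SE/P plus VIFs."""

    table: pd.DataFrame  # index variant; beta, se, p, vif
    dropped: list[str]
    n_used: int


def code_dosage(
    ds: GenotypeDataset,
    model: str = ESCAPE,
    sex: str | None = None,
) -> np.ndarray:
    """Per-sample dosage matrix under the given XCI model (NaN = missing).

    ``sex`` restricts to one stratum: other samples come back NaN so the
    vector stays aligned with the dataset.
    """
    if model not in _MALE_MAP:
        raise ValueError(f"unknown dosage model {model!r}")
    calls = ds.calls.astype(float)
    calls[ds.calls == MISSING] = np.nan
    male = ds.is_male
    if model == XCI:
        male_calls = calls[male]
        male_calls[male_calls == 1] = 2.0
        calls[male] = male_calls
    if sex is not None:
        keep = male if sex == "male" else ~male
        calls[~keep] = np.nan
    return calls


def _wald_ci(beta, se, crit):
    return beta - crit * se, beta + crit * se


def linear_assoc(
    y,
    dosage,
    covariates: pd.DataFrame | np.ndarray | None = None,
    variant: str = "",
    stratum: str = "all",
    model: str = ESCAPE,
    covariate_label: str = "none",
) -> AssocResult:
    """OLS of a quantitative trait on allele dosage (+ covariates).

    Listwise deletion of missing values; Wald t test on the dosage
    coefficient, 95% CI = beta +/- t_{0.975,df} * SE.
    """
    y = np.asarray(y, float)
    dosage = np.asarray(dosage, float)
    if covariates is not None:
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
        X = np.column_stack([dosage, cov])
    else:
        X = dosage[:, None]
    keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y_, X_ = y[keep], X[keep]
    if len(y_) < X_.shape[1] + 2:
        raise ValueError("too few complete cases")
    if np.ptp(X_[:, 0]) == 0:
        raise ValueError(f"{variant or 'dosage'}: constant dosage, no association fit")
    Xc = sm.add_constant(X_, has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates)")
    fit = sm.OLS(y_, Xc).fit()
    beta, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
    crit = stats.t.ppf(0.975, fit.df_resid)
    lo, hi = _wald_ci(beta, se, crit)
    return AssocResult(
        variant=variant, stratum=stratum, model=model,
        beta=float(beta), ci_low=float(lo), ci_high=float(hi),
        p=float(p), se=float(se), n_used=int(keep.sum()),
        covariates=covariate_label,
    )


def logistic_assoc(
    y_binary,
    dosage,
    covariates: pd.DataFrame | np.ndarray | None = None,
    variant: str = "",
    stratum: str = "all",
    model: str = ESCAPE,
    covariate_label: str = "none",
) -> AssocResult:
    """Logistic regression of a binary outcome on allele dosage (+ covariates).

    Newton/IRLS maximum likelihood; Wald z test and normal-based 95% CI on the
    log-odds scale.  Divergent |beta| > 15 flags (quasi-)separation and marks
    the result non-converged.
    """
    y = np.asarray(y_binary, float)
    dosage = np.asarray(dosage, float)
    if covariates is not None:
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
        X = np.column_stack([dosage, cov])
    else:
        X = dosage[:, None]
    keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y_, X_ = y[keep], X[keep]
    if len(np.unique(y_)) < 2:
        raise ValueError("both outcome classes must be present")
    Xc = sm.add_constant(X_, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y_, Xc).fit(disp=0, maxiter=50)
        except np.linalg.LinAlgError:
            # Newton blows up under (quasi-)separation; a gradient method
            # diverges gracefully instead, which the |beta| check then flags
            fit = sm.Logit(y_, Xc).fit(disp=0, maxiter=200, method="bfgs")
    beta, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
    converged = bool(fit.mle_retvals.get("converged", True)) and abs(beta) <= 15
    z = stats.norm.ppf(0.975)
    lo, hi = _wald_ci(beta, se, z)
    return AssocResult(
        variant=variant, stratum=stratum, model=model,
        beta=float(beta), ci_low=float(lo), ci_high=float(hi),
        p=float(p), se=float(se), n_used=int(keep.sum()),
        covariates=covariate_label, converged=converged,
    )


def clayton_x_test(y, calls, is_male) -> tuple[float, float]:
    """Sex-stratified 1-df score test for an X-linked quantitative trait.

    Doses follow the random-XCI coding (males hemizygous, counted 0/2).  With
    sex strata s, U = sum_s sum_i (y_i - ybar_s)(g_i - gbar_s) and
    V = sum_s [sum (y - ybar_s)^2][sum (g - gbar_s)^2]/(n_s - 1); under the
    null T = U^2/V is chi-square with 1 df.  Pooling both sexes this way
    recovers the extra power the stratified X test is used for.

    Returns (T, two-sided P).  Strata with fewer than 2 complete cases are
    dropped with a warning.
    """
    y = np.asarray(y, float)
    calls = np.asarray(calls, float)
    calls = np.where(calls == MISSING, np.nan, calls)
    is_male = np.asarray(is_male, bool)
    g = calls.copy()
    g[is_male & (g == 1)] = 2.0

    U = 0.0
    V = 0.0
    used = 0
    for male_stratum in (False, True):
        sel = (is_male == male_stratum) & np.isfinite(y) & np.isfinite(g)
        n_s = int(sel.sum())
        if n_s < 2:
            if (is_male == male_stratum).any():
                warnings.warn(
                    f"stratum {'male' if male_stratum else 'female'} has n<2; dropped"
                )
            continue
        ys, gs = y[sel], g[sel]
        dy, dg = ys - ys.mean(), gs - gs.mean()
        U += float(dy @ dg)
        V += float((dy @ dy) * (dg @ dg)) / (n_s - 1)
        used += n_s
    if used == 0 or V <= 0:
        return 0.0, 1.0
    T = U * U / V
    return float(T), float(stats.chi2.sf(T, 1))


def joint_conditional_assoc(
    y,
    dosages: pd.DataFrame,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> JointAssocResult:
    """One OLS with all SNP dosages entered simultaneously.

    Conditional Wald P per SNP plus variance-inflation factors.  A pair of
    exactly collinear dosage columns keeps only the earlier one (map order);
    the dropped id is reported.
    """
    dosages = pd.DataFrame(dosages)
    if dosages.shape[1] < 2:
        raise ValueError("joint model needs >= 2 SNPs")
    y = np.asarray(y, float)

    dropped: list[str] = []
    keep_cols = list(dosages.columns)
    # exact collinearity among dosage columns -> drop the later of each pair
    vals = dosages.to_numpy(float)
    complete = np.isfinite(vals).all(axis=1) & np.isfinite(y)
    corr = np.corrcoef(vals[complete].T)
    for b in range(len(keep_cols) - 1, 0, -1):
        for a in range(b):
            if keep_cols[b] is None or keep_cols[a] is None:
                continue
            if abs(corr[a, b]) > 1 - 1e-12:
                warnings.warn(
                    f"{dosages.columns[b]} perfectly collinear with "
                    f"{dosages.columns[a]}; dropped"
                )
                dropped.append(str(dosages.columns[b]))
                keep_cols[b] = None
                break
    cols = [c for c in keep_cols if c is not None]
    Xd = dosages[cols].to_numpy(float)

    if covariates is not None:
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
        X = np.column_stack([Xd, cov])
    else:
        X = Xd
    keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
    if keep.sum() <= X.shape[1] + 1:
        raise ValueError("too few complete cases for the joint model")
    y_, X_ = y[keep], X[keep]
    Xc = sm.add_constant(X_, has_constant="add")
    fit = sm.OLS(y_, Xc).fit()

    m = len(cols)
    vifs = []
    for j in range(m):
        others = np.delete(X_, j, axis=1)
        r2 = sm.OLS(X_[:, j], sm.add_constant(others, has_constant="add")).fit().rsquared
        vifs.append(1.0 / max(1 - r2, 1e-12))
    table = pd.DataFrame(
        {
            "beta": fit.params[1 : 1 + m],
            "se": fit.bse[1 : 1 + m],
            "p": fit.pvalues[1 : 1 + m],
            "vif": vifs,
        },
        index=[str(c) for c in cols],
    )
    return JointAssocResult(table=table, dropped=dropped, n_used=int(keep.sum()))


def power_linear_f2(
    n: int, f2: float, alpha: float = 0.05, df_model: int = 1
) -> float:
    """Power of the linear-model F test for a Cohen-f2 effect size.

    Noncentrality ncp = f2 * n; power = P(F(df_model, n - df_model - 1; ncp)
    exceeds the central 1-alpha critical value).  f2 = 0 returns alpha.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0,1)")
    if f2 < 0:
        raise ValueError("f2 must be >= 0")
    df2 = n - df_model - 1
    if df2 < 1:
        raise ValueError("n too small for df_model")
    crit = stats.f.ppf(1 - alpha, df_model, df2)
    if f2 == 0:
        return float(alpha)
    return float(stats.ncf.sf(crit, df_model, df2, f2 * n))
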