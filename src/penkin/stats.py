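"""Random-intercept mixed models, Satterthwaite F tests, contrasts, Spearman.

The design is the study's Group x Direction x Bigram factorial measured on
subject-level cell means (one row per subject x direction x bigram).  The
model per measure is

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, sigma2_subject),
                                      e_ij ~ N(0, sigma2_resid),

with sum-to-zero (effect) coding for the three two-level factors and all
interactions.  Estimation is REML, profiled down to the single variance
ratio lambda = sigma2_subject / sigma2_resid: for fixed lambda the GLS
coefficients and the REML criterion are closed-form, so lambda is found by
bounded scalar minimisation.  Type-III Wald F tests use Satterthwaite
denominator degrees of freedom via the delta method over the two variance
components, with the component covariance taken from the inverse (numerical)
REML observed information.  Effect size is partial eta-squared,
df1*F / (df1*F + df2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats as sps

FACTORS = ("group", "direction", "bigram")
TERMS = ("group", "direction", "bigram",
         "group:direction", "group:bigram", "direction:bigram",
         "group:direction:bigram")


class DesignError(ValueError):
    """Rank-deficient or otherwise unusable fixed-effect design."""


class ConvergenceError(RuntimeError):
    """The REML scalar search failed to converge."""


# ---------------------------------------------------------------------------
# design construction

def _effect_codes(cells: pd.DataFrame) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Sum-to-zero codes (+1 for the first sorted level, -1 for the second)."""
    codes = {}
    levels = {}
    for f in FACTORS:
        lv = sorted(cells[f].unique())
        if len(lv) != 2:
            raise DesignError(f"factor {f!r} must have exactly 2 levels, got {lv}")
        levels[f] = lv
        codes[f] = np.where(cells[f].to_numpy() == lv[0], 1.0, -1.0)
    return levels, codes


def _design_matrix(cells: pd.DataFrame) -> tuple[np.ndarray, list[str], dict]:
    levels, codes = _effect_codes(cells)
    cols = [np.ones(len(cells))]
    names = ["(Intercept)"]
    for term in TERMS:
        parts = term.split(":")
        col = np.ones(len(cells))
        for p in parts:
            col = col * codes[p]
        cols.append(col)
        names.append(term)
    X = np.column_stack(cols)
    return X, names, levels


@dataclass
class LMMFit:
    """A fitted random-intercept mixed model for one response."""

    response: str
    term_names: list[str]
    beta: np.ndarray
    sigma2_subject: float
    sigma2_resid: float
    loglik_reml: float          # REML log-likelihood at the optimum
    X: np.ndarray
    y: np.ndarray
    subject_codes: np.ndarray   # integer subject index per row
    n_subjects: int
    levels: dict
    theta_cov: np.ndarray       # inverse REML information over the components
    theta_info: np.ndarray      # the information matrix itself

    @property
    def lambda_hat(self) -> float:
        return self.sigma2_subject / self.sigma2_resid if self.sigma2_resid > 0 else 0.0

    def _Sigma(self, theta: np.ndarray) -> np.ndarray:
        s2s, s2e = theta
        n = self.y.size
        Z = np.zeros((n, self.n_subjects))
        Z[np.arange(n), self.subject_codes] = 1.0
        return s2e * np.eye(n) + s2s * (Z @ Z.T)

    def cov_beta(self, theta: np.ndarray | None = None) -> np.ndarray:
        """GLS coefficient covariance at variance components ``theta``."""
        if theta is None:
            theta = np.array([self.sigma2_subject, self.sigma2_resid])
        Sigma = self._Sigma(theta)
        Si = linalg.inv(Sigma)
        return linalg.inv(self.X.T @ Si @ self.X)

    def fitted(self) -> np.ndarray:
        return self.X @ self.beta


def _reml_pieces(lam: float, X: np.ndarray, y: np.ndarray,
                 subject_codes: np.ndarray, n_subjects: int):
    """GLS solve and profiled REML criterion for V = I + lam * Z Z'.

    Uses the per-subject block structure: within subject i of m_i rows,
    V_i^{-1} = I - (lam / (1 + m_i lam)) J and log|V_i| = log(1 + m_i lam).
    """
    n, p = X.shape
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    ytViy = 0.0
    logdetV = 0.0
    for i in range(n_subjects):
        idx = subject_codes == i
        Xi, yi = X[idx], y[idx]
        m = int(idx.sum())
        c = lam / (1.0 + m * lam)
        xs, ys = Xi.sum(axis=0), yi.sum()
        XtViX += Xi.T @ Xi - c * np.outer(xs, xs)
        XtViy += Xi.T @ yi - c * xs * ys
        ytViy += yi @ yi - c * ys * ys
        logdetV += np.log1p(m * lam)
    try:
        cf = linalg.cho_factor(XtViX)
    except linalg.LinAlgError as exc:
        raise DesignError(f"rank-deficient fixed-effect design: {exc}") from exc
    beta = linalg.cho_solve(cf, XtViy)
    rss = float(ytViy - XtViy @ beta)          # r' V^{-1} r
    sigma2 = max(rss / (n - p), 1e-300)        # guard exact-fit degeneracy
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise DesignError("rank-deficient fixed-effect design")
    neg2_reml = ((n - p) * np.log(2 * np.pi * sigma2) + (n - p)
                 + logdetV + logdetXtViX)
    if not np.isfinite(neg2_reml):
        neg2_reml = np.inf
    return beta, sigma2, neg2_reml


def reml_neg2loglik(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                    subject_codes: np.ndarray, n_subjects: int) -> float:
    """-2 REML log-likelihood as a function of (sigma2_subject, sigma2_resid).

    Same criterion as the profiled form but without profiling sigma2_resid —
    used for the numerical information matrix behind Satterthwaite df.
    """
    s2s, s2e = theta
    if s2e <= 0 or s2s < 0:
        return np.inf
    n, p = X.shape
    XtSiX = np.zeros((p, p))
    XtSiy = np.zeros(p)
    ytSiy = 0.0
    logdetS = 0.0
    for i in range(n_subjects):
        idx = subject_codes == i
        Xi, yi = X[idx], y[idx]
        m = int(idx.sum())
        c = (s2s / s2e) / (1.0 + m * s2s / s2e)
        xs, ys = Xi.sum(axis=0), yi.sum()
        XtSiX += (Xi.T @ Xi - c * np.outer(xs, xs)) / s2e
        XtSiy += (Xi.T @ yi - c * xs * ys) / s2e
        ytSiy += (yi @ yi - c * ys * ys) / s2e
        logdetS += np.log1p(m * s2s / s2e) + m * np.log(s2e)
    try:
        beta = np.linalg.solve(XtSiX, XtSiy)
    except np.linalg.LinAlgError:
        return np.inf
    quad = float(ytSiy - XtSiy @ beta)
    sign, logdetXtSiX = np.linalg.slogdet(XtSiX)
    out = (n - p) * np.log(2 * np.pi) + logdetS + logdetXtSiX + quad
    return out if np.isfinite(out) else np.inf


def fit_random_intercept_lmm(cells: pd.DataFrame, response: str,
                             lambda_max: float = 1e4) -> LMMFit:
    """REML fit of the Group x Direction x Bigram model with a per-subject
    random intercept, on the subject cell-mean table."""
    needed = {"subject_id", *FACTORS, response}
    missing = needed - set(cells.columns)
    if missing:
        raise DesignError(f"cell table missing columns {sorted(missing)}")
    for g in sorted(cells["group"].unique()):
        if cells.loc[cells["group"] == g, "subject_id"].nunique() < 2:
            raise DesignError(f"need at least 2 subjects per group (group {g!r})")

    cells = cells.reset_index(drop=True)
    subjects = sorted(cells["subject_id"].unique())
    sub_idx = {s: i for i, s in enumerate(subjects)}
    subject_codes = cells["subject_id"].map(sub_idx).to_numpy()
    X, names, levels = _design_matrix(cells)
    y = cells[response].to_numpy(dtype=float)

    def crit(log_lam: float) -> float:
        return _reml_pieces(np.exp(log_lam), X, y, subject_codes, len(subjects))[2]

    res = optimize.minimize_scalar(crit, bounds=(np.log(1e-8), np.log(lambda_max)),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    if not res.success:
        raise ConvergenceError(f"REML scalar search failed: {res.message}")
    lam = float(np.exp(res.x))
    # The boundary lambda = 0 (no subject variance) is a legitimate optimum
    # that the open search can only approach; take it when it wins.
    beta0, sigma20, crit0 = _reml_pieces(0.0, X, y, subject_codes, len(subjects))
    if crit0 <= res.fun + 1e-10:
        lam = 0.0
        beta, sigma2, neg2 = beta0, sigma20, crit0
    else:
        beta, sigma2, neg2 = _reml_pieces(lam, X, y, subject_codes, len(subjects))

    theta = np.array([lam * sigma2, sigma2])
    info, info_inv = _reml_information(theta, X, y, subject_codes, len(subjects))
    return LMMFit(
        response=response, term_names=names, beta=beta,
        sigma2_subject=theta[0], sigma2_resid=theta[1],
        loglik_reml=-0.5 * neg2, X=X, y=y,
        subject_codes=subject_codes, n_subjects=len(subjects),
        levels=levels, theta_cov=info_inv, theta_info=info,
    )


def _reml_information(theta: np.ndarray, X, y, subject_codes,
                      n_subjects) -> tuple[np.ndarray, np.ndarray]:
    """Numerical REML observed information over the two variance
    components, and its inverse.  One-sided steps are used against the
    sigma2_subject >= 0 boundary."""
    f = lambda th: reml_neg2loglik(th, X, y, subject_codes, n_subjects) / 2.0
    h = np.maximum(1e-7, 1e-4 * np.maximum(theta, theta[1]))
    # against the sigma2_subject >= 0 boundary, step only forward in theta[0]
    shift0 = theta[0] < h[0]

    def step(i: int, k: float) -> np.ndarray:
        th = theta.copy()
        th[i] += k * h[i]
        if shift0:
            th[0] = max(th[0], 0.0) + (h[0] if i != 0 else 0.0)
        return th

    H = np.zeros((2, 2))
    for i in range(2):
        fwd = shift0 and i == 0
        if fwd:
            H[i, i] = (f(step(i, 0)) - 2 * f(step(i, 1)) + f(step(i, 2))) / h[i] ** 2
        else:
            H[i, i] = (f(step(i, 1)) - 2 * f(step(i, 0)) + f(step(i, -1))) / h[i] ** 2
    # mixed partial (central in theta[1]; forward-shifted in theta[0] at boundary)
    def f2(k0: float, k1: float) -> float:
        th = theta.copy()
        base0 = theta[0] + (h[0] if shift0 else 0.0)
        th[0] = base0 + k0 * h[0]
        th[1] = theta[1] + k1 * h[1]
        return f(th)

    H[0, 1] = H[1, 0] = (f2(1, 1) - f2(1, -1) - f2(-1, 1) + f2(-1, -1)) / (4 * h[0] * h[1])
    if not np.isfinite(H).all():
        # degenerate fit (e.g. an exactly constant response); downstream df
        # computations fall back to the residual df
        return H, np.zeros((2, 2))
    try:
        return H, linalg.inv(H)
    except linalg.LinAlgError as exc:
        raise DesignError(f"singular REML information matrix: {exc}") from exc


def satterthwaite_df(fit: LMMFit, c: np.ndarray) -> float:
    """Satterthwaite denominator df for the scalar contrast c'beta:
    df = 2 (c' C(theta) c)^2 / Var(c' C(theta) c), with the variance from the
    delta method over the variance components."""
    theta = np.array([fit.sigma2_subject, fit.sigma2_resid])
    g_of = lambda th: float(c @ fit.cov_beta(th) @ c)
    f0 = g_of(theta)
    grad = np.zeros(2)
    for i in range(2):
        h = max(1e-8, 1e-5 * max(theta[i], theta[1]))
        if i == 0 and theta[0] < h:     # boundary: one-sided
            tp = theta.copy(); tp[0] += h
            grad[0] = (g_of(tp) - f0) / h
        else:
            tp = theta.copy(); tm = theta.copy()
            tp[i] += h; tm[i] -= h
            grad[i] = (g_of(tp) - g_of(tm)) / (2 * h)
    if fit.sigma2_subject <= 1e-10 * fit.sigma2_resid:
        # subject variance estimated on its boundary: treat it as
        # structurally zero, so the df collapse to the fixed-effects case
        info_ee = fit.theta_info[1, 1]
        var = float(grad[1] ** 2 / info_ee) if np.isfinite(info_ee) and info_ee > 0 else 0.0
    else:
        var = float(grad @ fit.theta_cov @ grad)
    if var <= 0:
        # information numerically singular in this direction; fall back to the
        # residual-df bound rather than failing the whole analysis
        n, p = fit.X.shape
        return float(n - p)
    return 2.0 * f0 ** 2 / var


@dataclass
class EffectTest:
    term: str
    F: float
    df1: int
    df2: float
    p: float
    eta_p2: float


def partial_eta_sq(F: float, df1: int, df2: float) -> float:
    """Partial eta-squared from a Wald F: df1*F / (df1*F + df2)."""
    if F < 0 or df1 < 1 or df2 <= 0:
        raise ValueError("need F >= 0, df1 >= 1, df2 > 0")
    return df1 * F / (df1 * F + df2)


def type3_f_tests(fit: LMMFit) -> list[EffectTest]:
    """Type-III Wald F tests for the seven factorial terms.

    Under sum-to-zero coding each term is a single coefficient, so each F is
    a squared t with df1 = 1 and its own Satterthwaite df2.
    """
    C = fit.cov_beta()
    out = []
    for j, name in enumerate(fit.term_names):
        if name == "(Intercept)":
            continue
        c = np.zeros(fit.beta.size)
        c[j] = 1.0
        F = float(fit.beta[j] ** 2 / C[j, j])
        df2 = satterthwaite_df(fit, c)
        p = float(sps.f.sf(F, 1, df2))
        out.append(EffectTest(term=name, F=F, df1=1, df2=df2, p=p,
                              eta_p2=partial_eta_sq(F, 1, df2)))
    return out


def effect_tests_frame(tests: list[EffectTest]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in tests])


@dataclass
class ContrastResult:
    group: str
    direction: str
    label: str          # "ll - ln"
    estimate: float
    se: float
    t: float
    df: float
    p_unadjusted: float
    p_holm: float = np.nan


def _cell_row(levels: dict, group: str, direction: str, bigram: str) -> np.ndarray:
    """Design row of the estimated marginal mean for one factorial cell."""
    code = {f: (1.0 if val == levels[f][0] else -1.0)
            for f, val in zip(FACTORS, (group, direction, bigram))}
    row = [1.0]
    for term in TERMS:
        v = 1.0
        for p in term.split(":"):
            v *= code[p]
        row.append(v)
    return np.array(row)


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (monotone, >= unadjusted)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def pairwise_contrasts(fit: LMMFit) -> list[ContrastResult]:
    """The four ll - ln contrasts of estimated marginal cell means, one per
    (group, direction), with Satterthwaite df and Holm adjustment over the
    4-contrast family."""
    lv = fit.levels
    C = fit.cov_beta()
    results = []
    for g in lv["group"]:
        for d in lv["direction"]:
            c = _cell_row(lv, g, d, "ll") - _cell_row(lv, g, d, "ln")
            est = float(c @ fit.beta)
            se = float(np.sqrt(c @ C @ c))
            df = satterthwaite_df(fit, c)
            tval = est / se
            p = float(2 * sps.t.sf(abs(tval), df))
            results.append(ContrastResult(group=g, direction=d, label="ll - ln",
                                          estimate=est, se=se, t=tval, df=df,
                                          p_unadjusted=p))
    adj = holm_adjust(np.array([r.p_unadjusted for r in results]))
    for r, a in zip(results, adj):
        r.p_holm = float(a)
    return results


def contrasts_frame(contrasts: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in contrasts])


@dataclass
class CorrelationMatrix:
    variables: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def spearman_matrix(subjects: pd.DataFrame,
                    variables: list[str] | None = None) -> CorrelationMatrix:
    """Pairwise-complete Spearman correlations with two-sided p-values from
    the t approximation t = rho * sqrt((n-2)/(1-rho^2)) on n-2 df.

    Ties receive average ranks.  A variable with zero variance has undefined
    correlations, reported as NaN.
    """
    if variables is None:
        variables = [c for c in subjects.columns
                     if np.issubdtype(subjects[c].dtype, np.number)]
    k = len(variables)
    rho = np.full((k, k), np.nan)
    pm = np.full((k, k), np.nan)
    nm = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            a = subjects[variables[i]].to_numpy(dtype=float)
            b = subjects[variables[j]].to_numpy(dtype=float)
            mask = np.isfinite(a) & np.isfinite(b)
            n = int(mask.sum())
            nm[i, j] = nm[j, i] = n
            if n < 4:
                continue
            av, bv = a[mask], b[mask]
            if np.ptp(av) == 0 or np.ptp(bv) == 0:
                if i == j and np.ptp(av) == 0:
                    continue
                if i != j:
                    continue
            if i == j:
                rho[i, j] = 1.0
                pm[i, j] = 0.0
                continue
            r = float(sps.spearmanr(av, bv).statistic)
            rho[i, j] = rho[j, i] = r
            if abs(r) >= 1.0:
                pval = 0.0
            else:
                tstat = r * np.sqrt((n - 2) / (1 - r ** 2))
                pval = float(2 * sps.t.sf(abs(tstat), n - 2))
            pm[i, j] = pm[j, i] = pval
    return CorrelationMatrix(
        variables=list(variables),
        rho=pd.DataFrame(rho, index=variables, columns=variables),
        p=pd.DataFrame(pm, index=variables, columns=variables),
        n=pd.DataFrame(nm, index=variables, columns=variables),
    )
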