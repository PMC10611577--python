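"""Inferential layer: correlations, t-tests, ICC, and Baron–Kenny mediation.

Conventions
-----------
* Every p-value's tail is an explicit ``alternative`` argument; nothing is
  inferred from the sign of an effect.
* Zero-variance inputs yield a *degenerate report* (flagged result with an
  infinite or zero statistic) for the t-tests, and an error where no
  meaningful report exists (correlations on constants).
* The Sobel statistic is the classical delta-method form
  ``a·b / sqrt(b²·SE_a² + a²·SE_b²)`` on unstandardized coefficients, with
  a two-tailed standard-normal p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError


# ---------------------------------------------------------------------------
# results containers


@dataclass
class CorrelationResult:
    r: float
    n: int
    t: float
    df: int
    p: float
    alternative: str
    degenerate: bool = False

    @property
    def p_two_tailed(self) -> float:
        return _tail_p(self.t, self.df, "two-sided")

    @property
    def p_one_tailed(self) -> float:
        side = "greater" if self.t >= 0 else "less"
        return _tail_p(self.t, self.df, side)


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean: float
    alternative: str
    degenerate: bool = False


@dataclass
class ICCResult:
    icc: float
    p: float
    degenerate: bool = False


@dataclass
class PathEstimate:
    """One regression path: unstandardized b, standardized beta, SE, t, p."""

    b: float
    beta: float
    se: float
    t: float
    p: float
    df: int


@dataclass
class MediationResult:
    path_a: PathEstimate
    path_b: PathEstimate
    path_c: PathEstimate
    path_c_prime: PathEstimate
    sobel_z: float
    sobel_p: float
    n: int
    boot_ci: tuple[float, float] | None = None

    @property
    def indirect_beta(self) -> float:
        return self.path_a.beta * self.path_b.beta


# ---------------------------------------------------------------------------
# helpers


def _tail_p(t: float, df: int, alternative: str) -> float:
    if alternative == "two-sided":
        return float(2.0 * sps.t.sf(abs(t), df))
    if alternative == "greater":
        return float(sps.t.sf(t, df))
    if alternative == "less":
        return float(sps.t.cdf(t, df))
    raise ValueError(f"unknown alternative {alternative!r}")


def _check_finite(*arrays) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite values in input")


# ---------------------------------------------------------------------------
# correlations and t-tests


def pearson(x, y, alternative: str = "two-sided") -> CorrelationResult:
    """Pearson correlation with exact t conversion: t = r·sqrt(n-2)/sqrt(1-r²)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    _check_finite(x, y)
    if x.std() == 0 or y.std() == 0:
        raise DegenerateDataError("zero-variance input to correlation")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0 - 1e-12:
        t = np.inf if r > 0 else -np.inf
        p = 0.0
        return CorrelationResult(r, n, t, df, p, alternative, degenerate=True)
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    return CorrelationResult(r, n, float(t), df, _tail_p(t, df, alternative), alternative)


def one_sample_t(x, null_value: float = 0.0, alternative: str = "two-sided") -> TTestResult:
    """One-sample t-test of mean(x) against ``null_value``."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    _check_finite(x)
    n = x.size
    df = n - 1
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        if mean == null_value:
            return TTestResult(0.0, df, 1.0 if alternative == "two-sided" else 0.5,
                               mean, alternative, degenerate=True)
        t = np.inf if mean > null_value else -np.inf
        return TTestResult(t, df, _tail_p(t, df, alternative), mean, alternative, degenerate=True)
    t = (mean - null_value) / (sd / np.sqrt(n))
    return TTestResult(float(t), df, _tail_p(t, df, alternative), mean, alternative)


def paired_t(x_pre, x_post, alternative: str = "two-sided") -> TTestResult:
    """Paired t-test on ``x_pre - x_post`` differences (df = n - 1)."""
    x_pre = np.asarray(x_pre, dtype=float)
    x_post = np.asarray(x_post, dtype=float)
    if x_pre.shape != x_post.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(x_pre - x_post, 0.0, alternative)


# ---------------------------------------------------------------------------
# reliability


def icc_absolute_agreement(session1, session2) -> ICCResult:
    """Test–retest ICC: two-way model, single rater, absolute agreement.

    This is the ICC(A,1) of McGraw & Wong, whose value is identical under
    random- and mixed-effects assumptions; the F-test p-value comes with it.
    """
    s1 = np.asarray(session1, dtype=float)
    s2 = np.asarray(session2, dtype=float)
    if s1.shape != s2.shape or s1.ndim != 1:
        raise ValueError("sessions must be equal-length 1-D arrays")
    n = s1.size
    if n < 3:
        raise ValueError("need n >= 3 paired observations")
    _check_finite(s1, s2)
    both = np.concatenate([s1, s2])
    if np.std(both) == 0 or (np.std(s1) == 0 and np.std(s2) == 0):
        return ICCResult(np.nan, np.nan, degenerate=True)
    import pingouin as pg

    df = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "session": np.repeat([1, 2], n),
            "value": both,
        }
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # exact-agreement edge cases
        res = pg.intraclass_corr(df, targets="subject", raters="session", ratings="value")
    row = res[res["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
    return ICCResult(float(row["ICC"]), float(row["pval"]))


# ---------------------------------------------------------------------------
# mediation


def standardized_betas_from_corr(r_xy: float, r_xm: float, r_my: float, n: int):
    """Two-predictor standardized regression solved from a correlation matrix.

    For Y regressed on X and M with pairwise correlations r_xy (X,Y),
    r_xm (X,M), r_my (M,Y):

        beta_b  = (r_my - r_xy·r_xm) / (1 - r_xm²)      (M -> Y | X)
        beta_c' = (r_xy - r_my·r_xm) / (1 - r_xm²)      (X -> Y | M)
        SE      = sqrt((1 - R²) / ((1 - r_xm²)(n - 3)))

    Returns a dict with betas, shared SE, and t statistics.  Serves as a
    desk-scale cross-check of a full mediation fit from printed correlations.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    C = np.array([[1, r_xm, r_xy], [r_xm, 1, r_my], [r_xy, r_my, 1]], dtype=float)
    if np.linalg.eigvalsh(C).min() < -1e-10:
        raise ValueError("correlation matrix not positive semidefinite")
    if abs(r_xm) >= 1.0 - 1e-12:
        raise ValueError("predictors collinear: |r_xm| = 1")
    denom = 1.0 - r_xm**2
    beta_b = (r_my - r_xy * r_xm) / denom
    beta_c_prime = (r_xy - r_my * r_xm) / denom
    r_squared = beta_b * r_my + beta_c_prime * r_xy
    se = np.sqrt((1.0 - r_squared) / (denom * (n - 3)))
    return {
        "beta_b": float(beta_b),
        "beta_c_prime": float(beta_c_prime),
        "se": float(se),
        "t_b": float(beta_b / se),
        "t_c_prime": float(beta_c_prime / se),
        "r_squared": float(r_squared),
        "df": n - 3,
    }


def sobel_test(a: float, se_a: float, b: float, se_b: float) -> tuple[float, float]:
    """Classical Sobel z for the indirect effect a·b, with two-tailed normal p."""
    denom = np.sqrt(b**2 * se_a**2 + a**2 * se_b**2)
    if denom == 0:
        raise DegenerateDataError("zero standard errors in Sobel test")
    z = a * b / denom
    return float(z), float(2.0 * sps.norm.sf(abs(z)))


def _ols_path(y: np.ndarray, X: np.ndarray, col: int) -> tuple[float, float, float, float, int]:
    """OLS of y on [1, X]; returns (b, se, t, p, df) for column ``col`` of X."""
    n = y.size
    design = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise DegenerateDataError("collinear design in mediation regression")
    resid = y - design @ coef
    df = n - design.shape[1]
    if df <= 0:
        raise ValueError("not enough observations for the regression")
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(design.T @ design)
    j = col + 1  # skip intercept
    b = float(coef[j])
    se = float(np.sqrt(cov[j, j]))
    if se == 0:
        raise DegenerateDataError("degenerate variance in mediation regression")
    t = b / se
    return b, se, float(t), _tail_p(t, df, "two-sided"), df


def mediate(x, m, y, n_boot: int = 0, seed: int = 0) -> MediationResult:
    """Baron–Kenny mediation of X on Y through M, with the Sobel test.

    Fits the three OLS regressions
        c  : Y ~ X            (total effect)
        a  : M ~ X
        b,c': Y ~ X + M       (mediator effect and direct remainder)
    reporting unstandardized b, standardized beta, SE, t, and two-tailed p
    per path.  Standardized betas satisfy beta_c = beta_a·beta_b + beta_c'
    exactly.  ``n_boot > 0`` adds a percentile bootstrap CI for the
    unstandardized indirect effect a·b (off by default).
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (x.shape == m.shape == y.shape) or x.ndim != 1:
        raise ValueError("x, m, y must be equal-length 1-D arrays")
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4")
    _check_finite(x, m, y)
    for name, v in (("x", x), ("m", m), ("y", y)):
        if v.std() == 0:
            raise DegenerateDataError(f"zero variance in {name}")

    def z(v):
        return (v - v.mean()) / v.std(ddof=1)

    zx, zm, zy = z(x), z(m), z(y)

    def fit(dep, preds, zdep, zpreds, col) -> PathEstimate:
        b, se, t, p, df = _ols_path(dep, preds, col)
        beta, _, _, _, _ = _ols_path(zdep, zpreds, col)
        return PathEstimate(b=b, beta=beta, se=se, t=t, p=p, df=df)

    path_c = fit(y, x[:, None], zy, zx[:, None], 0)
    path_a = fit(m, x[:, None], zm, zx[:, None], 0)
    xm = np.column_stack([x, m])
    zxm = np.column_stack([zx, zm])
    path_c_prime = fit(y, xm, zy, zxm, 0)
    path_b = fit(y, xm, zy, zxm, 1)

    sobel_z, sobel_p = sobel_test(path_a.b, path_a.se, path_b.b, path_b.se)

    boot_ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        ab = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                a_i, *_ = _ols_path(m[idx], x[idx, None], 0)
                b_i, *_ = _ols_path(y[idx], np.column_stack([x[idx], m[idx]]), 1)
                ab[i] = a_i * b_i
            except (DegenerateDataError, np.linalg.LinAlgError):
                ab[i] = np.nan
        ab = ab[np.isfinite(ab)]
        boot_ci = (float(np.percentile(ab, 2.5)), float(np.percentile(ab, 97.5)))

    return MediationResult(
        path_a=path_a,
        path_b=path_b,
        path_c=path_c,
        path_c_prime=path_c_prime,
        sobel_z=sobel_z,
        sobel_p=sobel_p,
        n=n,
        boot_ci=boot_ci,
    )
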