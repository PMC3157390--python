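"""Per-association tests: one-sided trend score test, Wald linear test,
odds ratios with confidence intervals, and the risk-report interaction
regression.

Binary traits use the score test for logistic regression of status on
risk-allele dosage with no covariates — the Cochran-Armitage trend test.
Quantitative traits use the Wald test from an ordinary least-squares fit of
the trait on dosage.  All p-values are one-sided in the direction of the
published effect.  A replication call uses p < 0.05; a weaker
"directional-only" call uses p < 0.5 (correct sign of the estimate).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm

__all__ = [
    "TestResult",
    "ReplicationCall",
    "trend_z_from_table",
    "trend_score_test",
    "wald_linear_test",
    "or_with_ci",
    "classify_replication",
    "interaction_risk_report_test",
    "UntestableError",
]

_MIN_P = float(np.nextafter(0, 1))


class UntestableError(ValueError):
    """Raised when an association cannot be tested in the cohort
    (monomorphic genotype, empty group, degenerate design)."""


@dataclass(frozen=True)
class TestResult:
    association_id: str
    statistic: float
    p_one_sided: float
    direction_published: str
    n_cases: int | None = None
    n_controls: int | None = None
    n: int | None = None
    effect_estimate: float | None = None
    ci95: tuple[float, float] | None = None
    separated: bool = False


@dataclass(frozen=True)
class ReplicationCall:
    status: str  # replicated | directional_only | not_replicated
    alpha_rep: float = 0.05
    alpha_dir: float = 0.5


def _one_sided_p(z: float, direction: str) -> float:
    if direction == "+":
        p = norm.sf(z)
    elif direction == "-":
        p = norm.cdf(z)
    else:
        raise ValueError("direction must be '+' or '-'")
    return float(min(max(p, _MIN_P), 1.0 - 1e-16))


def trend_z_from_table(case_counts, control_counts):
    """Signed trend (score) z from 2x3 genotype count tables.

    Accepts arrays with trailing dimension 3 (counts at dosage 0/1/2) and
    broadcasts over leading dimensions.  The sign is that of
    mean(case dosage) - mean(control dosage); under the null the statistic
    is asymptotically standard normal.
    """
    r = np.asarray(case_counts, dtype=float)
    s = np.asarray(control_counts, dtype=float)
    g = np.arange(3.0)
    nr = r.sum(axis=-1)
    ns = s.sum(axis=-1)
    n = nr + ns
    tot = r + s
    mean_all = (tot * g).sum(axis=-1) / n
    var_all = (tot * g * g).sum(axis=-1) / n - mean_all**2
    mu1 = (r * g).sum(axis=-1) / nr
    mu0 = (s * g).sum(axis=-1) / ns
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (mu1 - mu0) / np.sqrt(var_all * (1.0 / nr + 1.0 / ns))
    return z


def _counts_by_dosage(dosage: np.ndarray) -> np.ndarray:
    return np.bincount(dosage.astype(int), minlength=3)[:3]


def _clean_pair(genotypes, status):
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(status, dtype=float)
    keep = ~np.isnan(g) & ~np.isnan(y)
    return g[keep], y[keep]


def trend_score_test(genotypes, status, direction: str, association_id: str = "") -> TestResult:
    """One-sided Cochran-Armitage trend test of binary status on dosage.

    ``genotypes`` are risk-allele dosages in {0,1,2} (NaN = missing,
    dropped), ``status`` is 0/1.  The one-sided p is taken in the published
    direction: for direction '+', small p means cases carry more risk
    alleles than controls.
    """
    g, y = _clean_pair(genotypes, status)
    if not np.isin(g[~np.isnan(g)], [0, 1, 2]).all():
        raise ValueError("dosages must be 0, 1 or 2")
    n_cases = int((y == 1).sum())
    n_controls = int((y == 0).sum())
    if n_cases == 0 or n_controls == 0:
        raise UntestableError("need at least one case and one control")
    if np.ptp(g) == 0:
        raise UntestableError("genotype is constant")
    r = _counts_by_dosage(g[y == 1])
    s = _counts_by_dosage(g[y == 0])
    z = float(trend_z_from_table(r, s))
    return TestResult(
        association_id=association_id,
        statistic=z,
        p_one_sided=_one_sided_p(z, direction),
        direction_published=direction,
        n_cases=n_cases,
        n_controls=n_controls,
        n=n_cases + n_controls,
    )


def wald_linear_test(genotypes, trait, direction: str, association_id: str = "") -> TestResult:
    """One-sided Wald test of a quantitative trait regressed on dosage."""
    g, y = _clean_pair(genotypes, trait)
    if g.size < 3:
        raise UntestableError("need at least 3 observations")
    if np.ptp(g) == 0:
        raise UntestableError("genotype is constant")
    if np.ptp(y) == 0:
        raise UntestableError("trait is constant")
    fit = sm.OLS(y, sm.add_constant(g)).fit()
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if se == 0.0 or not math.isfinite(se):
        # perfect linear fit: decisive in the direction of the slope
        z = math.inf if beta > 0 else -math.inf
    else:
        z = beta / se
    lo, hi = beta - 1.96 * se, beta + 1.96 * se
    return TestResult(
        association_id=association_id,
        statistic=z,
        p_one_sided=_one_sided_p(z, direction),
        direction_published=direction,
        n=int(g.size),
        effect_estimate=beta,
        ci95=(lo, hi),
    )


def or_with_ci(genotypes, status, published_or: float | None = None):
    """Per-allele odds ratio with 95% Wald interval from a logistic fit.

    Returns ``(or_hat, (lo, hi), contains, separated)`` where ``contains``
    flags whether the interval covers ``published_or`` (None if not given).
    Complete separation yields an infinite-width interval and
    ``separated=True`` rather than an exception.
    """
    g, y = _clean_pair(genotypes, status)
    if np.ptp(g) == 0 or len(np.unique(y)) < 2:
        raise UntestableError("degenerate design for logistic fit")
    X = sm.add_constant(g)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        b = float(fit.params[1])
        se = float(fit.bse[1])
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception:
        converged, se, b = False, math.inf, math.nan
    if not converged or not math.isfinite(se) or se > 50:
        or_hat = math.exp(b) if math.isfinite(b) else math.nan
        return or_hat, (0.0, math.inf), None if published_or is None else True, True
    lo, hi = math.exp(b - 1.96 * se), math.exp(b + 1.96 * se)
    contains = None if published_or is None else (lo <= published_or <= hi)
    return math.exp(b), (lo, hi), contains, False


def classify_replication(result: TestResult, alpha_rep: float = 0.05, alpha_dir: float = 0.5) -> ReplicationCall:
    """Replicated (p < alpha_rep), directional-only (p < alpha_dir), or
    not replicated."""
    p = result.p_one_sided
    if p < alpha_rep:
        status = "replicated"
    elif p < alpha_dir:
        status = "directional_only"
    else:
        status = "not_replicated"
    return ReplicationCall(status=status, alpha_rep=alpha_rep, alpha_dir=alpha_dir)


def interaction_risk_report_test(status, predicted_risk, results_available, covariates) -> float:
    """Wald p-value for the (predicted risk) x (results available)
    interaction in a logistic regression of reported status.

    ``covariates`` is an (n, k) array/DataFrame of adjustment covariates
    (age, sex and ancestry principal components).  Tests whether having
    seen a personal risk estimate changes the relation between predicted
    risk and self-reported status.
    """
    y = np.asarray(status, dtype=float)
    risk = np.asarray(predicted_risk, dtype=float)
    avail = np.asarray(results_available, dtype=float)
    if np.ptp(avail) == 0:
        raise UntestableError("interaction inestimable: results_available is constant")
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    X = np.column_stack([risk, avail, risk * avail, cov])
    X = sm.add_constant(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    # columns: const, risk, avail, interaction, covariates...
    return float(fit.pvalues[3])
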