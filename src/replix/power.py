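"""Analytic power for the Cochran-Armitage trend test under phenotype misclassification.

The model follows the classical case-control power framework for trend
tests: genotype frequencies in the population come from Hardy-Weinberg
equilibrium at the risk-allele frequency, disease risk per genotype follows
a logit-additive (multiplicative-odds) per-allele odds-ratio model
constrained to a given population prevalence, and case/control genotype
distributions are obtained by Bayes' rule.  Two extensions are layered on
top:

* **Phenotype misclassification** — a fraction ``e_case`` of reported cases
  are actually controls and a fraction ``e_control`` of reported controls
  are (or will become) cases.  Observed group genotype distributions are the
  corresponding convex mixtures of the true case and control distributions,
  which attenuates the mean-dosage contrast and hence power.
* **Proxy dilution** — when a surrogate SNP in incomplete LD (squared
  correlation ``proxy_r2``) is tested instead of the reported SNP, both
  group sizes are scaled by ``proxy_r2``.

Power is the normal approximation for the trend (score) test on dosage
scores 0/1/2: the contrast is the difference in mean dosage between the
observed case and control distributions; the null standard error uses the
size-weighted pooled genotype distribution, the alternative standard error
uses the group-specific variances.

A winner's-curse adjustment for log-odds-ratio inflation in discovery
studies is provided as :func:`adjust_winners_curse`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "GenotypeModel",
    "PowerInput",
    "PowerResult",
    "genotype_distributions",
    "apply_misclassification",
    "power_trend_test",
    "effective_sample_size",
    "adjust_winners_curse",
    "hwe_genotype_freqs",
]

_DOSAGES = np.arange(3.0)


def hwe_genotype_freqs(raf: float) -> np.ndarray:
    """Hardy-Weinberg genotype frequencies (0, 1, 2 risk-allele copies)."""
    if not 0.0 < raf < 1.0:
        raise ValueError(f"risk-allele frequency must be in (0,1), got {raf}")
    q = raf
    return np.array([(1.0 - q) ** 2, 2.0 * q * (1.0 - q), q * q])


@dataclass(frozen=True)
class GenotypeModel:
    """Population genotype frequencies, penetrances and the implied
    case/control genotype distributions."""

    genotype_freqs: np.ndarray
    penetrances: np.ndarray
    case_dist: np.ndarray
    control_dist: np.ndarray

    def __post_init__(self) -> None:
        for name in ("genotype_freqs", "case_dist", "control_dist"):
            v = getattr(self, name)
            if abs(float(np.sum(v)) - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1 (got {np.sum(v)!r})")

    @property
    def prevalence(self) -> float:
        return float(np.dot(self.genotype_freqs, self.penetrances))


@dataclass(frozen=True)
class PowerInput:
    """Inputs for one misclassification-adjusted power calculation.

    ``e_control`` defaults to min(prevalence, 0.10): a reported control is a
    latent case with probability bounded by the disease prevalence, capped
    at 10%.  ``inflation`` deflates the published log-OR by 1/(1+inflation)
    before the calculation (winner's-curse correction); 0 disables it.
    """

    n_cases: int
    n_controls: int
    raf: float
    or_published: float
    prevalence: float
    alpha: float = 0.05
    sidedness: str = "one"
    e_case: float = 0.05
    e_control: float | None = None
    proxy_r2: float = 1.0
    inflation: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("group sizes must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")
        if self.sidedness not in ("one", "two"):
            raise ValueError("sidedness must be 'one' or 'two'")
        e_ctrl = self.resolved_e_control
        for name, e in (("e_case", self.e_case), ("e_control", e_ctrl)):
            if not 0.0 <= e < 0.5:
                raise ValueError(f"{name} must be in [0, 0.5), got {e}")
        if not 0.0 < self.proxy_r2 <= 1.0:
            raise ValueError("proxy_r2 must be in (0,1]")
        if self.inflation < 0.0:
            raise ValueError("inflation must be nonnegative")

    @property
    def resolved_e_control(self) -> float:
        if self.e_control is not None:
            return self.e_control
        return min(self.prevalence, 0.10)


@dataclass(frozen=True)
class PowerResult:
    power: float
    noncentrality: float
    effective_n_cases: float
    effective_n_controls: float


def genotype_distributions(raf: float, or_published: float, prevalence: float) -> GenotypeModel:
    """Solve the logit-additive penetrance model and return case/control
    genotype distributions.

    Genotype g has disease odds ``odds0 * OR**g``; the baseline odds0 is
    solved numerically so the population prevalence matches.  Case and
    control distributions follow by Bayes' rule.
    """
    if or_published <= 0.0:
        raise ValueError("odds ratio must be positive")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0,1)")
    f = hwe_genotype_freqs(raf)
    orr = float(or_published)

    def mean_pen(log_odds0: float) -> float:
        odds = math.exp(log_odds0) * orr ** _DOSAGES
        return float(np.dot(f, odds / (1.0 + odds))) - prevalence

    lo, hi = -40.0, 40.0
    if mean_pen(lo) > 0.0 or mean_pen(hi) < 0.0:  # pragma: no cover - extreme params
        raise ValueError("no baseline odds solves the prevalence constraint")
    log_odds0 = brentq(mean_pen, lo, hi, xtol=1e-14)
    odds = math.exp(log_odds0) * orr ** _DOSAGES
    pen = odds / (1.0 + odds)
    case = f * pen
    ctrl = f * (1.0 - pen)
    return GenotypeModel(
        genotype_freqs=f,
        penetrances=pen,
        case_dist=case / case.sum(),
        control_dist=ctrl / ctrl.sum(),
    )


def apply_misclassification(model: GenotypeModel, e_case: float, e_control: float) -> GenotypeModel:
    """Mix true case/control genotype distributions to reflect misreport.

    Observed cases are (1-e_case) true cases plus e_case true controls, and
    symmetrically for controls.  Genotype frequencies and penetrances are
    unchanged (they describe the population, not the reported groups).
    """
    for name, e in (("e_case", e_case), ("e_control", e_control)):
        if not 0.0 <= e < 0.5:
            raise ValueError(f"{name} must be in [0, 0.5), got {e}")
    case = (1.0 - e_case) * model.case_dist + e_case * model.control_dist
    ctrl = (1.0 - e_control) * model.control_dist + e_control * model.case_dist
    return GenotypeModel(
        genotype_freqs=model.genotype_freqs,
        penetrances=model.penetrances,
        case_dist=case,
        control_dist=ctrl,
    )


def effective_sample_size(n: float, proxy_r2: float) -> float:
    """Sample size scaled by the proxy's squared correlation with the
    reported SNP (n * r^2)."""
    if not 0.0 < proxy_r2 <= 1.0:
        raise ValueError("proxy_r2 must be in (0,1]")
    if n <= 0:
        raise ValueError("n must be positive")
    return n * proxy_r2


def adjust_winners_curse(log_or: float, inflation: float, mode: str = "deflate") -> float:
    """Winner's-curse adjustment on the log-odds-ratio scale.

    ``inflate`` maps a true log-OR to the expected discovery estimate,
    log_or * (1 + inflation); ``deflate`` inverts it.
    """
    if inflation < 0.0:
        raise ValueError("inflation must be nonnegative")
    if mode == "inflate":
        return log_or * (1.0 + inflation)
    if mode == "deflate":
        return log_or / (1.0 + inflation)
    raise ValueError("mode must be 'deflate' or 'inflate'")


def power_trend_test(inp: PowerInput) -> PowerResult:
    """Normal-approximation power of the trend test for one association.

    The published OR is optionally deflated for winner's curse, converted to
    observed case/control genotype distributions under the penetrance model,
    mixed for misclassification, and the group sizes scaled by the proxy
    r^2.  Power is evaluated in the direction of the (adjusted) published
    effect; for a two-sided alpha both rejection tails are summed, so the
    null power equals alpha under either sidedness.
    """
    log_or = adjust_winners_curse(math.log(inp.or_published), inp.inflation, "deflate")
    model = genotype_distributions(inp.raf, math.exp(log_or), inp.prevalence)
    model = apply_misclassification(model, inp.e_case, inp.resolved_e_control)

    r = effective_sample_size(inp.n_cases, inp.proxy_r2)
    s = effective_sample_size(inp.n_controls, inp.proxy_r2)

    mu1 = float(np.dot(_DOSAGES, model.case_dist))
    mu0 = float(np.dot(_DOSAGES, model.control_dist))
    v1 = float(np.dot(_DOSAGES**2, model.case_dist)) - mu1**2
    v0 = float(np.dot(_DOSAGES**2, model.control_dist)) - mu0**2

    pooled = (r * model.case_dist + s * model.control_dist) / (r + s)
    mup = float(np.dot(_DOSAGES, pooled))
    vp = float(np.dot(_DOSAGES**2, pooled)) - mup**2

    se_null = math.sqrt(vp * (1.0 / r + 1.0 / s))
    se_alt = math.sqrt(v1 / r + v0 / s)
    delta = mu1 - mu0  # sign of the adjusted published effect

    if inp.sidedness == "two":
        z_crit = norm.isf(inp.alpha / 2.0)
        power = float(
            norm.cdf((abs(delta) - z_crit * se_null) / se_alt)
            + norm.cdf((-abs(delta) - z_crit * se_null) / se_alt)
        )
    else:
        z_crit = norm.isf(inp.alpha)
        power = float(norm.cdf((abs(delta) - z_crit * se_null) / se_alt))

    return PowerResult(
        power=min(max(power, 0.0), 1.0),
        noncentrality=abs(delta) / se_alt,
        effective_n_cases=r,
        effective_n_controls=s,
    )
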