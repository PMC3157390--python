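"""Exact distribution of the replication count and observed-vs-expected summaries.

Each attempted replication is modelled as an independent Bernoulli trial
whose success probability is the analytic power for that association.  The
number of successes then follows a Poisson-binomial distribution, computed
exactly by the standard dynamic-programming recurrence

    f_i(k) = f_{i-1}(k) (1 - p_i) + f_{i-1}(k-1) p_i,   f_0 = point mass at 0.

A 95% prediction interval [L, U] takes the largest L with P(X < L) <= 2.5%
and the smallest U with P(X > U) <= 2.5%.  Summaries report the observed
count against the expected count (sum of powers) and the success ratio
observed/expected, with the interval mapped onto the ratio scale by
dividing the integer bounds by the expected count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .power import PowerInput, power_trend_test

__all__ = [
    "AssociationPower",
    "CountDistribution",
    "poisson_binomial_dp",
    "prediction_interval",
    "success_ratio_summary",
    "aggregate_by_class",
    "expected_directionality",
]


@dataclass(frozen=True)
class AssociationPower:
    """One association's contribution to the expectation accounting."""

    association_id: str
    power: float
    class_label: str = "all"
    observed: bool | None = None


@dataclass(frozen=True)
class CountDistribution:
    pmf: np.ndarray
    mean: float
    interval: tuple[int, int]


def poisson_binomial_dp(powers: Sequence[float]) -> np.ndarray:
    """Exact pmf of the number of successes among independent Bernoulli
    trials with probabilities ``powers``."""
    p = np.asarray(list(powers), dtype=float)
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValueError("success probabilities must lie in [0,1]")
    pmf = np.zeros(p.size + 1)
    pmf[0] = 1.0
    for i, pi in enumerate(p):
        # shift-and-mix; only entries 0..i+1 can be nonzero
        pmf[1 : i + 2] = pmf[1 : i + 2] * (1.0 - pi) + pmf[: i + 1] * pi
        pmf[0] *= 1.0 - pi
    return pmf


def prediction_interval(pmf: np.ndarray, coverage: float = 0.95) -> tuple[int, int]:
    """Equal-tail prediction interval on the support of ``pmf``.

    L is the largest integer with P(X < L) <= (1-coverage)/2 and U the
    smallest with P(X > U) <= (1-coverage)/2; both tails use weak
    inequalities, so the interval always covers at least ``coverage``.
    """
    pmf = np.asarray(pmf, dtype=float)
    tail = (1.0 - coverage) / 2.0
    cdf = np.cumsum(pmf)
    n = pmf.size - 1
    lower = 0
    for ell in range(n, 0, -1):
        if cdf[ell - 1] <= tail + 1e-12:
            lower = ell
            break
    upper = n
    for u in range(n + 1):
        if 1.0 - cdf[u] <= tail + 1e-12:
            upper = u
            break
    return lower, upper


def count_distribution(powers: Sequence[float], coverage: float = 0.95) -> CountDistribution:
    pmf = poisson_binomial_dp(powers)
    return CountDistribution(pmf=pmf, mean=float(np.sum(powers)), interval=prediction_interval(pmf, coverage))


def success_ratio_summary(
    powers: Sequence[AssociationPower] | Sequence[float],
    observed: int | None = None,
    coverage: float = 0.95,
) -> dict:
    """Observed-vs-expected summary for one set of associations.

    ``powers`` may be AssociationPower records (observed calls read from
    them unless ``observed`` overrides) or bare probabilities with an
    explicit observed count.
    """
    if powers and isinstance(powers[0], AssociationPower):
        ps = [a.power for a in powers]
        if observed is None:
            calls = [a.observed for a in powers]
            if any(c is None for c in calls):
                missing = [a.association_id for a, c in zip(powers, calls) if c is None]
                raise ValueError(f"observed call missing for: {missing}")
            observed = int(sum(calls))
    else:
        ps = [float(p) for p in powers]
        if observed is None:
            raise ValueError("observed count required with bare probabilities")

    dist = count_distribution(ps, coverage)
    expected = dist.mean
    lower, upper = dist.interval
    out = {
        "attempts": len(ps),
        "expected": expected,
        "observed": observed,
        "interval": (lower, upper),
        "inside_interval": lower <= observed <= upper,
    }
    if expected > 0:
        out["ratio"] = observed / expected
        out["ratio_interval"] = (lower / expected, upper / expected)
    else:
        out["ratio"] = float("nan")
        out["ratio_interval"] = (float("nan"), float("nan"))
        out["inside_interval"] = observed == 0
    return out


def aggregate_by_class(
    powers: Sequence[AssociationPower],
    exclude: Iterable[str] = (),
    coverage: float = 0.95,
) -> pd.DataFrame:
    """Per-class and overall observed-vs-expected summaries.

    ``exclude`` removes associations (e.g. ones with known conflicting
    published evidence) from both the observed and expected sides before
    summarising.
    """
    excl = set(exclude)
    kept = [a for a in powers if a.association_id not in excl]
    unassigned = [a.association_id for a in kept if not a.class_label]
    if unassigned:
        raise ValueError(f"associations without a class label: {unassigned}")
    rows = []
    by_class: dict[str, list[AssociationPower]] = {}
    for a in kept:
        by_class.setdefault(a.class_label, []).append(a)
    for label in sorted(by_class):
        rows.append((label, success_ratio_summary(by_class[label], coverage=coverage)))
    rows.append(("overall", success_ratio_summary(kept, coverage=coverage)))
    records = []
    for label, s in rows:
        records.append(
            {
                "class": label,
                "attempts": s["attempts"],
                "expected": s["expected"],
                "observed": s["observed"],
                "ratio": s["ratio"],
                "ratio_lo": s["ratio_interval"][0],
                "ratio_hi": s["ratio_interval"][1],
                "inside_interval": s["inside_interval"],
            }
        )
    return pd.DataFrame.from_records(records)


def expected_directionality(
    power_inputs: Mapping[str, PowerInput],
    observed_directional: int | None = None,
    coverage: float = 0.95,
) -> dict:
    """Expectation accounting for correct effect direction among
    non-replicated associations.

    Each association's success probability is its power recomputed at a
    one-sided alpha of 0.5 — the probability that the cohort estimate
    merely lands on the published side of zero.  ``power_inputs`` should be
    restricted to the associations that did not replicate.
    """
    from dataclasses import replace

    ps = []
    for aid, inp in power_inputs.items():
        res = power_trend_test(replace(inp, alpha=0.5, sidedness="one"))
        ps.append(AssociationPower(association_id=aid, power=res.power))
    if observed_directional is None:
        dist = count_distribution([a.power for a in ps], coverage)
        return {
            "attempts": len(ps),
            "expected": dist.mean,
            "interval": dist.interval,
            "powers": {a.association_id: a.power for a in ps},
        }
    return success_ratio_summary(ps, observed=observed_directional, coverage=coverage)
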