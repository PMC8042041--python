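"""Approximate power of the IVW-style MR test for a binary outcome.

Uses the standard two-sided normal (noncentrality) approximation: the IVW
z-statistic for a causal log-odds effect theta, instruments explaining a
fraction r^2 of exposure variance, and an outcome GWAS of n individuals with
case fraction phi has noncentrality

    ncp = theta * sqrt(n * r^2 * phi * (1 - phi))

and power  Phi(-z_{1-a/2} + |ncp|) + Phi(-z_{1-a/2} - |ncp|).

This is an approximation: it ignores weak-instrument bias, pleiotropy and
winner's curse, and treats instrument strength as known.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .errors import ParameterError


@dataclass
class PowerResult:
    power: float
    alpha: float
    n_outcome: int
    case_fraction: float
    r2_instrument: float
    theta: float


def mr_power(
    theta: float,
    r2_instrument: float,
    n_outcome: int,
    case_fraction: float,
    alpha: float = 0.05,
) -> PowerResult:
    """Two-sided power of the MR test at significance level ``alpha``.

    ``power == alpha`` exactly at ``theta == 0`` and is monotone
    non-decreasing in |theta|, n_outcome and r2_instrument.
    """
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    if not 0 < case_fraction < 1:
        raise ParameterError(f"case_fraction must be in (0, 1), got {case_fraction}")
    if not 0 <= r2_instrument <= 1:
        raise ParameterError(f"r2_instrument must be in [0, 1], got {r2_instrument}")
    if n_outcome < 1:
        raise ParameterError(f"n_outcome must be >= 1, got {n_outcome}")
    z = stats.norm.isf(alpha / 2)
    ncp = abs(theta) * (n_outcome * r2_instrument * case_fraction * (1 - case_fraction)) ** 0.5
    power = float(stats.norm.cdf(-z + ncp) + stats.norm.cdf(-z - ncp))
    return PowerResult(
        power=power,
        alpha=alpha,
        n_outcome=int(n_outcome),
        case_fraction=case_fraction,
        r2_instrument=r2_instrument,
        theta=theta,
    )
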