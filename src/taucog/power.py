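"""Simulated-intervention power analysis.

An intervention is simulated by attenuating every subject's annual change
by a fraction f (multiplying by 1−f). The effect size between actual and
attenuated change vectors is a two-sample Cohen's d with pooled SD, and
the required per-arm sample size is the smallest integer n whose
two-sample two-tailed t-test (df = 2n−2, noncentrality |d|·sqrt(n/2))
reaches the target power at the given alpha, evaluated on the noncentral-t
distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ATTENUATIONS = (0.20, 0.30, 0.40)


class DegenerateEndpointError(ValueError):
    """Effect size (numerically) zero: required n is unbounded."""


def attenuate(changes: np.ndarray, f: float) -> np.ndarray:
    """Multiply every change by (1 − f); requires 0 <= f < 1."""
    if not (0.0 <= f < 1.0):
        raise ValueError(f"attenuation fraction must lie in [0, 1), got {f}")
    return (1.0 - f) * np.asarray(changes, dtype=float)


def cohens_d_two_sample(x: np.ndarray, y: np.ndarray) -> float:
    """(mean(x) − mean(y)) / pooled SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs length >= 2")
    n1, n2 = x.size, y.size
    pooled = math.sqrt(
        ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    )
    if pooled == 0.0:
        raise ZeroDivisionError("pooled SD is zero; d undefined")
    return float((x.mean() - y.mean()) / pooled)


def power_two_sample_t(d: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-tailed two-sample t-test at per-arm size n."""
    df = 2 * n - 2
    if df < 1:
        return 0.0
    nc = abs(d) * math.sqrt(n / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def n_per_arm(
    d: float, alpha: float = 0.05, power: float = 0.80, max_n: int = 10_000_000
) -> int:
    """Smallest per-arm n (>= 2) reaching the target power.

    Starts from the normal-approximation solution and verifies the exact
    noncentral-t power at n and n−1.
    """
    if d == 0.0 or not np.isfinite(d):
        raise DegenerateEndpointError("effect size is zero; required n is unbounded")
    za = stats.norm.ppf(1.0 - alpha / 2.0)
    zb = stats.norm.ppf(power)
    n = max(2, int(math.floor(2.0 * ((za + zb) / abs(d)) ** 2)) - 2)
    while n < max_n and power_two_sample_t(d, n, alpha) < power:
        n += 1
    if n >= max_n:
        raise DegenerateEndpointError("required n exceeds the search bound")
    while n > 2 and power_two_sample_t(d, n - 1, alpha) >= power:
        n -= 1
    return n


@dataclass
class PowerResult:
    endpoint: str
    attenuation: float
    effect_size: float | None
    n_per_arm: int | None
    detectable: bool = True


def power_table(
    endpoints: dict,
    attenuations=DEFAULT_ATTENUATIONS,
    alpha: float = 0.05,
    power: float = 0.80,
) -> pd.DataFrame:
    """Required per-arm n for every endpoint x attenuation.

    `endpoints` maps endpoint name -> vector of actual annual changes for
    the same subjects. Cells whose effect size is degenerate (zero-mean
    change) are marked not detectable rather than aborting the table.
    """
    rows = []
    for name, x in endpoints.items():
        x = np.asarray(x, dtype=float)
        for f in attenuations:
            y = attenuate(x, f)
            try:
                d = cohens_d_two_sample(x, y)
                n = n_per_arm(d, alpha=alpha, power=power)
                rows.append(PowerResult(name, f, d, n, True))
            except (DegenerateEndpointError, ZeroDivisionError):
                rows.append(PowerResult(name, f, None, None, False))
    return pd.DataFrame(
        {
            "endpoint": [r.endpoint for r in rows],
            "attenuation": [r.attenuation for r in rows],
            "effect_size": [r.effect_size for r in rows],
            "n_per_arm": [r.n_per_arm for r in rows],
            "detectable": [r.detectable for r in rows],
        }
    )
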