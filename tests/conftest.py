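"""Shared fixtures and independent oracles.

The oracles here are deliberately naive (plain-Python loops, explicit
formulas) so they stay independent of the vectorised implementations they
check.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence

import numpy as np
import pytest

from phqtraj.cohort import VisitRecord


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def ccf_oracle(x: Sequence[float], y: Sequence[float], k: int) -> float:
    """Direct-summation sample cross-covariance (plain loops)."""
    n = len(x)
    xbar = sum(x) / n
    ybar = sum(y) / n
    if k >= 0:
        return sum((x[t + k] - xbar) * (y[t] - ybar) for t in range(n - k)) / (n - k)
    m = -k
    return sum((x[t] - xbar) * (y[t + m] - ybar) for t in range(n - m)) / (n - m)


def rho_oracle(x: Sequence[float], y: Sequence[float], k: int) -> float:
    n = len(x)
    xbar = sum(x) / n
    ybar = sum(y) / n
    sx = math.sqrt(sum((v - xbar) ** 2 for v in x) / n)
    sy = math.sqrt(sum((v - ybar) ** 2 for v in y) / n)
    return ccf_oracle(x, y, k) / (sx * sy)


def sliding_window_oracle(biweeks: Sequence[int], min_visits: int, window: int) -> bool:
    """Exhaustive inclusion-rule check over every possible window start."""
    if not biweeks:
        return False
    for start in range(0, max(biweeks) + 1):
        if sum(1 for b in biweeks if start <= b < start + window) >= min_visits:
            return True
    return False


def pattern_oracle(series: Sequence[tuple], d: int) -> str:
    """Exhaustive consecutive-pair pattern scan on (phq8_total, item9) tuples."""
    a = b = False
    for (p0, i0), (p1, i1) in zip(series, series[1:]):
        if p1 - p0 >= d and i1 - i0 <= -1:
            a = True
        if p1 - p0 <= -d and i1 - i0 >= 1:
            b = True
    return {(True, True): "both", (True, False): "a_only", (False, True): "b_only", (False, False): "none"}[(a, b)]


def gp_posterior_oracle(t_train, y_train, t_test, length_scale, signal_var, noise_var):
    """Closed-form GP posterior mean by direct matrix algebra (prior mean =
    training mean, squared-exponential kernel)."""
    t_train = np.asarray(t_train, float)
    t_test = np.asarray(t_test, float)
    y = np.asarray(y_train, float)
    ybar = y.mean()

    def k(a, b):
        return signal_var * np.exp(-((a[:, None] - b[None, :]) ** 2) / (2 * length_scale**2))

    K = k(t_train, t_train) + noise_var * np.eye(len(t_train))
    Ks = k(t_test, t_train)
    return ybar + Ks @ np.linalg.solve(K, y - ybar)


def gp_loglik_oracle(t, y, length_scale, signal_var, noise_var):
    """Closed-form GP marginal log-likelihood of centered data."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    yc = y - y.mean()
    K = signal_var * np.exp(-((t[:, None] - t[None, :]) ** 2) / (2 * length_scale**2))
    K = K + noise_var * np.eye(len(t))
    sign, logdet = np.linalg.slogdet(K)
    return float(-0.5 * yc @ np.linalg.solve(K, yc) - 0.5 * logdet - 0.5 * len(t) * np.log(2 * np.pi))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_visit(pid: str, t_days: int, phq8_total: int, item9: int) -> VisitRecord:
    q, r = divmod(phq8_total, 8)
    items = tuple([q + 1] * r + [q] * (8 - r)) + (item9,)
    return VisitRecord(pid, t_days, items)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
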