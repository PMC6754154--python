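"""Sample cross-correlation between fitted PHQ-8 and Item-9 trajectories.

For two series :math:`x_t, y_t` sampled on the common biweekly grid, the
sample cross-covariance at lag :math:`k \\ge 0` is

.. math::

    \\hat\\gamma_{xy}(k) = \\frac{1}{N-k} \\sum_{t=1}^{N-k}
        (x_{t+k} - \\bar x)(y_t - \\bar y),

mirrored for :math:`k < 0`, with full-series means and the :math:`1/(N-|k|)`
normalisation implemented exactly as written.  The CCF is
:math:`\\hat\\rho_{xy}(k) = \\hat\\gamma_{xy}(k) / (\\hat\\sigma_x \\hat\\sigma_y)`
with :math:`\\hat\\sigma` the 1/N-convention sample deviations, so that
:math:`\\hat\\rho(0) = 1` for identical series.  (Because :math:`\\hat\\gamma`
divides by :math:`N-|k|` while :math:`\\hat\\sigma` divides by :math:`N`,
:math:`|\\hat\\rho|` may exceed 1 by a sliver at large :math:`|k|`; a 1e-9
slack is tolerated.)

With :math:`x` = PHQ-8 and :math:`y` = Item 9, a *positive* lag at maximum
CCF means Item 9 leads PHQ-8 — suicidal ideation changes before overall
severity does — and lag 0 means the two move in synchrony.

Patients whose fitted Item-9 (or PHQ-8) series is constant have an
identically-zero CCF; such profiles are flagged *degenerate* and excluded
from population lag summaries, mirroring the exclusion of flat-ideation
patients in this kind of analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CcfProfile",
    "sample_cross_covariance",
    "sample_ccf",
    "lag_at_max",
    "population_lag_summary",
    "DEFAULT_LAGS",
]

DEFAULT_LAGS: Tuple[int, ...] = tuple(range(-5, 6))
_DEGENERATE_TOL = 1e-12


def sample_cross_covariance(x: Sequence[float], y: Sequence[float], k: int) -> float:
    """Sample cross-covariance :math:`\\hat\\gamma_{xy}(k)` at integer lag ``k``.

    Requires ``len(x) == len(y) == N > |k|``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    k = int(k)
    if n <= abs(k):
        raise ValueError(f"need N > |k| (N={n}, k={k})")
    xc = x - x.mean()
    yc = y - y.mean()
    if k >= 0:
        return float(np.dot(xc[k:], yc[: n - k]) / (n - k))
    m = -k
    return float(np.dot(xc[: n - m], yc[m:]) / (n - m))


@dataclass
class CcfProfile:
    """CCF of one patient over a symmetric lag window (units: biweeks)."""

    patient_id: str
    lags: Tuple[int, ...]
    rho: np.ndarray
    lag_at_max: Optional[int]
    degenerate: bool

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho.shape != (len(self.lags),):
            raise ValueError("rho must have one value per lag")
        # The printed estimator divides gamma by N-|k| but sigma by N, so
        # |rho(k)| is bounded by N/(N-|k|) (Cauchy-Schwarz on the truncated
        # sum), not by 1; for the 20-point grid and |k| <= 5 that is 4/3.
        if np.any(np.abs(self.rho) > 1.5):
            raise ValueError("|rho| exceeds any value the estimator can produce")
        if (self.lag_at_max is None) != self.degenerate:
            raise ValueError("lag_at_max is null iff the profile is degenerate")

    def rho_at(self, k: int) -> float:
        return float(self.rho[self.lags.index(k)])


def _pick_lag(lags: Sequence[int], rho: np.ndarray) -> int:
    """Argmax lag; ties (within 1e-12) break to smallest |k|, then negative k."""
    top = rho.max()
    candidates = [k for k, r in zip(lags, rho) if r >= top - 1e-12]
    return min(candidates, key=lambda k: (abs(k), k))


def sample_ccf(
    x: Sequence[float],
    y: Sequence[float],
    lags: Sequence[int] = DEFAULT_LAGS,
    patient_id: str = "",
) -> CcfProfile:
    """Full CCF profile of one series pair over ``lags``.

    If either series has zero sample deviation the profile is degenerate:
    ``rho`` is identically zero and ``lag_at_max`` is ``None``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lags = tuple(int(k) for k in lags)
    sx = float(np.sqrt(np.mean((x - x.mean()) ** 2)))
    sy = float(np.sqrt(np.mean((y - y.mean()) ** 2)))
    if sx * sy < _DEGENERATE_TOL:
        return CcfProfile(patient_id, lags, np.zeros(len(lags)), None, True)
    rho = np.array([sample_cross_covariance(x, y, k) / (sx * sy) for k in lags])
    if np.all(np.abs(rho) < _DEGENERATE_TOL):
        return CcfProfile(patient_id, lags, np.zeros(len(lags)), None, True)
    return CcfProfile(patient_id, lags, rho, _pick_lag(lags, rho), False)


def lag_at_max(profile: CcfProfile) -> Optional[int]:
    """Lag at which the CCF attains its maximum (``None`` when degenerate)."""
    if profile.degenerate:
        return None
    return _pick_lag(profile.lags, profile.rho)


def population_lag_summary(profiles: Sequence[CcfProfile]) -> Dict[str, object]:
    """Histogram of lag-at-maximum over the non-degenerate profiles.

    Returns ``histogram`` (lag -> count over non-degenerate profiles only)
    plus ``n_total``, ``n_degenerate``, ``n_lag0`` and ``fraction_lag0`` (the
    share of non-degenerate patients whose two measures move in synchrony;
    ``None`` when every profile is degenerate).
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    histogram: Dict[int, int] = {}
    n_degenerate = 0
    for p in profiles:
        if p.degenerate:
            n_degenerate += 1
            continue
        histogram[p.lag_at_max] = histogram.get(p.lag_at_max, 0) + 1
    n_total = len(profiles)
    n_nondeg = n_total - n_degenerate
    n_lag0 = histogram.get(0, 0)
    return {
        "histogram": dict(sorted(histogram.items())),
        "n_total": n_total,
        "n_degenerate": n_degenerate,
        "n_lag0": n_lag0,
        "fraction_lag0": (n_lag0 / n_nondeg) if n_nondeg else None,
    }
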