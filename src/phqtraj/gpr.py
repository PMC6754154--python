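"""Gaussian-process continuization of irregular PHQ series.

Each patient's irregular observations of one measure (the 0-24 PHQ-8 total or
the 0-3 Item 9) are fitted with GP regression — squared-exponential kernel
plus i.i.d. Gaussian observation noise — and the posterior mean/sd is read
off on a fixed biweekly grid of 20 points (weeks 0, 2, ..., 38, anchored at
the patient's first visit).  Hyperparameters are chosen once per measure by a
grid search maximising the mean per-patient marginal log-likelihood.

Two deliberate numerical choices:

* the GP prior mean is the patient's own observation mean (data are centered
  before fitting and the mean is added back).  A patient whose observations
  are all identical therefore gets an *exactly* constant posterior mean,
  which downstream makes their cross-correlation profile exactly degenerate
  rather than numerically-almost-flat;
* posterior means are clipped to the legal score range of the measure after
  prediction (the GP is unconstrained, the scores are bounded).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel

from phqtraj.cohort import ConfigurationError, VisitRecord

__all__ = [
    "GprSettings",
    "Hyperparams",
    "FittedTrajectory",
    "UnfittablePatientError",
    "default_settings",
    "patient_series",
    "grid_search_hyperparams",
    "fit_patient",
    "fit_cohort",
]

logger = logging.getLogger(__name__)

SCORE_RANGE = {"phq8": (0.0, 24.0), "item9": (0.0, 3.0)}


@dataclass(frozen=True)
class Hyperparams:
    length_scale_weeks: float
    signal_variance: float
    noise_variance: float


@dataclass(frozen=True)
class GprSettings:
    """Hyperparameter search grid for one measure.

    The two measures live on different scales (0-24 vs 0-3), so each gets its
    own variance grid; length-scales span sub-visit to full-horizon
    smoothness for both.
    """

    measure: str
    kernel_family: str = "rbf+white"
    length_scale_weeks: Tuple[float, ...] = (2.0, 4.0, 8.0, 16.0, 32.0)
    signal_variance: Tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    noise_variance: Tuple[float, ...] = (0.1, 0.5, 1.0, 2.0)

    def __post_init__(self) -> None:
        if self.measure not in SCORE_RANGE:
            raise ConfigurationError(f"measure must be one of {sorted(SCORE_RANGE)}")
        if self.kernel_family != "rbf+white":
            raise ConfigurationError("only the 'rbf+white' kernel family is implemented")
        for name in ("length_scale_weeks", "signal_variance", "noise_variance"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ConfigurationError(f"empty candidate grid for {name}")
            if any(v <= 0 for v in vals):
                raise ConfigurationError(f"all {name} candidates must be > 0")

    def grid(self) -> List[Hyperparams]:
        """Candidate points in deterministic (length-scale, signal, noise) order."""
        return [
            Hyperparams(ls, sv, nv)
            for ls, sv, nv in itertools.product(
                self.length_scale_weeks, self.signal_variance, self.noise_variance
            )
        ]


def default_settings(measure: str) -> GprSettings:
    """Per-measure default grids (variances in squared score units of the measure)."""
    if measure == "phq8":
        return GprSettings(
            measure="phq8",
            signal_variance=(4.0, 9.0, 16.0, 36.0),
            noise_variance=(0.25, 1.0, 4.0),
        )
    return GprSettings(
        measure="item9",
        signal_variance=(0.25, 0.5, 1.0, 2.0),
        noise_variance=(0.05, 0.1, 0.25, 0.5),
    )


@dataclass
class FittedTrajectory:
    """GP posterior of one measure for one patient on the biweekly grid."""

    patient_id: str
    measure: str
    grid_weeks: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    loglik: float

    def __post_init__(self) -> None:
        self.grid_weeks = np.asarray(self.grid_weeks, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (self.grid_weeks.shape == self.mean.shape == self.sd.shape):
            raise ValueError("grid, mean and sd must share one shape")
        if np.any(self.sd < 0):
            raise ValueError("posterior sd must be nonnegative")


class UnfittablePatientError(ValueError):
    """Patient has too few observations of the measure to fit a GP."""


def patient_series(
    records: Sequence[VisitRecord], measure: str
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Per-patient (weeks-since-first-visit, value) series for one measure.

    Times are anchored at each patient's first visit so the biweekly grid is
    patient-relative, matching the way the observation window is defined.
    """
    if measure not in SCORE_RANGE:
        raise ConfigurationError(f"measure must be one of {sorted(SCORE_RANGE)}")
    by_patient: Dict[str, List[Tuple[int, float]]] = {}
    for rec in records:
        val = float(rec.phq8_total if measure == "phq8" else rec.item9)
        by_patient.setdefault(rec.patient_id, []).append((rec.t_days, val))
    out = {}
    for pid, pts in by_patient.items():
        pts.sort()
        t0 = pts[0][0]
        t = np.array([(d - t0) / 7.0 for d, _ in pts], dtype=float)
        y = np.array([v for _, v in pts], dtype=float)
        out[pid] = (t, y)
    return out


def _make_gp(hp: Hyperparams) -> GaussianProcessRegressor:
    kernel = ConstantKernel(hp.signal_variance, "fixed") * RBF(hp.length_scale_weeks, "fixed")
    # Observation noise enters as alpha (= white-noise variance on the
    # diagonal), so predicted sd refers to the latent curve, not to a new
    # noisy observation.
    return GaussianProcessRegressor(kernel=kernel, alpha=hp.noise_variance, optimizer=None)


def _marginal_loglik(t: np.ndarray, y: np.ndarray, hp: Hyperparams) -> float:
    gp = _make_gp(hp)
    gp.fit(t[:, None], y - y.mean())
    return float(gp.log_marginal_likelihood_value_)


def grid_search_hyperparams(
    observations: Dict[str, Tuple[np.ndarray, np.ndarray]],
    settings: GprSettings,
    max_patients: int | None = None,
) -> Hyperparams:
    """Pick the grid point maximising the mean per-patient marginal log-likelihood.

    ``max_patients`` caps the number of series entering the search (first in
    sorted patient order, deterministic): the hyperparameters are population
    -level, and the mean marginal likelihood stabilises with a few dozen
    patients, so large cohorts need not pay the full grid x cohort cost.

    Patients with fewer than two observations are ignored, as are constant
    series: their likelihood is maximised by the smallest total variance on
    offer regardless of smoothness, so the (many) all-zero Item-9 series
    would otherwise dominate the selection while carrying no information
    about it.  Ties break to the earlier point in grid order; the search is
    fully deterministic.
    """
    usable = {pid: (t, y) for pid, (t, y) in observations.items() if len(y) >= 2}
    if not usable:
        raise ConfigurationError("need at least one patient with >= 2 observations")
    informative = {pid: (t, y) for pid, (t, y) in usable.items() if float(np.std(y)) > 0}
    if informative:
        usable = informative
    if max_patients is not None and len(usable) > max_patients:
        usable = {pid: usable[pid] for pid in sorted(usable)[:max_patients]}
    grid = settings.grid()
    best_hp, best_mean = None, -np.inf
    for hp in grid:
        mean_ll = float(np.mean([_marginal_loglik(t, y, hp) for t, y in usable.values()]))
        if mean_ll > best_mean:
            best_hp, best_mean = hp, mean_ll
    return best_hp


def fit_patient(
    times_weeks: np.ndarray,
    values: np.ndarray,
    hyperparams: Hyperparams,
    *,
    patient_id: str = "",
    measure: str = "phq8",
    horizon_weeks: int = 40,
    clip: bool = True,
) -> FittedTrajectory:
    """GP posterior of one patient's series on the biweekly grid.

    Raises :class:`UnfittablePatientError` below two observations.
    """
    t = np.asarray(times_weeks, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-d arrays of equal length")
    if len(y) < 2:
        raise UnfittablePatientError(
            f"patient {patient_id!r}: {len(y)} observation(s) of {measure}, need >= 2"
        )
    grid = np.arange(0.0, float(horizon_weeks), 2.0)

    ybar = y.mean()
    gp = _make_gp(hyperparams)
    gp.fit(t[:, None], y - ybar)
    mean, sd = gp.predict(grid[:, None], return_std=True)
    mean = mean + ybar
    if clip:
        lo, hi = SCORE_RANGE[measure]
        mean = np.clip(mean, lo, hi)
    return FittedTrajectory(
        patient_id=patient_id,
        measure=measure,
        grid_weeks=grid,
        mean=mean,
        sd=np.maximum(sd, 0.0),
        loglik=float(gp.log_marginal_likelihood_value_),
    )


def fit_cohort(
    records: Sequence[VisitRecord],
    measure: str,
    hyperparams: Hyperparams,
    *,
    horizon_weeks: int = 40,
    patient_ids: Iterable[str] | None = None,
) -> List[FittedTrajectory]:
    """Fit every (selected) patient; unfittable patients are skipped with a warning."""
    series = patient_series(records, measure)
    if patient_ids is not None:
        keep = set(patient_ids)
        series = {pid: s for pid, s in series.items() if pid in keep}
    fitted = []
    for pid, (t, y) in series.items():
        try:
            fitted.append(
                fit_patient(
                    t, y, hyperparams, patient_id=pid, measure=measure, horizon_weeks=horizon_weeks
                )
            )
        except UnfittablePatientError as exc:
            logger.warning("excluding unfittable patient: %s", exc)
    return fitted
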