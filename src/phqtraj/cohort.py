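"""Synthetic chronic-depression cohort generator.

Real longitudinal PHQ-9 EHR extracts for treated chronic depression are
access restricted, so every downstream stage of this package is exercised on
synthetic cohorts that reproduce the structure those stages assume:

* ~hundreds of patients, each with at least ``min_visits`` questionnaire
  administrations inside a 40-week (20 biweek) observation window;
* irregular inter-visit gaps (discretised gamma);
* a latent PHQ-8 severity curve per patient drawn from one of five trajectory
  classes (increasing, decreasing, stable, peak-then-decline, periodic);
* an Item-9 (suicidal ideation, 0-3) latent curve that is a rescaled,
  time-shifted copy of the PHQ-8 curve — the shift is the *planted* lead/lag
  recovered later by the cross-correlation stage — plus independent
  zero-masking to reproduce the heavy zero inflation of real Item-9 records;
* ordinal observation noise: scores are perturbed, rounded and clipped to the
  legal 0-3 item / 0-24 total ranges.

Every cohort comes with a :class:`GroundTruth` giving each patient's latent
class, planted lag and noiseless latent curves, so recovery can be scored
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np

__all__ = [
    "SimConfig",
    "VisitRecord",
    "Demographics",
    "PatientTruth",
    "GroundTruth",
    "TRAJECTORY_CLASSES",
    "generate_cohort",
    "plant_lagged_item9",
    "select_cohort",
]

TRAJECTORY_CLASSES = ("increasing", "decreasing", "stable", "peak_then_decline", "periodic")

#: Fixed demographic dictionaries (categories and sampling marginals).
DEMOGRAPHIC_CATEGORIES: Dict[str, Tuple[Tuple[str, float], ...]] = {
    "age_band": (("18-44", 0.38), ("45-64", 0.42), ("65+", 0.20)),
    "sex": (("F", 0.68), ("M", 0.32)),
    "race_eth": (("white", 0.60), ("black", 0.12), ("asian", 0.10), ("hispanic", 0.12), ("other", 0.06)),
    "charlson_band": (("0", 0.50), ("1-2", 0.35), ("3+", 0.15)),
}

MAX_ABS_LAG = 5  # biweeks; the lag window used throughout the pipeline
DAYS_PER_BIWEEK = 14


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic cohort.

    Parameters
    ----------
    n_patients:
        Cohort size.
    horizon_weeks:
        Observation window length; visits fall strictly inside it.  40 weeks
        = 20 biweekly reporting periods.
    min_visits:
        Minimum questionnaire administrations per patient (inclusion rule of
        the emulated study population).
    mean_gap_weeks, gap_dispersion:
        Mean and dispersion of the gamma distribution the inter-visit gaps
        are drawn from (dispersion = 1/shape; larger = more irregular).  The
        default mean of 2.5 weeks reflects the questionnaire's own two-week
        reporting window in a frequently monitored treatment population —
        the cadence the biweekly continuization grid presumes.
    class_mix:
        Probability of each latent trajectory class, in the order of
        :data:`TRAJECTORY_CLASSES`.
    lag_biweeks:
        Planted Item-9 lead (+) / lag (-) relative to PHQ-8, in biweeks.
        Positive means suicidal ideation changes *before* overall severity.
    item9_zero_prob:
        Probability that a patient is an ideation non-reporter (their whole
        Item-9 curve is masked to zero); the main source of zero inflation.
    noise_sd:
        SD of additive Gaussian observation noise, in units of the score the
        observation is reported on (0-24 for the PHQ-8 total, 0-3 for Item 9).
    seed:
        Generator seed; identical configs produce bit-identical cohorts.
    """

    n_patients: int
    horizon_weeks: int = 40
    min_visits: int = 6
    mean_gap_weeks: float = 2.5
    gap_dispersion: float = 0.5
    class_mix: Tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    lag_biweeks: int = 0
    item9_zero_prob: float = 0.3
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be a positive integer")
        if self.min_visits < 2:
            raise ConfigurationError("min_visits must be >= 2")
        mix = np.asarray(self.class_mix, dtype=float)
        if mix.size != len(TRAJECTORY_CLASSES) or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-12:
            raise ConfigurationError(
                f"class_mix must be {len(TRAJECTORY_CLASSES)} nonnegative probabilities summing to 1"
            )
        if not 0.0 <= self.item9_zero_prob <= 1.0:
            raise ConfigurationError("item9_zero_prob must lie in [0, 1]")
        if abs(self.lag_biweeks) > MAX_ABS_LAG:
            raise ConfigurationError(f"|lag_biweeks| must be <= {MAX_ABS_LAG}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.mean_gap_weeks <= 0 or self.gap_dispersion <= 0:
            raise ConfigurationError("visit gap parameters must be positive")


@dataclass(frozen=True)
class VisitRecord:
    """One questionnaire administration: time plus the nine item scores."""

    patient_id: str
    t_days: int
    items: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != 9:
            raise ValueError("a visit must carry exactly 9 item scores")
        if any((not 0 <= v <= 3) for v in self.items):
            raise ValueError(f"item scores must lie in 0..3, got {self.items}")
        if self.t_days < 0:
            raise ValueError("t_days must be nonnegative")

    @property
    def phq8_total(self) -> int:
        """Sum of items 1-8 (overall depression severity, 0-24)."""
        return int(sum(self.items[:8]))

    @property
    def item9(self) -> int:
        """Suicidal-ideation item (0-3)."""
        return int(self.items[8])


@dataclass(frozen=True)
class Demographics:
    patient_id: str
    age_band: str
    sex: str
    race_eth: str
    charlson_band: str


@dataclass
class PatientTruth:
    """Noiseless generating state for one synthetic patient."""

    patient_id: str
    latent_class: str
    lag_biweeks: int
    params: Dict[str, float]
    phq8_latent_grid: np.ndarray  # total scale, on the 20-point biweekly grid
    item9_latent_grid: np.ndarray  # 0-3 scale, unmasked
    phq8_fn: Callable[[np.ndarray], np.ndarray] = field(repr=False, default=None)
    item9_fn: Callable[[np.ndarray], np.ndarray] = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "latent_class": self.latent_class,
            "lag_biweeks": self.lag_biweeks,
            "params": {k: float(v) for k, v in self.params.items()},
            "phq8_latent_grid": [float(v) for v in self.phq8_latent_grid],
            "item9_latent_grid": [float(v) for v in self.item9_latent_grid],
        }


@dataclass
class GroundTruth:
    """Per-patient generating truth for a whole cohort."""

    config: SimConfig
    patients: Dict[str, PatientTruth]

    def to_dict(self) -> dict:
        cfg = self.config
        return {
            "config": {
                "n_patients": cfg.n_patients,
                "horizon_weeks": cfg.horizon_weeks,
                "min_visits": cfg.min_visits,
                "mean_gap_weeks": cfg.mean_gap_weeks,
                "gap_dispersion": cfg.gap_dispersion,
                "class_mix": list(cfg.class_mix),
                "lag_biweeks": cfg.lag_biweeks,
                "item9_zero_prob": cfg.item9_zero_prob,
                "noise_sd": cfg.noise_sd,
                "seed": cfg.seed,
            },
            "patients": {pid: pt.to_dict() for pid, pt in self.patients.items()},
        }


# ---------------------------------------------------------------------------
# Latent trajectory classes
# ---------------------------------------------------------------------------
# All latent curves are smooth functions of week defined on the whole real
# line (so the Item-9 time shift never needs edge handling) and take values
# inside the legal 0-24 total range by construction.  Shapes deliberately
# carry curvature: a time shift of a straight line is the same line, so a
# planted lag on a purely linear trend would be unrecoverable by any
# cross-correlation method.


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


#: Class mix used for lead/lag planting studies.  The sample CCF on a short
#: window identifies a displacement only when the trajectory has a localized
#: or oscillatory temporal feature; for monotone trends a shifted ramp is
#: nearly the same ramp, so the lag-at-maximum shrinks toward zero no matter
#: how the estimate is computed.  Lag-recovery experiments therefore draw
#: from the peaked and periodic classes, and the monotone classes are kept
#: for subtype studies (where only shape, not displacement, matters).
LAG_STUDY_CLASS_MIX: Tuple[float, ...] = (0.0, 0.0, 0.0, 0.5, 0.5)


def _draw_class_params(cls: str, rng: np.random.Generator) -> Dict[str, float]:
    if cls in ("increasing", "decreasing", "peak_then_decline"):
        p = {
            "base": rng.uniform(2.0, 6.0),
            "amp": rng.uniform(8.0, 14.0),
            "t0": rng.uniform(16.0, 24.0),
        }
        if cls == "peak_then_decline":
            p["width"] = rng.uniform(4.0, 7.0)
        else:
            p["scale"] = rng.uniform(2.0, 4.0)
        return p
    if cls == "stable":
        return {
            "level": rng.uniform(6.0, 16.0),
            "amp": rng.uniform(1.5, 2.5),
            "phase": rng.uniform(16.0, 24.0),
        }
    if cls == "periodic":
        return {
            "level": rng.uniform(8.0, 14.0),
            "amp": rng.uniform(4.0, 7.0),
            "period": rng.uniform(22.0, 30.0),
            "phase": rng.uniform(0.0, 6.0),
        }
    raise ValueError(f"unknown trajectory class {cls!r}")


def _latent_fn(cls: str, p: Dict[str, float]) -> Callable[[np.ndarray], np.ndarray]:
    """PHQ-8 total-scale latent curve (weeks -> score) for one patient.

    Within-class parameter jitter is moderate relative to the between-class
    shape differences — that is what makes the classes *subtypes* rather
    than a continuum, and what a clustering stage can be scored against.
    """
    if cls == "increasing":
        return lambda t: p["base"] + p["amp"] * _sigmoid((np.asarray(t, float) - p["t0"]) / p["scale"])
    if cls == "decreasing":
        return lambda t: p["base"] + p["amp"] * _sigmoid(-(np.asarray(t, float) - p["t0"]) / p["scale"])
    if cls == "stable":
        # shallow mid-window sag (~2-point swing over the whole window):
        # relative stability.  Oriented as a dip so that, after per-patient
        # normalisation, the class is not a broadened copy of the peak class.
        return lambda t: p["level"] - p["amp"] * np.cos(2 * np.pi * (np.asarray(t, float) - p["phase"]) / 80.0)
    if cls == "peak_then_decline":
        return lambda t: p["base"] + p["amp"] * np.exp(
            -((np.asarray(t, float) - p["t0"]) ** 2) / (2.0 * p["width"] ** 2)
        )
    if cls == "periodic":
        return lambda t: p["level"] + p["amp"] * np.sin(
            2 * np.pi * (np.asarray(t, float) - p["phase"]) / p["period"]
        )
    raise ValueError(f"unknown trajectory class {cls!r}")


def plant_lagged_item9(
    phq8_latent: Callable[[np.ndarray], np.ndarray],
    lag_biweeks: int,
    zero_prob: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Callable[[np.ndarray], np.ndarray]:
    """Derive an Item-9 latent curve from a PHQ-8 latent curve.

    The Item-9 curve at week *t* is the PHQ-8 curve at week
    ``t + 2 * lag_biweeks``, rescaled from the 0-24 total to the 0-3 item
    range.  Positive ``lag_biweeks`` therefore makes Item 9 *lead* PHQ-8:
    ideation shows now what severity will show ``lag_biweeks`` biweeks later,
    which is exactly the configuration a positive lag-at-maximum CCF flags
    downstream.

    ``zero_prob`` is the probability that the whole curve is masked to zero:
    an "ideation non-reporter" whose Item 9 stays at 0 regardless of
    severity.  This is the dominant form of zero inflation in real PHQ data
    — a large minority of patients never endorse the ideation item at all —
    and downstream such patients surface as degenerate (identically flat)
    cross-correlation profiles and are excluded from lag summaries, exactly
    like the flat-ideation patients excluded in the emulated study
    population.  Masking is drawn once per call from ``rng`` (independently
    across patients), so the returned curve is a deterministic function.
    """
    if abs(int(lag_biweeks)) > MAX_ABS_LAG:
        raise ConfigurationError(f"|lag_biweeks| must be <= {MAX_ABS_LAG}, got {lag_biweeks}")
    if not 0.0 <= zero_prob <= 1.0:
        raise ConfigurationError("zero_prob must lie in [0, 1]")
    shift_weeks = 2.0 * int(lag_biweeks)

    if zero_prob > 0.0:
        if zero_prob < 1.0 and rng is None:
            raise ConfigurationError("0 < zero_prob < 1 requires an rng")
        if zero_prob >= 1.0 or rng.random() < zero_prob:
            masked = lambda t: np.zeros_like(np.asarray(t, dtype=float))
            masked.is_masked = True
            return masked

    def item9(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.clip(phq8_latent(t + shift_weeks) / 8.0, 0.0, 3.0)

    item9.is_masked = False
    return item9


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _draw_visit_days(cfg: SimConfig, rng: np.random.Generator) -> List[int]:
    """Irregular visit days in [0, horizon), guaranteed >= min_visits.

    Gaps come from a gamma with the configured mean/dispersion, discretised
    to whole days (>= 2).  If a draw yields too few visits the patient's
    schedule is redrawn; an evenly spaced fallback keeps the guarantee
    unconditional.
    """
    horizon_days = cfg.horizon_weeks * 7
    shape = 1.0 / cfg.gap_dispersion
    scale = cfg.mean_gap_weeks * 7.0 * cfg.gap_dispersion
    for _ in range(200):
        days = [0]
        while True:
            gap = max(2, int(round(rng.gamma(shape, scale))))
            nxt = days[-1] + gap
            if nxt >= horizon_days:
                break
            days.append(nxt)
        if len(days) >= cfg.min_visits:
            return days
    step = max(1, (horizon_days - 1) // (cfg.min_visits - 1))
    return [i * step for i in range(cfg.min_visits)]


def _split_total_into_items(total: int) -> Tuple[int, ...]:
    """Deterministically spread a 0-24 total over eight 0-3 items."""
    q, r = divmod(int(total), 8)
    return tuple([q + 1] * r + [q] * (8 - r))


def _observe(latent_value: float, noise_sd: float, upper: int, rng: np.random.Generator) -> int:
    # rng.normal(0, 0) is exactly 0, so the draw keeps the stream aligned
    # between noisy and noiseless configs.
    return int(np.clip(round(float(latent_value) + rng.normal(0.0, noise_sd)), 0, upper))


def _draw_demographics(pid: str, rng: np.random.Generator) -> Demographics:
    draws = {}
    for feat, cats in DEMOGRAPHIC_CATEGORIES.items():
        labels = [c for c, _ in cats]
        probs = [p for _, p in cats]
        draws[feat] = labels[rng.choice(len(labels), p=probs)]
    return Demographics(patient_id=pid, **draws)


def generate_cohort(cfg: SimConfig) -> Tuple[List[VisitRecord], List[Demographics], GroundTruth]:
    """Generate one synthetic cohort.

    Returns the visit records (time-sorted within patient), the demographics
    table, and the :class:`GroundTruth` (latent class, planted lag and
    noiseless latent curves per patient).  Identical ``cfg`` (including seed)
    yields bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    mix = np.asarray(cfg.class_mix, dtype=float)

    visits: List[VisitRecord] = []
    demographics: List[Demographics] = []
    truths: Dict[str, PatientTruth] = {}

    width = max(4, len(str(cfg.n_patients)))
    for i in range(cfg.n_patients):
        pid = f"P{i:0{width}d}"
        cls = TRAJECTORY_CLASSES[rng.choice(len(TRAJECTORY_CLASSES), p=mix)]
        params = _draw_class_params(cls, rng)
        phq8_fn = _latent_fn(cls, params)
        item9_clean = plant_lagged_item9(phq8_fn, cfg.lag_biweeks, zero_prob=0.0)
        item9_masked = plant_lagged_item9(phq8_fn, cfg.lag_biweeks, cfg.item9_zero_prob, rng)

        grid_weeks = np.arange(0, cfg.horizon_weeks, 2, dtype=float)
        truths[pid] = PatientTruth(
            patient_id=pid,
            latent_class=cls,
            lag_biweeks=cfg.lag_biweeks,
            params=params,
            phq8_latent_grid=np.clip(phq8_fn(grid_weeks), 0.0, 24.0),
            item9_latent_grid=item9_clean(grid_weeks),
            phq8_fn=phq8_fn,
            item9_fn=item9_clean,
        )

        for t_day in _draw_visit_days(cfg, rng):
            t_week = t_day / 7.0
            total = _observe(float(phq8_fn(t_week)), cfg.noise_sd, 24, rng)
            # A masked non-reporter answers the ideation item with a
            # structural zero; reporting noise applies only to real latents.
            item9 = _observe(float(item9_masked(t_week)), cfg.noise_sd, 3, rng)
            if getattr(item9_masked, "is_masked", False):
                item9 = 0
            visits.append(VisitRecord(pid, t_day, _split_total_into_items(total) + (item9,)))

        demographics.append(_draw_demographics(pid, rng))

    return visits, demographics, GroundTruth(config=cfg, patients=truths)


# ---------------------------------------------------------------------------
# Inclusion rule
# ---------------------------------------------------------------------------


def select_cohort(
    records: Sequence[VisitRecord], min_visits: int = 6, window_biweeks: int = 20
) -> List[str]:
    """Apply the study inclusion rule.

    A patient is included iff some run of ``window_biweeks`` *consecutive*
    two-week periods contains at least ``min_visits`` of their visits
    (biweek index = ``t_days // 14``).  Returns included patient ids in order
    of first appearance; an empty record set gives an empty list.
    """
    order: List[str] = []
    by_patient: Dict[str, List[int]] = {}
    for rec in records:
        if rec.patient_id not in by_patient:
            by_patient[rec.patient_id] = []
            order.append(rec.patient_id)
        by_patient[rec.patient_id].append(rec.t_days // DAYS_PER_BIWEEK)

    included = []
    for pid in order:
        biweeks = sorted(by_patient[pid])
        if len(biweeks) < min_visits:
            continue
        ok = False
        for start in range(0, biweeks[-1] + 1):
            n_in = sum(1 for b in biweeks if start <= b < start + window_biweeks)
            if n_in >= min_visits:
                ok = True
                break
        if ok:
            included.append(pid)
    return included
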