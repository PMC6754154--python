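"""Change-pattern analyses on the unfitted raw scores.

Complementing the fitted-trajectory analyses, this module works directly on
the raw questionnaire records:

* short-term association — the per-week rate of change of PHQ-8 (per-item
  average, 0-3) and Item 9 between consecutive observations at most one
  month apart;
* long-term association — score change at the 3-, 6- and 9-month anchors
  (windowed mean around month *t* minus the first observation);
* Spearman rank correlation plus ordinary least squares of the Item-9 change
  on the PHQ-8 change, pooled across patients;
* opposite-direction patterns between consecutive observations:
  pattern (a) = PHQ-8 total rises by at least *d* while Item 9 falls by at
  least 1; pattern (b) = PHQ-8 falls by at least *d* while Item 9 rises by
  at least 1 (the clinically worrying "ideation up while severity improves"
  signature), with *d* in {2, 3, 4};
* the resulting four-subgroup partition (a-only / b-only / both / none) and
  a chi-square test of homogeneity of that partition across demographic
  strata.

Pattern thresholds *d* apply to the 0-24 PHQ-8 total; association analyses
use the per-item average (total / 8) so the two measures share the 0-3
scale.  One month is taken as 30.44 days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

from phqtraj.cohort import Demographics, VisitRecord

__all__ = [
    "ChangePair",
    "PatternLabel",
    "SUBGROUPS",
    "DAYS_PER_MONTH",
    "InsufficientDataError",
    "DegenerateTableError",
    "short_term_rate_pairs",
    "anchor_deltas",
    "association",
    "classify_patterns",
    "classify_cohort",
    "analysis_population",
    "partition_counts",
    "chi_square_table",
    "chi_square_homogeneity",
]

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.44
DAYS_PER_WEEK = 7.0
SUBGROUPS = ("a_only", "b_only", "both", "none")


class InsufficientDataError(ValueError):
    pass


class DegenerateTableError(ValueError):
    pass


@dataclass(frozen=True)
class ChangePair:
    """One (PHQ-8 change, Item-9 change) observation pair.

    ``kind`` is ``short_term_rate`` (units: score per week, PHQ-8 as per-item
    average) or ``anchor_delta_{3,6,9}m`` (score units).
    """

    patient_id: str
    kind: str
    phq8_change: float
    item9_change: float


@dataclass(frozen=True)
class PatternLabel:
    patient_id: str
    threshold_d: int
    subgroup: str

    def __post_init__(self) -> None:
        if self.subgroup not in SUBGROUPS:
            raise ValueError(f"subgroup must be one of {SUBGROUPS}")


def _by_patient(records: Sequence[VisitRecord]) -> Dict[str, List[VisitRecord]]:
    grouped: Dict[str, List[VisitRecord]] = {}
    for rec in records:
        grouped.setdefault(rec.patient_id, []).append(rec)
    for pid in grouped:
        grouped[pid].sort(key=lambda r: r.t_days)
    return grouped


def short_term_rate_pairs(records: Sequence[VisitRecord]) -> List[ChangePair]:
    """Rates of change between consecutive observations at most one month apart.

    One pair per qualifying consecutive-visit gap, pooled across patients.
    PHQ-8 is converted to the per-item average before the rate is taken, so
    both rates are on the same 0-3 score scale (per week).
    """
    pairs: List[ChangePair] = []
    for pid, recs in _by_patient(records).items():
        for prev, cur in zip(recs, recs[1:]):
            gap_days = cur.t_days - prev.t_days
            if gap_days <= 0 or gap_days > DAYS_PER_MONTH:
                continue
            gap_weeks = gap_days / DAYS_PER_WEEK
            pairs.append(
                ChangePair(
                    patient_id=pid,
                    kind="short_term_rate",
                    phq8_change=(cur.phq8_total - prev.phq8_total) / 8.0 / gap_weeks,
                    item9_change=(cur.item9 - prev.item9) / gap_weeks,
                )
            )
    return pairs


def anchor_deltas(records: Sequence[VisitRecord], t_months: int) -> List[ChangePair]:
    """Change at the month-``t`` anchor relative to the first observation.

    The anchor value is the mean of the records whose time (measured from the
    first observation) falls within ``[t - 0.5, t + 0.5]`` months; patients
    with an empty window contribute no pair.
    """
    if t_months not in (3, 6, 9):
        raise ValueError("anchors are defined at months 3, 6 and 9")
    lo = (t_months - 0.5) * DAYS_PER_MONTH
    hi = (t_months + 0.5) * DAYS_PER_MONTH
    pairs: List[ChangePair] = []
    for pid, recs in _by_patient(records).items():
        t0 = recs[0].t_days
        in_win = [r for r in recs if lo <= (r.t_days - t0) <= hi]
        if not in_win:
            continue
        phq8_first = recs[0].phq8_total / 8.0
        item9_first = float(recs[0].item9)
        phq8_anchor = float(np.mean([r.phq8_total for r in in_win])) / 8.0
        item9_anchor = float(np.mean([r.item9 for r in in_win]))
        pairs.append(
            ChangePair(
                patient_id=pid,
                kind=f"anchor_delta_{t_months}m",
                phq8_change=phq8_anchor - phq8_first,
                item9_change=item9_anchor - item9_first,
            )
        )
    return pairs


def association(pairs: Sequence[ChangePair]) -> Dict[str, float]:
    """Spearman correlation and OLS of Item-9 change on PHQ-8 change.

    Spearman uses average ranks for ties with the large-sample p-value; the
    regression slope/R^2 come from ordinary least squares.  Requires at
    least three pairs.
    """
    if len(pairs) < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {len(pairs)}")
    x = np.array([p.phq8_change for p in pairs])
    y = np.array([p.item9_change for p in pairs])
    rho, pval = stats.spearmanr(x, y)
    ols = stats.linregress(x, y)
    return {
        "spearman_rho": float(rho),
        "spearman_p": float(pval),
        "ols_slope": float(ols.slope),
        "ols_r2": float(ols.rvalue**2),
        "n_pairs": len(pairs),
    }


def classify_patterns(
    patient_records: Sequence[VisitRecord],
    d: int,
    max_gap_days: Optional[float] = None,
) -> PatternLabel:
    """Classify one patient's opposite-direction change patterns at threshold ``d``.

    Scans consecutive observation pairs (optionally capped at
    ``max_gap_days``); pattern (a) fires when the PHQ-8 total rises by at
    least ``d`` while Item 9 falls by at least 1 on the same pair, pattern
    (b) on the mirrored changes.  The patient's subgroup is a_only / b_only /
    both / none according to which patterns fired anywhere in the series.
    """
    recs = sorted(patient_records, key=lambda r: r.t_days)
    if not recs:
        raise ValueError("classify_patterns needs at least one record")
    pid = recs[0].patient_id
    if any(r.patient_id != pid for r in recs):
        raise ValueError("classify_patterns takes the records of a single patient")
    if len(recs) < 2:
        logger.warning("patient %s has < 2 observations; labelled 'none'", pid)
        return PatternLabel(pid, int(d), "none")

    fired_a = fired_b = False
    for prev, cur in zip(recs, recs[1:]):
        if max_gap_days is not None and (cur.t_days - prev.t_days) > max_gap_days:
            continue
        d_phq8 = cur.phq8_total - prev.phq8_total
        d_item9 = cur.item9 - prev.item9
        if d_phq8 >= d and d_item9 <= -1:
            fired_a = True
        if d_phq8 <= -d and d_item9 >= 1:
            fired_b = True
    subgroup = {(True, True): "both", (True, False): "a_only", (False, True): "b_only", (False, False): "none"}[
        (fired_a, fired_b)
    ]
    return PatternLabel(pid, int(d), subgroup)


def analysis_population(records: Sequence[VisitRecord]) -> List[str]:
    """Patients whose raw Item-9 series is not identically zero.

    Patients who never report any suicidal ideation carry no information
    about Item-9 change patterns and are excluded from the partition.
    """
    return [pid for pid, recs in _by_patient(records).items() if any(r.item9 > 0 for r in recs)]


def classify_cohort(
    records: Sequence[VisitRecord],
    d: int,
    population: Optional[Sequence[str]] = None,
    max_gap_days: Optional[float] = None,
) -> List[PatternLabel]:
    """Pattern labels for every patient in the analysis population."""
    grouped = _by_patient(records)
    if population is None:
        population = analysis_population(records)
    return [classify_patterns(grouped[pid], d, max_gap_days) for pid in population]


def partition_counts(labels: Sequence[PatternLabel]) -> Dict[str, Dict[str, float]]:
    """Counts and percentages over the four mutually exclusive subgroups."""
    counts = {g: 0 for g in SUBGROUPS}
    for lab in labels:
        counts[lab.subgroup] += 1
    n = len(labels)
    pct = {g: (100.0 * c / n if n else 0.0) for g, c in counts.items()}
    return {"counts": counts, "percentages": pct, "n": n}


def chi_square_table(table: np.ndarray) -> Dict[str, float]:
    """Pearson chi-square homogeneity statistic for a contingency table.

    ``statistic = sum (O - E)^2 / E`` with expected counts from the row/column
    marginals, ``dof = (r-1)(c-1)``; ``low_expected_flag`` is set when any
    expected cell is below 5 (large-sample approximation suspect).  A zero
    row or column marginal raises :class:`DegenerateTableError`.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DegenerateTableError("contingency table must be at least 2x2")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise DegenerateTableError("zero row/column marginal")
    expected = np.outer(row, col) / obs.sum()
    statistic = float(((obs - expected) ** 2 / expected).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return {
        "statistic": statistic,
        "dof": dof,
        "p": float(stats.chi2.sf(statistic, dof)),
        "low_expected_flag": bool(np.any(expected < 5)),
    }


def chi_square_homogeneity(
    labels: Sequence[PatternLabel],
    demographics: Sequence[Demographics],
    feature: str,
) -> Dict[str, float]:
    """Homogeneity of the subgroup partition across one demographic feature.

    Builds the subgroup x category contingency table (empty subgroups or
    unused categories are dropped before testing, since a zero marginal makes
    the statistic undefined).
    """
    demo_by_pid = {d.patient_id: d for d in demographics}
    cats = sorted({getattr(demo_by_pid[lab.patient_id], feature) for lab in labels})
    table = np.zeros((len(SUBGROUPS), len(cats)), dtype=float)
    for lab in labels:
        i = SUBGROUPS.index(lab.subgroup)
        j = cats.index(getattr(demo_by_pid[lab.patient_id], feature))
        table[i, j] += 1
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    return chi_square_table(table)
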