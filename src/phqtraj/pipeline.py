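"""End-to-end pipeline orchestration.

``run_all`` executes simulate -> select -> fit -> ccf -> patterns ->
subtypes, writing each stage's tables to the output directory and a run
manifest (stage order, derived per-stage seeds, configuration hash and
per-output row counts).  A single global seed deterministically derives
every stage seed, so identical configuration + seed reproduces every output
and the manifest hash bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Tuple, Union

import numpy as np
import pandas as pd

from phqtraj import io as pio
from phqtraj.autoencoder import (
    ConstantTrajectoryError,
    SgdSettings,
    encode,
    normalize_input,
    train,
)
from phqtraj.ccf import population_lag_summary, sample_ccf
from phqtraj.cohort import (
    ConfigurationError,
    SimConfig,
    VisitRecord,
    generate_cohort,
    select_cohort,
)
from phqtraj.gpr import default_settings, fit_cohort, grid_search_hyperparams, patient_series
from phqtraj.patterns import (
    InsufficientDataError,
    analysis_population,
    anchor_deltas,
    association,
    chi_square_homogeneity,
    classify_cohort,
    partition_counts,
    short_term_rate_pairs,
)
from phqtraj.subtypes import ActivationMatrix, embed_and_cluster, group_mean_trajectories, reorder_activations

__all__ = [
    "PipelineConfig",
    "StageError",
    "ValidationError",
    "FormatError",
    "load_visits",
    "run_all",
    "ALL_STAGES",
]

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "select", "fit", "ccf", "patterns", "subtypes")
DEMOGRAPHIC_FEATURES = ("age_band", "sex", "race_eth", "charlson_band")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class FormatError(ValueError):
    pass


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline-level configuration.

    ``latent_size`` is the autoencoder's H; the input length M is implied by
    the horizon (``horizon_weeks / 2`` biweekly grid points, 20 by default).
    """

    sim: SimConfig
    lag_window: int = 5
    thresholds: Tuple[int, ...] = (2, 3, 4)
    latent_size: int = 25
    sgd: SgdSettings = field(default_factory=SgdSettings)
    subtype_measure: str = "phq8"
    n_clusters: Union[int, str] = "auto"
    seed: int = 0
    stages: Tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        if self.sim.horizon_weeks % 2 != 0:
            raise ConfigurationError("horizon_weeks must be an even number of weeks")
        if self.lag_window < 1:
            raise ConfigurationError("lag_window must be >= 1")
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ConfigurationError(f"unknown stages: {unknown}")
        if self.subtype_measure not in ("phq8", "item9"):
            raise ConfigurationError("subtype_measure must be 'phq8' or 'item9'")

    @property
    def grid_length(self) -> int:
        return self.sim.horizon_weeks // 2

    _FLAT_KEYS = (
        "n_patients", "horizon_weeks", "min_visits", "mean_gap_weeks", "gap_dispersion",
        "class_mix", "lag_biweeks", "item9_zero_prob", "noise_sd",
        "lag_window", "thresholds", "latent_size", "subtype_measure", "n_clusters",
        "seed", "stages", "learning_rate", "batch_size", "epochs", "l2",
    )

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        """Build from a flat declarative mapping; unknown keys are errors."""
        unknown = sorted(set(raw) - set(cls._FLAT_KEYS))
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {unknown}")
        sim_keys = {
            "n_patients", "horizon_weeks", "min_visits", "mean_gap_weeks",
            "gap_dispersion", "class_mix", "lag_biweeks", "item9_zero_prob", "noise_sd",
        }
        sim_kwargs = {k: raw[k] for k in sim_keys if k in raw}
        if "class_mix" in sim_kwargs:
            sim_kwargs["class_mix"] = tuple(sim_kwargs["class_mix"])
        sgd_kwargs = {
            k: raw[k] for k in ("learning_rate", "batch_size", "epochs", "l2") if k in raw
        }
        top = {}
        for k in ("lag_window", "latent_size", "subtype_measure", "n_clusters", "seed"):
            if k in raw:
                top[k] = raw[k]
        if "thresholds" in raw:
            top["thresholds"] = tuple(raw["thresholds"])
        if "stages" in raw:
            top["stages"] = tuple(raw["stages"])
        return cls(sim=SimConfig(**sim_kwargs), sgd=SgdSettings(**sgd_kwargs), **top)

    def to_canonical_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = dataclasses.asdict(self.sim)
        d["sgd"] = dataclasses.asdict(self.sgd)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_canonical_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def derive_stage_seeds(global_seed: int) -> Dict[str, int]:
    """One deterministic sub-seed per stage from the global seed."""
    state = np.random.SeedSequence(global_seed).generate_state(len(ALL_STAGES))
    return {stage: int(s % (2**31)) for stage, s in zip(ALL_STAGES, state)}


def load_visits(path: Path) -> List[VisitRecord]:
    """Read and validate a visits table.

    Requires columns ``patient_id, t_days, item1..item9``; every item must be
    an integer in 0..3 and times nonnegative.  Malformed rows are reported
    together, by row number.  Rows are returned time-sorted within patient
    (out-of-order input is sorted with a log note).
    """
    df = pio.read_table(path)
    required = ["patient_id", "t_days"] + [f"item{i}" for i in range(1, 10)]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")

    records: List[VisitRecord] = []
    bad: List[str] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        items = tuple(int(getattr(row, f"item{i}")) for i in range(1, 10))
        try:
            records.append(VisitRecord(str(row.patient_id), int(row.t_days), items))
        except ValueError as exc:
            bad.append(f"row {row_no}: {exc}")
    if bad:
        raise ValidationError(f"{path}: {len(bad)} invalid row(s): " + "; ".join(bad[:10]))

    ordered = sorted(records, key=lambda r: (r.patient_id, r.t_days))
    if [(r.patient_id, r.t_days) for r in records] != [(r.patient_id, r.t_days) for r in ordered]:
        logger.info("%s: rows were not time-sorted per patient; sorted on load", path)
    return ordered


def run_all(config: PipelineConfig, out_dir: Path) -> dict:
    """Execute the configured stages and return the run manifest.

    Any stage failure raises :class:`StageError` naming the stage; outputs of
    completed stages are retained in ``out_dir`` for debugging.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    seeds = derive_stage_seeds(config.seed)
    stages = [s for s in ALL_STAGES if s in config.stages]
    row_counts: Dict[str, int] = {}

    def _write(df: pd.DataFrame, name: str, stage: str) -> None:
        pio.write_table(df, out / name, stage, chash)
        row_counts[name] = len(df)

    state: Dict[str, object] = {}
    for stage in stages:
        try:
            if stage == "simulate":
                sim_cfg = replace(config.sim, seed=seeds["simulate"])
                visits, demo, truth = generate_cohort(sim_cfg)
                state.update(visits=visits, demographics=demo, truth=truth)
                _write(pio.visits_frame(visits), "visits.csv", stage)
                _write(pio.demographics_frame(demo), "demographics.csv", stage)
                pio.write_json(truth.to_dict(), out / "ground_truth.json")
            elif stage == "select":
                visits = state["visits"]
                included = select_cohort(visits, config.sim.min_visits, config.grid_length)
                state["included"] = included
                _write(pd.DataFrame({"patient_id": included}), "selected_patients.csv", stage)
            elif stage == "fit":
                visits = state["visits"]
                included = state.get("included")
                fitted_all = []
                selected_params = {}
                for measure in ("phq8", "item9"):
                    series = patient_series(visits, measure)
                    if included is not None:
                        series = {p: s for p, s in series.items() if p in set(included)}
                    hp = grid_search_hyperparams(series, default_settings(measure), max_patients=40)
                    selected_params[measure] = dataclasses.asdict(hp)
                    fitted = fit_cohort(
                        visits, measure, hp,
                        horizon_weeks=config.sim.horizon_weeks, patient_ids=included,
                    )
                    state[f"fitted_{measure}"] = fitted
                    fitted_all.extend(fitted)
                pio.write_json(selected_params, out / "gpr_selected_params.json")
                _write(pio.fitted_frame(fitted_all), "fitted.csv", stage)
            elif stage == "ccf":
                lags = tuple(range(-config.lag_window, config.lag_window + 1))
                phq8 = {t.patient_id: t for t in state["fitted_phq8"]}
                item9 = {t.patient_id: t for t in state["fitted_item9"]}
                profiles = [
                    sample_ccf(phq8[pid].mean, item9[pid].mean, lags, patient_id=pid)
                    for pid in phq8
                    if pid in item9
                ]
                state["profiles"] = profiles
                summary = population_lag_summary(profiles)
                state["lag_summary"] = summary
                _write(pio.ccf_frame(profiles), "ccf_profiles.csv", stage)
                _write(pio.lag_histogram_frame(summary), "lag_histogram.csv", stage)
                pio.write_json(
                    {k: v for k, v in summary.items() if k != "histogram"},
                    out / "lag_summary.json",
                )
            elif stage == "patterns":
                visits = state["visits"]
                demo = state["demographics"]
                assoc_rows = []
                horizons = [("short_term", short_term_rate_pairs(visits))] + [
                    (f"{m}m", anchor_deltas(visits, m)) for m in (3, 6, 9)
                ]
                for name, pairs in horizons:
                    try:
                        a = association(pairs)
                    except InsufficientDataError:
                        a = {"spearman_rho": np.nan, "spearman_p": np.nan,
                             "ols_slope": np.nan, "ols_r2": np.nan, "n_pairs": len(pairs)}
                    assoc_rows.append({"horizon": name, **a})
                _write(pd.DataFrame(assoc_rows), "association.csv", stage)

                population = analysis_population(visits)
                all_labels, partition_rows, chisq_rows = [], [], []
                for d in config.thresholds:
                    labels = classify_cohort(visits, d, population)
                    all_labels.extend(labels)
                    part = partition_counts(labels)
                    for g in part["counts"]:
                        partition_rows.append(
                            {"threshold_d": d, "subgroup": g,
                             "count": part["counts"][g], "percent": part["percentages"][g]}
                        )
                    for feat in DEMOGRAPHIC_FEATURES:
                        try:
                            res = chi_square_homogeneity(labels, demo, feat)
                        except Exception as exc:  # degenerate table
                            logger.warning("chi-square for %s at d=%d skipped: %s", feat, d, exc)
                            continue
                        chisq_rows.append({"threshold_d": d, "feature": feat, **res})
                state["labels"] = all_labels
                _write(pio.labels_frame(all_labels), "pattern_labels.csv", stage)
                _write(pd.DataFrame(partition_rows), "partition_table.csv", stage)
                _write(pd.DataFrame(chisq_rows), "chisq.csv", stage)
            elif stage == "subtypes":
                fitted = state[f"fitted_{config.subtype_measure}"]
                rows, pids = [], []
                for tr in fitted:
                    try:
                        rows.append(normalize_input(tr.mean))
                        pids.append(tr.patient_id)
                    except ConstantTrajectoryError:
                        logger.warning("patient %s excluded from subtypes (flat curve)", tr.patient_id)
                X = np.stack(rows)
                model, trace = train(X, config.latent_size, config.sgd, seed=seeds["subtypes"])
                act = ActivationMatrix(encode(model, X), tuple(pids))
                assignments, emb, inertias = embed_and_cluster(
                    act, config.n_clusters, seed=seeds["subtypes"]
                )
                reordered = reorder_activations(act, assignments)
                means = group_mean_trajectories(
                    assignments, list(state["fitted_phq8"]) + list(state["fitted_item9"])
                )
                grid = fitted[0].grid_weeks
                pio.write_json(pio.model_dict(model), out / "model.json")
                _write(pio.activations_frame(reordered), "activations.csv", stage)
                _write(pio.clusters_frame(assignments), "clusters.csv", stage)
                _write(pio.group_means_frame(means, grid), "group_mean_trajectories.csv", stage)
                _write(
                    pd.DataFrame([{"K": k, "inertia": v} for k, v in sorted(inertias.items())]),
                    "inertia.csv", stage,
                )
                state["assignments"] = assignments
        except Exception as exc:
            raise StageError(stage, exc) from exc

    output_hashes = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        for p in sorted(out.iterdir())
        if p.suffix in (".csv", ".json") and p.name != "manifest.json"
    }
    manifest = {
        "stages": stages,
        "stage_seeds": {s: seeds[s] for s in stages},
        "global_seed": config.seed,
        "config_hash": chash,
        "row_counts": row_counts,
        "output_hashes": output_hashes,
    }
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    pio.write_json(manifest, out / "manifest.json")
    return manifest
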