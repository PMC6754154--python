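"""Plain-CSV / JSON readers and writers for the pipeline's tables.

Every table written here starts with a provenance comment line
(``# stage=<stage> config=<hash>``) naming the producing stage and the
configuration hash, followed by an ordinary CSV with a header row.  Readers
skip comment lines.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Sequence

import numpy as np
import pandas as pd

from phqtraj.autoencoder import AutoencoderModel
from phqtraj.ccf import CcfProfile
from phqtraj.cohort import Demographics, VisitRecord
from phqtraj.gpr import FittedTrajectory
from phqtraj.patterns import ChangePair, PatternLabel
from phqtraj.subtypes import ActivationMatrix, SubtypeAssignment

__all__ = ["write_table", "read_table", "write_json", "read_fitted"]


def read_fitted(path: Path) -> Dict[str, Dict[str, "FittedTrajectory"]]:
    """Load fitted.csv back into per-measure FittedTrajectory maps."""
    df = read_table(path)
    fitted: Dict[str, Dict[str, FittedTrajectory]] = {}
    for (pid, measure), grp in df.groupby(["patient_id", "measure"], sort=False):
        grp = grp.sort_values("week")
        fitted.setdefault(measure, {})[str(pid)] = FittedTrajectory(
            patient_id=str(pid),
            measure=measure,
            grid_weeks=grp["week"].to_numpy(),
            mean=grp["mean"].to_numpy(),
            sd=grp["sd"].to_numpy(),
            loglik=float("nan"),
        )
    return fitted


def write_table(df: pd.DataFrame, path: Path, stage: str, config_hash: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} config={config_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(obj: dict, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


# ---- stage-specific frames -------------------------------------------------


def visits_frame(visits: Sequence[VisitRecord]) -> pd.DataFrame:
    rows = [
        {"patient_id": v.patient_id, "t_days": v.t_days, **{f"item{i+1}": v.items[i] for i in range(9)}}
        for v in visits
    ]
    return pd.DataFrame(rows)


def demographics_frame(demo: Sequence[Demographics]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": d.patient_id,
                "age_band": d.age_band,
                "sex": d.sex,
                "race_eth": d.race_eth,
                "charlson_band": d.charlson_band,
            }
            for d in demo
        ]
    )


def fitted_frame(fitted: Sequence[FittedTrajectory]) -> pd.DataFrame:
    rows = []
    for tr in fitted:
        for w, m, s in zip(tr.grid_weeks, tr.mean, tr.sd):
            rows.append(
                {"patient_id": tr.patient_id, "measure": tr.measure, "week": w, "mean": m, "sd": s}
            )
    return pd.DataFrame(rows)


def ccf_frame(profiles: Sequence[CcfProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for k, r in zip(p.lags, p.rho):
            rows.append(
                {"patient_id": p.patient_id, "lag": k, "rho": r, "degenerate": p.degenerate}
            )
    return pd.DataFrame(rows)


def lag_histogram_frame(summary: Dict[str, object]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"lag": k, "count": c} for k, c in summary["histogram"].items()]
    )


def pairs_frame(pairs: Sequence[ChangePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "kind": p.kind,
                "phq8_change": p.phq8_change,
                "item9_change": p.item9_change,
            }
            for p in pairs
        ]
    )


def labels_frame(labels: Sequence[PatternLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"patient_id": l.patient_id, "threshold_d": l.threshold_d, "subgroup": l.subgroup}
            for l in labels
        ]
    )


def model_dict(model: AutoencoderModel) -> dict:
    return {
        "W": model.W.tolist(),
        "b": model.b.tolist(),
        "b_prime": model.b_prime.tolist(),
        "u": model.u,
        "H": model.H,
        "M": model.M,
    }


def activations_frame(act: ActivationMatrix) -> pd.DataFrame:
    df = pd.DataFrame(act.values, columns=[f"h{j+1}" for j in range(act.values.shape[1])])
    df.insert(0, "patient_id", act.patient_ids)
    return df


def clusters_frame(assignments: Sequence[SubtypeAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": a.patient_id,
                "x": a.embedding_xy[0],
                "y": a.embedding_xy[1],
                "cluster": a.cluster,
            }
            for a in assignments
        ]
    )


def group_means_frame(means: Dict[int, Dict[str, np.ndarray]], grid_weeks: np.ndarray) -> pd.DataFrame:
    rows = []
    for cluster, per_measure in means.items():
        for measure, curve in per_measure.items():
            for w, v in zip(grid_weeks, curve):
                rows.append({"cluster": cluster, "measure": measure, "week": w, "mean": v})
    return pd.DataFrame(rows)
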