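"""Autoencoder subtype discovery.

Normalises each patient's fitted PHQ-8 curve, trains the tied-weight
autoencoder (H = 25 latent basis trajectories), selects H by 5-fold
cross-validation for context, embeds the activations with t-SNE, clusters
with k-means (K chosen by the inertia knee), reorders the activation matrix
by cluster and writes per-cluster mean trajectories of both measures.
Cluster labels are finally scored against the generator's latent classes.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from phqtraj import io as pio
from phqtraj.autoencoder import (
    ConstantTrajectoryError,
    SgdSettings,
    cross_validate,
    encode,
    normalize_input,
    train,
)
from phqtraj.subtypes import (
    ActivationMatrix,
    embed_and_cluster,
    group_mean_trajectories,
    reorder_activations,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "pipeline"
SEED = 20260920


def main() -> None:
    fitted = pio.read_fitted(OUT / "fitted.csv")
    rows, pids = [], []
    for pid, tr in fitted["phq8"].items():
        try:
            rows.append(normalize_input(tr.mean))
            pids.append(pid)
        except ConstantTrajectoryError:
            continue
    X = np.stack(rows)
    print(f"{len(pids)} patients enter subtype discovery")

    cv = cross_validate(X, [1, 5, 10, 25], folds=5, seed=SEED,
                        sgd=SgdSettings(epochs=100))
    print("5-fold CV validation MSE by latent size:")
    for H, res in cv.items():
        print(f"  H={H:2d}: {res['mean_mse']:.3f} +/- {res['sd_mse']:.3f}")

    model, trace = train(X, 25, SgdSettings(), seed=SEED)
    print(f"training MSE: epoch 1 {trace[0]:.3f} -> final {trace[-1]:.3f}")
    act = ActivationMatrix(encode(model, X), tuple(pids))
    assignments, _, inertias = embed_and_cluster(act, "auto", seed=SEED)
    K = len({a.cluster for a in assignments})
    print(f"inertia knee selects K = {K}")

    pio.write_json(pio.model_dict(model), OUT / "model.json")
    pio.write_table(pio.activations_frame(reorder_activations(act, assignments)),
                    OUT / "activations.csv", "subtypes", "analysis")
    pio.write_table(pio.clusters_frame(assignments), OUT / "clusters.csv", "subtypes", "analysis")
    all_fitted = list(fitted["phq8"].values()) + list(fitted["item9"].values())
    means = group_mean_trajectories(assignments, all_fitted)
    grid = next(iter(fitted["phq8"].values())).grid_weeks
    pio.write_table(pio.group_means_frame(means, grid),
                    OUT / "group_mean_trajectories.csv", "subtypes", "analysis")
    pio.write_table(pd.DataFrame([{"K": k, "inertia": v} for k, v in sorted(inertias.items())]),
                    OUT / "inertia.csv", "subtypes", "analysis")

    import json

    gt = json.loads((OUT / "ground_truth.json").read_text())
    true_classes = [gt["patients"][p]["latent_class"] for p in pids]
    ari = adjusted_rand_score(true_classes, [a.cluster for a in assignments])
    ct = pd.crosstab(pd.Series(true_classes, name="latent class"),
                     pd.Series([a.cluster for a in assignments], name="cluster"))
    print(f"adjusted Rand vs generating classes: {ari:.3f}")
    print(ct.to_string())


if __name__ == "__main__":
    main()
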