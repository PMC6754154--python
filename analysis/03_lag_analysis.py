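"""Cross-correlation lead/lag analysis.

Computes each patient's CCF between the fitted PHQ-8 and Item-9 curves over
lags -5..+5 biweeks, writes the profiles and the population lag-at-maximum
histogram, and runs a planted-lag recovery experiment: cohorts with a known
Item-9 lead of L biweeks, scored on how often the CCF argmax lands within
one biweek of L.  A final panel documents why monotone-ramp trajectories are
excluded from lag planting: a shifted ramp is nearly the same ramp, so the
finite-window CCF shrinks their argmax toward zero.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from phqtraj import io as pio
from phqtraj.ccf import population_lag_summary, sample_ccf
from phqtraj.cohort import LAG_STUDY_CLASS_MIX, SimConfig, generate_cohort
from phqtraj.gpr import default_settings, fit_cohort, grid_search_hyperparams, patient_series

OUT = Path(__file__).resolve().parents[1] / "results" / "pipeline"
SEED = 20260920


def fit_both(visits):
    fitted = {}
    for measure in ("phq8", "item9"):
        series = patient_series(visits, measure)
        hp = grid_search_hyperparams(series, default_settings(measure), max_patients=40)
        fitted[measure] = {t.patient_id: t for t in fit_cohort(visits, measure, hp)}
    return fitted


def main() -> None:
    # 1. lag structure of the default cohort (no planted lead/lag)
    fitted = pio.read_fitted(OUT / "fitted.csv")
    profiles = [
        sample_ccf(tr.mean, fitted["item9"][pid].mean, patient_id=pid)
        for pid, tr in fitted["phq8"].items()
        if pid in fitted["item9"]
    ]
    summary = population_lag_summary(profiles)
    pio.write_table(pio.ccf_frame(profiles), OUT / "ccf_profiles.csv", "ccf", "analysis")
    pio.write_table(pio.lag_histogram_frame(summary), OUT / "lag_histogram.csv", "ccf", "analysis")
    print(f"default cohort: {summary['n_total']} patients, "
          f"{summary['n_degenerate']} degenerate (flat Item 9, excluded), "
          f"{100 * summary['fraction_lag0']:.0f}% of the rest in synchrony (lag 0)")

    # 2. planted-lag recovery
    rows = []
    for lag in range(-3, 4):
        cfg = SimConfig(
            n_patients=100, lag_biweeks=lag, noise_sd=0.2, item9_zero_prob=0.2,
            class_mix=LAG_STUDY_CLASS_MIX, seed=SEED + lag,
        )
        visits, _, _ = generate_cohort(cfg)
        f = fit_both(visits)
        ok = tot = 0
        for pid, tr in f["phq8"].items():
            prof = sample_ccf(tr.mean, f["item9"][pid].mean)
            if prof.degenerate:
                continue
            tot += 1
            ok += abs(prof.lag_at_max - lag) <= 1
        rows.append({"planted_lag": lag, "n_nondegenerate": tot, "recovered_within_1": ok,
                     "pct": 100.0 * ok / tot})
    rec = pd.DataFrame(rows)
    pio.write_table(rec, OUT / "lag_recovery.csv", "ccf", "analysis")
    print("planted-lag recovery (within +/-1 biweek):")
    print(rec.to_string(index=False))

    # 3. why monotone ramps are excluded from lag planting
    grid = np.arange(0, 40, 2.0)
    ramp = lambda t: 4 + 12 / (1 + np.exp(-(np.asarray(t, float) - 20) / 3))
    bump = lambda t: 4 + 12 * np.exp(-((np.asarray(t, float) - 20) ** 2) / 60)
    for name, f in [("sigmoid ramp", ramp), ("gaussian bump", bump)]:
        recovered = [sample_ccf(f(grid), f(grid + 2 * L) / 8).lag_at_max for L in range(-3, 4)]
        print(f"{name}: planted lags -3..3 recovered as {recovered}")


if __name__ == "__main__":
    main()
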