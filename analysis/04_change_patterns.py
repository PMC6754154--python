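"""Raw-score change-pattern analyses.

On the unfitted visit records: short-term (within one month) and long-term
(3/6/9-month anchor) association between PHQ-8 and Item-9 changes, the
opposite-direction pattern partition at thresholds d = 2, 3, 4 — pattern (b),
severity falling while ideation rises, is the clinically worrying signature —
and chi-square homogeneity of the partition across demographic strata.
"""

from pathlib import Path

import pandas as pd

from phqtraj import io as pio
from phqtraj.cohort import Demographics
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
from phqtraj.pipeline import DEMOGRAPHIC_FEATURES, load_visits

OUT = Path(__file__).resolve().parents[1] / "results" / "pipeline"


def main() -> None:
    visits = load_visits(OUT / "visits.csv")
    demo_df = pio.read_table(OUT / "demographics.csv")
    demographics = [Demographics(**row) for row in demo_df.astype(str).to_dict("records")]

    assoc_rows = []
    for name, pairs in [("short_term", short_term_rate_pairs(visits))] + [
        (f"{m}m", anchor_deltas(visits, m)) for m in (3, 6, 9)
    ]:
        try:
            assoc_rows.append({"horizon": name, **association(pairs)})
        except InsufficientDataError:
            assoc_rows.append({"horizon": name, "n_pairs": len(pairs)})
    assoc = pd.DataFrame(assoc_rows)
    pio.write_table(assoc, OUT / "association.csv", "patterns", "analysis")
    print("PHQ-8 vs Item-9 change association:")
    print(assoc.to_string(index=False))

    population = analysis_population(visits)
    print(f"\nanalysis population (Item 9 not all zeros): {len(population)} patients")
    part_rows, chisq_rows, all_labels = [], [], []
    for d in (2, 3, 4):
        labels = classify_cohort(visits, d, population)
        all_labels.extend(labels)
        part = partition_counts(labels)
        for g, c in part["counts"].items():
            part_rows.append({"threshold_d": d, "subgroup": g, "count": c,
                              "percent": part["percentages"][g]})
        for feat in DEMOGRAPHIC_FEATURES:
            try:
                chisq_rows.append(
                    {"threshold_d": d, "feature": feat,
                     **chi_square_homogeneity(labels, demographics, feat)}
                )
            except Exception:
                continue
    part_df = pd.DataFrame(part_rows)
    pio.write_table(pio.labels_frame(all_labels), OUT / "pattern_labels.csv", "patterns", "analysis")
    pio.write_table(part_df, OUT / "partition_table.csv", "patterns", "analysis")
    pio.write_table(pd.DataFrame(chisq_rows), OUT / "chisq.csv", "patterns", "analysis")
    print("\nchange-pattern partition (a: severity up / ideation down; b: severity down / ideation up):")
    print(part_df.pivot(index="threshold_d", columns="subgroup", values="count").to_string())
    b_pct = part_df[part_df.subgroup.isin(["b_only", "both"])].groupby("threshold_d")["percent"].sum()
    print("\npatients with any pattern (b) by threshold (%):")
    print(b_pct.round(1).to_string())
    sig = [r for r in chisq_rows if r["p"] < 0.05]
    print(f"\nchi-square homogeneity: {len(sig)} of {len(chisq_rows)} "
          "feature/threshold combinations differ at alpha = 0.05")


if __name__ == "__main__":
    main()
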