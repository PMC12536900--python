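"""Simulate the study-scale synthetic cohort.

Draws 569 subjects: 400-volume ROI time series over the 17-region atlas map,
16 inter-correlated self-report measures with published-descriptive margins,
a sparse linear symptom outcome (six generating effects), and realistic
missingness — MCAR per measure plus the by-design rule that removes the
depression inventory for subjects over 65.

Writes to results/cohort/: the predictor table (empty field = missing), the
outcome, the edge features, the generating truth, and per-subject time-series
CSVs for the first 20 subjects (kept small; edges for all subjects are
computed in memory).
"""

from pathlib import Path

import fcselect as fs
from fcselect.connectivity import connectivity_features
from fcselect.io import write_features, write_panel, write_predictor_table

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 20

def main() -> None:
    out = RESULTS / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    spec = fs.default_cohort_spec(seed=SEED)
    panel = fs.simulate_roi_timeseries(spec)
    features = connectivity_features(panel, spec.region_map)
    cohort = fs.simulate_predictors_and_outcome(spec, features)
    cohort = fs.inject_missingness(cohort, spec)

    write_predictor_table(cohort.predictor_table, out / "predictors.csv")
    cohort.outcome.to_csv(out / "outcome.csv")
    write_features(features, out / "features.csv")
    cohort.truth["beta"].to_csv(out / "truth_beta.csv")
    sub = panel.subjects[:20]
    write_panel(
        fs.RoiTimeSeriesPanel(
            subjects=sub, data={s: panel.data[s] for s in sub}, label_ids=panel.label_ids
        ),
        out / "timeseries_sample",
    )

    n_miss = int(cohort.predictor_table.isna().sum().sum())
    over65 = int((cohort.truth["predictors"]["age"] > 65).sum())
    print(f"cohort: n={spec.n_subjects}, predictors={cohort.predictor_table.shape[1]} "
          f"(16 self-report + {len(features.edge_labels)} edges)")
    print(f"outcome mean={cohort.outcome.mean():.2f} sd={cohort.outcome.std():.2f}")
    print(f"missing entries: {n_miss} (depression skipped for {over65} subjects over 65)")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
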