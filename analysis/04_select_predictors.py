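"""Impute-then-select: pooled spike-and-slab selection of symptom predictors.

Runs the SSVS Gibbs sampler (prior inclusion 0.5) independently on each of
the m completed datasets from 03_impute_missing.py, pools marginal inclusion
probabilities and model-averaged coefficients by arithmetic mean, and applies
the 0.5 cutoff with the 0.45-0.50 near-threshold band. Chains are shortened
to 4,000 iterations (1,000 burn-in) per imputation to keep the driver quick;
the study-scale run length is 20,000/5,000.

Writes the pooled table, the selection table, and the sorted MIP/gap table
used for graphical cutoff inspection, then compares the selection with the
generating truth. In this cohort the generating effects explain only ~9% of
outcome variance and the edge predictors are mutually correlated, so beyond
the generating set the selection also picks up correlated proxies with
diffuse MIPs — the expected behavior of model-averaged selection in a
low signal-to-noise, correlated-predictor regime.
"""

from pathlib import Path

import pandas as pd

from fcselect import SsvsConfig, impute_then_select, mip_plot_data, select_predictors
from fcselect.io import read_imputation_set

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 22


def main() -> None:
    imps = read_imputation_set(RESULTS / "imputations")
    outcome = pd.read_csv(RESULTS / "cohort" / "outcome.csv", index_col=0).iloc[:, 0]
    pooled = impute_then_select(
        imps, outcome, SsvsConfig(n_iter=4000, burn_in=1000, seed=SEED)
    )
    pooled.table.to_csv(RESULTS / "pooled_result.csv")
    selection = select_predictors(pooled)
    selection.to_csv(RESULTS / "selection.csv")
    mip_plot_data(pooled).to_csv(RESULTS / "mip_plot_data.csv")

    truth = pd.read_csv(RESULTS / "cohort" / "truth_beta.csv", index_col=0).iloc[:, 0]
    true_predictors = set(truth.index[truth != 0])
    selected = set(selection.index[selection["selected"]])
    print("selected predictors (pooled MIP >= 0.5):")
    print(selection.round(3).to_string())
    print(f"\ngenerating predictors recovered: "
          f"{len(true_predictors & selected)}/{len(true_predictors)}")
    extra = selected - true_predictors
    if extra:
        print(f"selected beyond the generating set: {sorted(extra)}")


if __name__ == "__main__":
    main()
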