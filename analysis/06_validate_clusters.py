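"""Inferential validation of the typologies.

Runs the full battery on the standardized classification variables: per-
variable ANOVA and Kruskal-Wallis, one-way MANOVA (Wilks' lambda and
Hotelling-Lawley trace), and all pairwise squared-Mahalanobis centroid
tests.  A difference is only called when parametric and nonparametric
procedures agree.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from stresstypo.inference import cluster_validation

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    argparse.ArgumentParser().parse_args()
    src = ROOT / "scratch" / "cohort"
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    assign = pd.read_csv(src / "assignments.csv", index_col="row_id")["cluster"]
    ind = pd.read_csv(src / "indicators.csv", index_col="row_id").loc[assign.index]
    Z = (ind - ind.mean()) / ind.std()

    battery = cluster_validation(Z, assign.to_numpy())
    (results / "validation_report.json").write_text(
        json.dumps(battery.to_dict(), indent=2)
    )

    manova = battery.manova
    print(f"k = {battery.k} clusters, {battery.n_pairwise} pairwise comparisons")
    print(f"Wilks' lambda = {manova['wilks_lambda'].value:.4f} "
          f"(F = {manova['wilks_lambda'].f_value:.1f}, p = {manova['wilks_lambda'].p:.3g})")
    print(f"Hotelling-Lawley trace = {manova['hotelling_lawley'].value:.3f} "
          f"(p = {manova['hotelling_lawley'].p:.3g})")
    worst = max(r.p for r in battery.pairwise)
    print(f"largest pairwise Mahalanobis p-value: {worst:.3g}")
    print("\nper-variable tests (both procedures):")
    print(battery.per_variable.map(lambda p: f"{p:.2g}").to_string())


if __name__ == "__main__":
    main()
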