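"""Relate typologies to personal data, illness and metabolic syndrome.

Cross-classifies the typologies against gender, age group, work category,
illness status and ATP III metabolic-syndrome status: within-typology vs
total percentages, an overall chi-square test per variable, and cellwise
adjusted Pearson residuals flagged at |APR| thresholds 2 / 3 / 3.5.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from stresstypo.association import associate, significant_associations

ROOT = Path(__file__).resolve().parents[1]
VARIABLES = ["sex", "age_group", "work_category", "illness", "mes_status"]


def main() -> None:
    argparse.ArgumentParser().parse_args()
    src = ROOT / "scratch" / "cohort"
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    assign = pd.read_csv(src / "assignments.csv", index_col="row_id")["cluster"]
    data = pd.read_csv(src / "cleaned.csv", index_col="row_id")
    # clustering ran on all questionnaire rows; clinical cleaning may have
    # dropped a few more, so profile the intersection
    assign = assign[assign.index.isin(data.index)]
    data = data.loc[assign.index]

    res = associate(assign, data, VARIABLES)
    overall = []
    for var, r in res.items():
        overall.append({"variable": var, "chi2": round(r.chi2, 2), "df": r.df,
                        "p": float(f"{r.p:.3g}")})
        profile = r.profile.within_typology_pct.round(1)
        profile.loc["total"] = r.profile.total_pct.round(1)
        profile.to_csv(results / f"profile_{var}.csv")
        r.apr.residuals.round(2).to_csv(results / f"apr_{var}.csv")
    pd.DataFrame(overall).to_csv(results / "association_overall_tests.csv", index=False)

    sig = significant_associations(res)
    (results / "associations.json").write_text(json.dumps(sig, indent=2))
    print(pd.DataFrame(overall).to_string(index=False))
    print(f"\n{len(sig)} flagged typology-category associations; strongest:")
    for row in sorted(sig, key=lambda r: -abs(r["apr"]))[:8]:
        print(f"  typology {row['typology']} x {row['variable']}={row['category']}: "
              f"APR {row['apr']:+.2f} ({row['flag']})")


if __name__ == "__main__":
    main()
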