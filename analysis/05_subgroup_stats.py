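"""Dystonia vs PD subgroup contrasts on the simulated cohort.

Tests the disease-group differences in direct-target and lead-tip
coordinates with the unpaired pooled-variance t-test (after a KS
normality check), mirroring how subgroup contrasts are reported for
bilateral lead cohorts.  Writes results/subgroup_tests.csv.
"""

from pathlib import Path

import pandas as pd

from gpilead.stats import compare_groups

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    leads_csv = ROOT / "synthetic_cohort" / "leads.csv"
    if not leads_csv.exists():
        raise SystemExit("run analysis/02_simulate_cohort.py first")
    leads = pd.read_csv(leads_csv)

    rows = []
    for field in (
        "direct_lat", "direct_ap", "direct_vert",
        "tip_lat", "tip_ap", "tip_vert",
        "active_lat", "active_ap", "active_vert",
    ):
        out = compare_groups(leads, field, "disease_group")
        rows.append(
            {
                "field": field,
                "group_a": out.groups[0], "group_b": out.groups[1],
                "mean_a": round(out.means[0], 2), "mean_b": round(out.means[1], 2),
                "sd_a": round(out.sds[0], 2), "sd_b": round(out.sds[1], 2),
                "n_a": out.n[0], "n_b": out.n[1],
                "p_value": round(out.p_value, 4),
                "significant": out.significant,
                "normality_ok": out.normality_ok,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "subgroup_tests.csv", index=False)
    for _, r in df.iterrows():
        star = "*" if r["significant"] else " "
        print(
            f"{r['field']:>12}: {r['group_a']} {r['mean_a']:.2f}+/-{r['sd_a']:.2f} "
            f"vs {r['group_b']} {r['mean_b']:.2f}+/-{r['sd_b']:.2f}  p={r['p_value']:.3f}{star}"
        )


if __name__ == "__main__":
    main()
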