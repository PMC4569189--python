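"""Atlas vs direct targets and lead targeting errors, simulated cohort.

Compares the two planning routes per lead (per-axis and Euclidean
differences), evaluates the in-plane targeting error of each implanted
lead at the level of its intended target, and the distances from each
target to the closest point of the contact-bearing lead segment.

Writes results/target_comparison_summary.csv from the per-lead table
produced by 03_localize_and_index.py.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    per_lead = ROOT / "pipeline" / "target_comparison.csv"
    if not per_lead.exists():
        raise SystemExit("run analysis/03_localize_and_index.py first")
    df = pd.read_csv(per_lead)

    cols = {
        "delta_lat": "atlas-direct dLAT",
        "delta_ap": "atlas-direct dAP",
        "delta_vert": "atlas-direct dVERT",
        "delta_euclid": "atlas-direct Euclidean",
        "error_d": "targeting error d",
        "closest_direct_euclid": "direct target to lead",
        "closest_atlas_euclid": "atlas target to lead",
    }
    summary = pd.DataFrame(
        {
            "quantity": list(cols.values()),
            "mean_mm": [df[c].mean() for c in cols],
            "sd_mm": [df[c].std(ddof=1) for c in cols],
            "n": len(df),
        }
    )
    summary.to_csv(ROOT / "target_comparison_summary.csv", index=False)
    for _, r in summary.iterrows():
        print(f"{r['quantity']}: {r['mean_mm']:.2f} +/- {r['sd_mm']:.2f} mm (n={r['n']})")


if __name__ == "__main__":
    main()
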