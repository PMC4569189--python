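"""Localize leads and index active contacts on the simulated cohort.

Reads the files written by 02_simulate_cohort.py, reconstructs each
lead from its tip and shaft points, derives the active-contact point
from the stimulation configuration, and indexes it against the GPi
mask.  Writes the per-lead pipeline outputs under results/pipeline/.
"""

import json
from pathlib import Path

from gpilead.pipeline import PipelineConfig, run_pipeline

ROOT = Path(__file__).resolve().parent.parent / "results"
IN = ROOT / "synthetic_cohort"


def main() -> None:
    if not (IN / "leads.csv").exists():
        raise SystemExit("run analysis/02_simulate_cohort.py first")
    out = run_pipeline(
        PipelineConfig(
            output_dir=ROOT / "pipeline",
            landmarks_csv=IN / "landmarks.csv",
            leads_csv=IN / "leads.csv",
            masks_dir=IN,
        )
    )
    summary = json.loads((out / "summary.json").read_text())
    print(f"localized {summary['n_leads']} leads -> {out}")
    mi = summary["mean_indices"]
    print(
        "mean contact indices: "
        f"AP {mi['ap_index']:.2f}, ML {mi['ml_index']:.2f}, VD {mi['vd_index']:.2f}"
    )
    for row in summary["location_labels"]:
        print(f"label {row['label']}: {row['count']} leads ({row['percent']}%)")


if __name__ == "__main__":
    main()
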