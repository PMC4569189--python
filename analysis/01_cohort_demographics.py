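"""Demographics and active-contact labels of the packaged GPi-DBS cohort.

Summarizes the published 13-patient / 26-lead bilateral cohort: age,
sex split, disease groups, chronic stimulation parameters, and where
the active contacts sit relative to the pallidal anatomy.

Writes results/cohort_demographics.csv and
results/active_contact_labels.csv.
"""

from pathlib import Path

from gpilead.datasets import load_gpi_cohort, patients_table
from gpilead.stats import describe, location_label_summary

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    leads = load_gpi_cohort()
    pts = patients_table(leads)

    rows = []
    for field, frame, decimals in [
        ("age", pts, 1),
        ("symptom_duration_years", pts, 1),
        ("voltage_v", leads, 1),
        ("pulse_width_us", leads, 0),
        ("frequency_hz", leads, 0),
    ]:
        d = describe(frame, field, decimals=decimals)
        d.insert(0, "field", field)
        rows.append(d)
    import pandas as pd

    demo = pd.concat(rows, ignore_index=True)
    demo.to_csv(OUT / "cohort_demographics.csv", index=False)

    labels = location_label_summary(leads)
    labels.to_csv(OUT / "active_contact_labels.csv", index=False)

    n_m = (pts["sex"] == "m").sum()
    age = demo[demo["field"] == "age"].iloc[0]
    print(f"{len(pts)} patients ({n_m} m / {len(pts) - n_m} f), {len(leads)} leads")
    print(f"age {age['mean_disp']} +/- {age['sd_disp']} years")
    for _, r in labels.iterrows():
        print(f"active contact {r['label']}: {r['count']}/26 leads ({r['percent']}%)")


if __name__ == "__main__":
    main()
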