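"""Packaged cohort data.

``load_gpi_cohort`` returns the published bilateral GPi-DBS cohort used
throughout the analyses: 13 patients (7 men, 6 women; 6 Parkinson's
disease, 7 dystonia of various subtypes), 26 implanted leads, one row
per lead with demographics, the anatomical label of the active contact,
the stimulation configuration and the chronic stimulation parameters.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_gpi_cohort", "patients_table"]


def load_gpi_cohort() -> pd.DataFrame:
    """One row per implanted lead (26 rows, 13 patients)."""
    with resources.files("gpilead.data").joinpath("gpi_dbs_cohort.csv").open() as fh:
        return pd.read_csv(fh)


def patients_table(leads: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-lead table to one row per patient.

    Keeps the per-patient fields (age, sex, disease, symptom duration);
    lead-level fields are dropped.
    """
    cols = [
        c
        for c in ("age", "sex", "disease", "disease_group", "symptom_duration_years")
        if c in leads.columns
    ]
    return leads.groupby("patient_id", as_index=False)[cols].first()
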