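"""Bundled reference cohort: published behavioral-economics parameters.

Twelve male rats (six methamphetamine, six saline) from a long-access
intravenous self-administration study; per-subject essential value, demand
intensity, maximal expenditure and Pmax as printed (2 decimal places) in the
study's sample table.  The RNA sample table carries both brain regions
(hippocampus and prefrontal cortex) per subject; one METH PFC sample was
compromised during transport and is flagged ``excluded``.

These printed values are inputs for reproduction checks; they are not
recomputed here.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_demand_cohort", "load_sample_table"]

# subject, group, EV, Q0, Omax, Pmax (behavioral values; identical across regions)
_SUBJECTS = [
    ("45", "METH", 0.82, 19.00, 22.77, 3.69),
    ("46", "METH", 0.79, 2.80, 22.06, 24.28),
    ("47", "METH", 2.64, 6.00, 73.54, 37.77),
    ("48", "METH", 1.81, 7.20, 50.43, 21.58),
    ("51", "METH", 1.01, 8.90, 28.24, 9.78),
    ("52", "METH", 4.22, 5.10, 117.66, 71.10),
    ("39", "SAL", 0.09, 0.87, 2.61, 9.26),
    ("40", "SAL", 0.00, 0.74, 0.11, 0.46),
    ("44", "SAL", 0.13, 1.40, 3.53, 7.77),
    ("49", "SAL", 0.15, 2.30, 4.15, 5.56),
    ("50", "SAL", 0.19, 1.70, 5.43, 9.84),
    ("53", "SAL", 0.07, 0.52, 1.91, 11.31),
]

# region, subject, RNA IQ, concentration (ug/uL), excluded
_SAMPLES = [
    ("Hip", "45", 7.0, 2.3208, False),
    ("Hip", "46", 7.0, 2.4656, False),
    ("Hip", "47", 8.2, 1.48624, False),
    ("Hip", "48", 7.6, 1.95136, False),
    ("Hip", "51", 7.4, 1.80288, False),
    ("Hip", "52", 9.1, 0.85248, False),
    ("PFC", "45", 7.6, 2.14736, False),
    ("PFC", "46", 7.2, 2.6532, False),
    ("PFC", "47", 7.4, 2.3032, False),
    ("PFC", "48", 8.3, 1.44056, False),
    ("PFC", "51", 7.6, 2.29496, True),  # compromised during transport
    ("PFC", "52", 7.6, 3.15064, False),
    ("Hip", "39", 6.8, 2.19064, False),
    ("Hip", "40", 7.2, 2.26464, False),
    ("Hip", "44", 7.2, 2.26144, False),
    ("Hip", "49", 7.8, 1.41472, False),
    ("Hip", "50", 7.8, 1.70512, False),
    ("Hip", "53", 8.1, 1.73056, False),
    ("PFC", "39", 8.0, 1.51104, False),
    ("PFC", "40", 7.5, 2.19352, False),
    ("PFC", "44", 7.5, 2.18944, False),
    ("PFC", "49", 7.7, 2.88296, False),
    ("PFC", "50", 7.9, 1.84504, False),
    ("PFC", "53", 7.9, 1.9628, False),
]


def load_demand_cohort() -> pd.DataFrame:
    """The 12 subjects' published demand parameters.

    Columns: ``subject_id, group, ev, q0, omax, pmax`` (6 METH + 6 SAL).
    """
    return pd.DataFrame(_SUBJECTS, columns=["subject_id", "group", "ev", "q0", "omax", "pmax"])


def load_sample_table() -> pd.DataFrame:
    """The 24 RNA samples (2 regions x 12 subjects) with quality metadata.

    Columns: ``sample_id, region, subject_id, group, rna_iq, conc, excluded``
    plus the subject's behavioral parameters.  Excluding the flagged sample
    leaves the unbalanced 5 METH + 6 SAL prefrontal-cortex design.
    """
    subjects = load_demand_cohort().set_index("subject_id")
    rows = []
    for region, subj, iq, conc, excluded in _SAMPLES:
        s = subjects.loc[subj]
        rows.append(
            dict(
                sample_id=f"{region} {subj}",
                region=region,
                subject_id=subj,
                group=s["group"],
                rna_iq=iq,
                conc=conc,
                excluded=excluded,
                ev=s["ev"],
                q0=s["q0"],
                omax=s["omax"],
                pmax=s["pmax"],
            )
        )
    return pd.DataFrame(rows)
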