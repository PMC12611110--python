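"""Bundled reference tables.

National counts of respiratory tract cancers (ICD-10 C32 larynx, C33 trachea,
C34 bronchus/lung) among Brazilians aged 40-79, 2013-2022, aggregated from the
public DATASUS *Painel Oncologia* and Mortality Information System dashboards.
Used by the descriptive cohort summary and as a worked example.
"""

from __future__ import annotations

import pandas as pd

from .data_model import CohortTable

# indicator -> cohort total
RTC_TOTALS = {"diagnosis": 140_245, "treatment": 119_460, "death": 260_969}

# (indicator, partition, stratum) -> count; female counts are the complements
_RTC_COUNTS = [
    ("diagnosis", "sex", "male", 90_466),
    ("diagnosis", "sex", "female", 140_245 - 90_466),
    ("diagnosis", "site", "trachea", 376),
    ("diagnosis", "site", "larynx", 41_951),
    ("diagnosis", "site", "lung_bronchus", 97_708),
    ("treatment", "sex", "male", 78_830),
    ("treatment", "sex", "female", 119_460 - 78_830),
    ("treatment", "site", "trachea", 146),
    ("treatment", "site", "larynx", 37_227),
    ("treatment", "site", "lung_bronchus", 83_885),
    ("death", "sex", "male", 163_830),
    ("death", "sex", "female", 260_969 - 163_830),
    ("death", "site", "trachea", 802),
    ("death", "site", "larynx", 38_989),
    ("death", "site", "lung_bronchus", 221_519),
]


def load_rtc_cohort() -> CohortTable:
    """The national RTC cohort count table as a :class:`CohortTable`."""
    df = pd.DataFrame(_RTC_COUNTS,
                      columns=["indicator", "partition", "stratum", "count"])
    return CohortTable(df, dict(RTC_TOTALS))
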