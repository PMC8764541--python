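"""Deterministic cohort fixtures mirroring the published study's marginal
structure (448 infants, 444 mothers, 4 twin-sharing mothers, printed Table-1
marginal counts).  Used by the acceptance machinery and reusable in tests."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .feature_tables import CohortMetadata, FeatureTable

N_INFANTS = 448
N_MOTHERS = 444

#: printed marginal counts of the study's infant characteristics
TABLE1_COUNTS = {
    "sex": {"female": 231, "male": 217},
    "age_category": {"3mo": 113, "4mo": 312, "5mo+": 20, "": 3},
    "feeding": {"breast": 255, "mixed": 131, "formula": 60, "": 2},
    "delivery": {"vaginal": 360, "cesarean": 88},
    "antibiotics": {"none": 428, "within_1mo": 20},
    "smoking": {"no": 288, "yes": 160},
}


def _expand(counts: dict[str, int], n: int) -> list[str]:
    values: list[str] = []
    for level, c in counts.items():
        values.extend([level] * c)
    if len(values) != n:
        raise ValueError(f"counts sum to {len(values)}, expected {n}")
    return values


def study_scale_metadata() -> CohortMetadata:
    """448 infants / 444 mothers / 448 links with 4 twin-sharing mothers and
    covariate columns holding exactly the printed marginal counts."""
    rows = []
    mothers = [f"M{j + 1:04d}" for j in range(N_MOTHERS)]
    for m in mothers:
        rows.append(
            {"sample_id": m, "subject_id": f"S-{m}", "role": "mother", "pair_id": ""}
        )
    columns = {
        name: _expand(counts, N_INFANTS) for name, counts in TABLE1_COUNTS.items()
    }
    for i in range(N_INFANTS):
        # infants beyond the mother count are second twins of the first mothers
        mother = mothers[i % N_MOTHERS]
        infant = f"I{i + 1:04d}"
        row = {
            "sample_id": infant,
            "subject_id": f"S-{infant}",
            "role": "infant",
            "pair_id": mother,
        }
        for name, values in columns.items():
            row[name] = values[i]
        rows.append(row)
    return CohortMetadata(pd.DataFrame(rows))


def minimal_table_for(metadata: CohortMetadata) -> FeatureTable:
    """Smallest valid count table covering every sample of a metadata fixture.

    Pair-structure computations (e.g. counting unrelated combinations) depend
    only on the sample set, so two constant features suffice.
    """
    sample_ids = tuple(metadata.frame["sample_id"])
    counts = np.ones((2, len(sample_ids)), dtype=np.int64)
    return FeatureTable(("fA", "fB"), sample_ids, counts)
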