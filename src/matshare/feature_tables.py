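"""Count-table data model, taxonomy maps, cohort metadata and table-level transforms.

The central object is :class:`FeatureTable`, a validated features x samples
matrix of non-negative integer counts.  Tables, taxonomy maps and sample
metadata are read and written as plain UTF-8 TSV files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

#: sentinel for an absent covariate value in metadata files
MISSING = ""

ROLE_MOTHER = "mother"
ROLE_INFANT = "infant"

_METADATA_REQUIRED = ("sample_id", "subject_id", "role", "pair_id")


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class FeatureTable:
    """Non-negative integer counts, features (rows) x samples (columns).

    Invariants enforced at construction: unique ids, matching dimensions,
    integral non-negative entries, and strictly positive per-sample totals.
    """

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                bad = np.argwhere(np.mod(counts, 1) != 0)[0]
                raise ValueError(
                    f"non-integer count at feature {self.feature_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        object.__setattr__(self, "counts", np.ascontiguousarray(counts, dtype=np.int64))
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.counts.size and self.counts.min() < 0:
            bad = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at feature {self.feature_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if len(self.feature_ids) == 0:
            raise ValueError("empty table: no features")
        totals = self.counts.sum(axis=0)
        if np.any(totals == 0):
            bad = self.sample_ids[int(np.argmin(totals))]
            raise ValueError(f"sample {bad!r} has zero total count")

    # -- lookups ---------------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature id: {feature_id!r}") from None

    def sample_counts(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_index(sample_id)]

    def detection(self) -> np.ndarray:
        """Boolean features x samples matrix; detected iff count >= 1."""
        return self.counts > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.feature_ids), columns=list(self.sample_ids)
        )


def read_feature_table(path: str | Path) -> FeatureTable:
    """Load a TSV feature table (header = sample ids, first column = feature ids)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table ({exc})") from exc
    if frame.isna().any().any():
        row = frame.index[frame.isna().any(axis=1)][0]
        raise ValueError(f"{path}: missing value in row {row!r}")
    try:
        values = frame.apply(pd.to_numeric).to_numpy()
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric count ({exc})") from exc
    return FeatureTable(
        feature_ids=tuple(str(i) for i in frame.index),
        sample_ids=tuple(str(c) for c in frame.columns),
        counts=values,
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="feature_id")


def drop_control_asvs(table: FeatureTable, control_asvs: Iterable[str]) -> FeatureTable:
    """Remove negative-control features; sample set and retained counts unchanged."""
    control = set(control_asvs)
    absent = control.difference(table.feature_ids)
    if absent:
        logger.info("control ids not present in table (ignored): %s", sorted(absent))
    keep = [i for i, f in enumerate(table.feature_ids) if f not in control]
    if not keep:
        raise ValueError("empty table: all features are control ASVs")
    return FeatureTable(
        feature_ids=tuple(table.feature_ids[i] for i in keep),
        sample_ids=table.sample_ids,
        counts=table.counts[keep, :],
    )


def relative_abundance(table: FeatureTable) -> np.ndarray:
    """Per-sample relative abundances; every column sums to 1."""
    totals = table.counts.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("zero-total sample")
    return table.counts / totals.astype(float)


def observed_richness(table: FeatureTable) -> np.ndarray:
    """Number of detected (count >= 1) features per sample."""
    return (table.counts > 0).sum(axis=0)


def rarefaction_curve(
    sample_counts: Sequence[int] | np.ndarray, depths: Sequence[int]
) -> np.ndarray:
    """Expected richness in a uniform subsample without replacement at each depth.

    E[S_d] = sum_a [1 - C(N - n_a, d) / C(N, d)] where n_a are the per-feature
    counts and N their total.  The hypergeometric term is P(feature a absent
    from the subsample).
    """
    counts = np.asarray(sample_counts)
    if counts.size == 0:
        raise ValueError("empty count vector")
    if np.any(counts < 0) or not np.all(np.equal(np.mod(counts, 1), 0)):
        raise ValueError("counts must be non-negative integers")
    counts = counts.astype(np.int64)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("zero-total sample")
    depths = np.asarray(depths, dtype=np.int64)
    if np.any(depths < 0) or np.any(depths > total):
        raise ValueError(f"depths must lie in [0, {total}]")
    expected = np.empty(len(depths), dtype=float)
    positive = counts[counts > 0]
    for i, d in enumerate(depths):
        # P(zero draws of feature a) under hypergeometric sampling of d reads
        p_absent = hypergeom.pmf(0, total, positive, int(d))
        expected[i] = float(np.sum(1.0 - p_absent))
    return expected


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaxonRecord:
    reference_id: str
    identity_pct: float
    taxon_label: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError(
                f"identity_pct must be in [0, 100], got {self.identity_pct}"
            )


class TaxonomyMap:
    """ASV id -> (reference id, % identity, taxon label).

    OTU membership is defined by reference-id equality for ASVs at or above
    the identity threshold; lower-identity ASVs fall back to their taxon label.
    """

    def __init__(self, records: Mapping[str, TaxonRecord]):
        self._records = dict(records)

    def __contains__(self, asv_id: str) -> bool:
        return asv_id in self._records

    def __len__(self) -> int:
        return len(self._records)

    def get(self, asv_id: str) -> TaxonRecord | None:
        return self._records.get(asv_id)

    def __getitem__(self, asv_id: str) -> TaxonRecord:
        return self._records[asv_id]

    @property
    def records(self) -> dict[str, TaxonRecord]:
        return dict(self._records)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TaxonomyMap) and self._records == other._records


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"asv_id", "reference_id", "identity_pct", "taxon_label"}
    missing = required.difference(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing taxonomy columns {sorted(missing)}")
    records: dict[str, TaxonRecord] = {}
    for row in frame.itertuples(index=False):
        if row.asv_id in records:
            raise ValueError(f"{path}: ASV {row.asv_id!r} mapped more than once")
        records[row.asv_id] = TaxonRecord(
            reference_id=row.reference_id,
            identity_pct=float(row.identity_pct),
            taxon_label="" if pd.isna(row.taxon_label) else str(row.taxon_label),
        )
    return TaxonomyMap(records)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    rows = [
        {
            "asv_id": asv,
            "reference_id": rec.reference_id,
            "identity_pct": rec.identity_pct,
            "taxon_label": rec.taxon_label,
        }
        for asv, rec in sorted(tax.records.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


UNASSIGNED = "unassigned"


def collapse_to_otus(
    table: FeatureTable, tax: TaxonomyMap, min_identity: float = 98.5
) -> tuple[FeatureTable, dict[str, str]]:
    """Sum member-ASV counts into OTUs defined by shared reference ids.

    ASVs below ``min_identity`` (or absent from the map) are grouped under
    their taxon label, or under ``unassigned`` when no label is available.
    Returns the OTU table and the asv_id -> otu_id mapping; the grand total
    of counts is conserved.
    """
    mapping: dict[str, str] = {}
    otu_order: list[str] = []
    otu_rows: dict[str, np.ndarray] = {}
    for i, asv in enumerate(table.feature_ids):
        rec = tax.get(asv)
        if rec is None:
            otu = UNASSIGNED
        elif rec.identity_pct >= min_identity:
            otu = rec.reference_id
        else:
            otu = rec.taxon_label if rec.taxon_label else UNASSIGNED
        mapping[asv] = otu
        if otu not in otu_rows:
            otu_rows[otu] = np.zeros(table.n_samples, dtype=np.int64)
            otu_order.append(otu)
        otu_rows[otu] += table.counts[i, :]
    collapsed = FeatureTable(
        feature_ids=tuple(otu_order),
        sample_ids=table.sample_ids,
        counts=np.vstack([otu_rows[o] for o in otu_order]),
    )
    return collapsed, mapping


# ---------------------------------------------------------------------------
# cohort metadata
# ---------------------------------------------------------------------------


class CohortMetadata:
    """Per-sample role, pair links and clinical covariates.

    Each infant row carries a ``pair_id`` equal to the sample id of its
    mother's sample; a mother sample may be linked by more than one infant
    (twins).  Empty strings denote missing covariate values.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        for col in _METADATA_REQUIRED:
            if col not in frame.columns:
                raise ValueError(f"metadata is missing required column {col!r}")
        frame["sample_id"] = frame["sample_id"].astype(str)
        _check_unique(list(frame["sample_id"]), "sample")
        roles = set(frame["role"])
        bad_roles = roles.difference({ROLE_MOTHER, ROLE_INFANT})
        if bad_roles:
            raise ValueError(f"unknown roles in metadata: {sorted(bad_roles)}")
        frame = frame.set_index("sample_id", drop=False)
        mother_ids = set(frame.loc[frame["role"] == ROLE_MOTHER, "sample_id"])
        infants = frame[frame["role"] == ROLE_INFANT]
        for sid, pair in zip(infants["sample_id"], infants["pair_id"]):
            if pd.isna(pair) or str(pair) == MISSING:
                raise ValueError(f"infant {sid!r} has no mother link")
            if str(pair) not in mother_ids:
                raise ValueError(
                    f"infant {sid!r} links to unknown mother sample {pair!r}"
                )
        self._frame = frame

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def infant_ids(self) -> list[str]:
        return list(self._frame.loc[self._frame["role"] == ROLE_INFANT, "sample_id"])

    @property
    def mother_ids(self) -> list[str]:
        return list(self._frame.loc[self._frame["role"] == ROLE_MOTHER, "sample_id"])

    def mother_of(self, infant_sample_id: str) -> str:
        row = self._frame.loc[infant_sample_id]
        if row["role"] != ROLE_INFANT:
            raise KeyError(f"{infant_sample_id!r} is not an infant sample")
        return str(row["pair_id"])

    def pairs(self) -> list[tuple[str, str]]:
        """Biological (infant_sample, mother_sample) links, in metadata order."""
        return [(i, self.mother_of(i)) for i in self.infant_ids]

    def covariate(self, name: str, role: str = ROLE_INFANT) -> pd.Series:
        """Covariate values for one role, with the missing sentinel mapped to NaN."""
        if name not in self._frame.columns:
            raise KeyError(f"unknown covariate {name!r}")
        sub = self._frame.loc[self._frame["role"] == role, name]
        return sub.replace(MISSING, np.nan)

    def __len__(self) -> int:
        return len(self._frame)


def read_metadata(path: str | Path) -> CohortMetadata:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return CohortMetadata(frame)


def write_metadata(metadata: CohortMetadata, path: str | Path) -> None:
    metadata.frame.to_csv(path, sep="\t", index=False)
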