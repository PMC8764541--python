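"""Shared-ASV identification, per-infant sharing statistics, the unrelated-pair
null, and the per-OTU sharing index."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .feature_tables import CohortMetadata, FeatureTable, relative_abundance
from .nonparametrics import mann_whitney

PROFILE_STATISTICS = ("n_shared", "pct_shared", "shared_abundance")


@dataclass(frozen=True)
class SharedProfile:
    """Per-(infant, mother) sharing summary.

    ``shared_asvs`` may be ``None`` for profiles streamed in bulk (the three
    summary statistics are always present).
    """

    infant_sample_id: str
    mother_sample_id: str
    shared_asvs: frozenset[str] | None
    n_shared: int
    pct_shared: float
    shared_abundance: float


@dataclass(frozen=True)
class SharingIndexResult:
    otu_id: str
    n_pairs_shared: int
    n_union: int

    @property
    def index(self) -> float | None:
        if self.n_union == 0:
            return None
        return self.n_pairs_shared / self.n_union


@dataclass(frozen=True)
class ComparisonReport:
    statistic: str
    n_related: int
    n_unrelated: int
    related_median: float
    unrelated_median: float
    related_range: tuple[float, float]
    unrelated_range: tuple[float, float]
    u: float
    p: float


def find_shared_asvs(
    infant_sample: str, mother_sample: str, table: FeatureTable
) -> frozenset[str]:
    """ASVs detected (count >= 1) in both samples."""
    inf = table.sample_counts(infant_sample) > 0
    mom = table.sample_counts(mother_sample) > 0
    both = inf & mom
    return frozenset(f for f, b in zip(table.feature_ids, both) if b)


def shared_profile(
    infant_sample: str, mother_sample: str, table: FeatureTable
) -> SharedProfile:
    """Number, percentage (over the infant's observed ASVs) and cumulative
    relative abundance (in the infant) of ASVs detected in both samples."""
    inf_counts = table.sample_counts(infant_sample)
    mom_counts = table.sample_counts(mother_sample)
    richness = int((inf_counts > 0).sum())
    if richness == 0:
        raise ValueError(f"infant sample {infant_sample!r} has no detected features")
    both = (inf_counts > 0) & (mom_counts > 0)
    n_shared = int(both.sum())
    total = float(inf_counts.sum())
    abundance = float(inf_counts[both].sum()) / total
    shared = frozenset(f for f, b in zip(table.feature_ids, both) if b)
    return SharedProfile(
        infant_sample_id=infant_sample,
        mother_sample_id=mother_sample,
        shared_asvs=shared,
        n_shared=n_shared,
        pct_shared=n_shared / richness,
        shared_abundance=abundance,
    )


def related_profiles(
    table: FeatureTable, metadata: CohortMetadata
) -> list[SharedProfile]:
    """One profile per biological (infant, mother) link, in metadata order."""
    return [shared_profile(i, m, table) for i, m in metadata.pairs()]


def _null_matrices(
    table: FeatureTable, metadata: CohortMetadata
) -> tuple[list[str], list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized all-infants x all-mothers sharing statistics.

    Returns (infants sorted asc, mothers sorted asc, n_shared, pct_shared,
    shared_abundance) where the matrices are infants x mothers.
    """
    infants = sorted(metadata.infant_ids)
    mothers = sorted(metadata.mother_ids)
    inf_idx = [table.sample_index(s) for s in infants]
    mom_idx = [table.sample_index(s) for s in mothers]
    det = table.detection()
    rel = relative_abundance(table)
    det_inf = det[:, inf_idx]
    det_mom = det[:, mom_idx].astype(float)
    n_shared = det_inf.astype(float).T @ det_mom
    abundance = rel[:, inf_idx].T @ det_mom
    richness = det_inf.sum(axis=0).astype(float)
    if np.any(richness == 0):
        bad = infants[int(np.argmin(richness))]
        raise ValueError(f"infant sample {bad!r} has no detected features")
    pct = n_shared / richness[:, None]
    return infants, mothers, n_shared, pct, abundance


def unrelated_pair_stats(
    table: FeatureTable, metadata: CohortMetadata
) -> pd.DataFrame:
    """All infant x non-own-mother statistics, infant-major, mother id ascending."""
    mothers_set = set(metadata.mother_ids)
    if len(mothers_set) < 2:
        raise ValueError("unrelated-pair null undefined for a single-mother cohort")
    infants, mothers, n_shared, pct, abundance = _null_matrices(table, metadata)
    own = {i: metadata.mother_of(i) for i in infants}
    mother_pos = {m: j for j, m in enumerate(mothers)}
    rows_i: list[str] = []
    rows_m: list[str] = []
    keep_i: list[int] = []
    keep_j: list[int] = []
    for a, infant in enumerate(infants):
        skip = mother_pos[own[infant]]
        for j, m in enumerate(mothers):
            if j == skip:
                continue
            rows_i.append(infant)
            rows_m.append(m)
            keep_i.append(a)
            keep_j.append(j)
    ii = np.asarray(keep_i)
    jj = np.asarray(keep_j)
    return pd.DataFrame(
        {
            "infant_sample_id": rows_i,
            "mother_sample_id": rows_m,
            "n_shared": n_shared[ii, jj].astype(int),
            "pct_shared": pct[ii, jj],
            "shared_abundance": abundance[ii, jj],
        }
    )


def unrelated_pair_profiles(
    table: FeatureTable, metadata: CohortMetadata, *, include_sets: bool = False
) -> Iterator[SharedProfile]:
    """Stream profiles for every infant x non-own-mother combination.

    Exactly n_infants x n_mothers - n_related profiles, in deterministic
    infant-major, mother-ascending order.  Twin infants each exclude the same
    single mother.  ``include_sets=True`` additionally materializes the shared
    ASV set of each profile (slower).
    """
    stats = unrelated_pair_stats(table, metadata)
    for row in stats.itertuples(index=False):
        shared = (
            find_shared_asvs(row.infant_sample_id, row.mother_sample_id, table)
            if include_sets
            else None
        )
        yield SharedProfile(
            infant_sample_id=row.infant_sample_id,
            mother_sample_id=row.mother_sample_id,
            shared_asvs=shared,
            n_shared=int(row.n_shared),
            pct_shared=float(row.pct_shared),
            shared_abundance=float(row.shared_abundance),
        )


def _extract(profiles: Iterable, statistic: str) -> np.ndarray:
    if statistic not in PROFILE_STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if isinstance(profiles, pd.DataFrame):
        return profiles[statistic].to_numpy(dtype=float)
    return np.asarray([getattr(p, statistic) for p in profiles], dtype=float)


def compare_related_vs_unrelated(
    related: Iterable,
    unrelated: Iterable,
    statistic: str = "shared_abundance",
) -> ComparisonReport:
    """Two-sided Mann-Whitney comparison of one sharing statistic between
    biological and unrelated pairs (profiles or stats frames accepted)."""
    rel = _extract(related, statistic)
    unrel = _extract(unrelated, statistic)
    if rel.size == 0 or unrel.size == 0:
        raise ValueError("both groups must be non-empty")
    mw = mann_whitney(rel, unrel, method="normal")
    return ComparisonReport(
        statistic=statistic,
        n_related=rel.size,
        n_unrelated=unrel.size,
        related_median=float(np.median(rel)),
        unrelated_median=float(np.median(unrel)),
        related_range=(float(rel.min()), float(rel.max())),
        unrelated_range=(float(unrel.min()), float(unrel.max())),
        u=mw.u,
        p=mw.p,
    )


def _pair_carriage(
    member_rows: Sequence[int], table: FeatureTable, metadata: CohortMetadata
) -> tuple[int, int]:
    """(pairs sharing >= 1 member ASV, pairs where mother or infant carries the OTU).

    Counting is at pair level: a mother of twins enters once per pair.
    """
    det = table.detection()[member_rows, :]
    n_shared_pairs = 0
    n_union = 0
    for infant, mother in metadata.pairs():
        mom = det[:, table.sample_index(mother)]
        inf = det[:, table.sample_index(infant)]
        if mom.any() or inf.any():
            n_union += 1
        if (mom & inf).any():
            n_shared_pairs += 1
    return n_shared_pairs, n_union


def sharing_index(
    otu_id: str,
    table: FeatureTable,
    metadata: CohortMetadata,
    asv_to_otu: Mapping[str, str],
) -> SharingIndexResult:
    """Per-OTU pair-sharing rate.

    numerator: biological pairs in which mother and infant share at least one
    member ASV; denominator: pairs in which either the mother or the infant
    carries any member ASV.  Undefined (index None) when the denominator is 0.
    """
    member_rows = [
        i
        for i, asv in enumerate(table.feature_ids)
        if asv_to_otu.get(asv) == otu_id
    ]
    if not member_rows:
        raise KeyError(f"OTU {otu_id!r} has no member ASV in the table")
    n_shared_pairs, n_union = _pair_carriage(member_rows, table, metadata)
    return SharingIndexResult(
        otu_id=otu_id, n_pairs_shared=n_shared_pairs, n_union=n_union
    )


def sharing_index_table(
    table: FeatureTable,
    metadata: CohortMetadata,
    asv_to_otu: Mapping[str, str],
) -> pd.DataFrame:
    """Sharing index for every OTU present in the mapping, as a DataFrame."""
    otus: list[str] = []
    seen: set[str] = set()
    for asv in table.feature_ids:
        otu = asv_to_otu.get(asv)
        if otu is not None and otu not in seen:
            seen.add(otu)
            otus.append(otu)
    rows = []
    for otu in otus:
        r = sharing_index(otu, table, metadata, asv_to_otu)
        rows.append(
            {
                "otu_id": r.otu_id,
                "n_pairs_shared": r.n_pairs_shared,
                "n_union": r.n_union,
                "index": r.index if r.index is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


def profiles_frame(profiles: Iterable[SharedProfile]) -> pd.DataFrame:
    """Tabular view of profiles (shared ASV sets serialized comma-joined)."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "infant_sample_id": p.infant_sample_id,
                "mother_sample_id": p.mother_sample_id,
                "n_shared": p.n_shared,
                "pct_shared": p.pct_shared,
                "shared_abundance": p.shared_abundance,
                "shared_asvs": ",".join(sorted(p.shared_asvs))
                if p.shared_asvs is not None
                else "",
            }
        )
    return pd.DataFrame(rows)


def shared_abundance_series(profiles: Iterable[SharedProfile]) -> pd.Series:
    """Per-infant shared abundance keyed by infant sample id."""
    data = {p.infant_sample_id: p.shared_abundance for p in profiles}
    return pd.Series(data, dtype=float)
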