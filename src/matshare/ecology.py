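"""Community-level analyses: square-root Bray-Curtis distances, principal
coordinate analysis, the origin-aware (shared vs nonshared) OTU table, and
hierarchical clustering of infant microbiota."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .feature_tables import CohortMetadata, FeatureTable, relative_abundance
from .nonparametrics import PairwiseTestResult, steel_dwass
from .transmission import SharedProfile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceMatrix:
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if v.size and (v.min() < -1e-12 or v.max() > 1.0 + 1e-9):
            raise ValueError("distances must lie in [0, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.sample_ids)
        return pd.DataFrame(self.values, index=ids, columns=ids)


@dataclass(frozen=True)
class Ordination:
    """Classical-scaling result: eigenvalues (all, descending, possibly
    negative) and coordinates over the positive axes only."""

    sample_ids: tuple[str, ...]
    eigenvalues: np.ndarray
    coordinates: np.ndarray
    proportion_explained: np.ndarray


@dataclass(frozen=True)
class ModifiedOtuTable:
    """Per-infant OTU abundances split into maternally-shared and nonshared parts."""

    infant_ids: tuple[str, ...]
    otu_ids: tuple[str, ...]
    shared: np.ndarray  # otus x infants
    nonshared: np.ndarray  # otus x infants

    def __post_init__(self) -> None:
        s = np.asarray(self.shared, dtype=float)
        ns = np.asarray(self.nonshared, dtype=float)
        shape = (len(self.otu_ids), len(self.infant_ids))
        if s.shape != shape or ns.shape != shape:
            raise ValueError("component matrices do not match id lists")
        if s.size and (s.min() < -1e-12 or ns.min() < -1e-12):
            raise ValueError("abundance components must be non-negative")
        object.__setattr__(self, "shared", s)
        object.__setattr__(self, "nonshared", ns)

    def totals(self) -> np.ndarray:
        """Unsplit per-OTU relative abundances (shared + nonshared)."""
        return self.shared + self.nonshared

    def stacked(self) -> tuple[list[str], np.ndarray]:
        """(feature names, matrix) with two rows per OTU: shared / nonshared."""
        names: list[str] = []
        rows: list[np.ndarray] = []
        for i, otu in enumerate(self.otu_ids):
            names.append(f"{otu}|shared")
            rows.append(self.shared[i])
            names.append(f"{otu}|nonshared")
            rows.append(self.nonshared[i])
        return names, np.vstack(rows)

    def to_frame(self) -> pd.DataFrame:
        names, matrix = self.stacked()
        return pd.DataFrame(matrix, index=names, columns=list(self.infant_ids))


@dataclass(frozen=True)
class ClusterAssignment:
    assignments: Mapping[str, int]
    k: int

    def __post_init__(self) -> None:
        labels = set(self.assignments.values())
        if len(labels) != self.k:
            raise ValueError(
                f"expected exactly {self.k} non-empty clusters, found {len(labels)}"
            )

    def members(self, label: int) -> list[str]:
        return [s for s, c in self.assignments.items() if c == label]

    def labels(self) -> list[int]:
        return sorted(set(self.assignments.values()))


def bray_curtis(
    abundances: np.ndarray,
    sample_ids: Sequence[str],
    transform: str = "sqrt",
) -> DistanceMatrix:
    """Pairwise Bray-Curtis distances between sample columns.

    BC(x, y) = sum|x - y| / sum(x + y), computed on element-wise square-rooted
    profiles when ``transform="sqrt"``.
    """
    x = np.asarray(abundances, dtype=float)
    if x.ndim != 2:
        raise ValueError("abundance matrix must be 2-D (features x samples)")
    if x.shape[1] != len(sample_ids):
        raise ValueError("sample ids do not match matrix columns")
    if np.any(x.sum(axis=0) <= 0):
        raise ValueError("empty profile (zero column) in abundance matrix")
    if transform == "sqrt":
        x = np.sqrt(x)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    n = x.shape[1]
    colsum = x.sum(axis=0)
    dist = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[:, i : i + 1] - x[:, i + 1 :]).sum(axis=0)
        denom = colsum[i] + colsum[i + 1 :]
        dist[i, i + 1 :] = diff / denom
    dist = dist + dist.T
    return DistanceMatrix(sample_ids=tuple(sample_ids), values=dist)


def table_bray_curtis(table: FeatureTable, transform: str = "sqrt") -> DistanceMatrix:
    """Bray-Curtis distances between all samples of a count table."""
    return bray_curtis(relative_abundance(table), table.sample_ids, transform=transform)


def pcoa(dm: DistanceMatrix) -> Ordination:
    """Classical scaling (double-centering of -D^2/2) of a distance matrix.

    All eigenvalues are reported, negatives included and uncorrected;
    coordinates are returned for the positive axes only, ordered by
    descending eigenvalue.
    """
    d = dm.values
    n = d.shape[0]
    if n < 3:
        raise ValueError("PCoA requires at least three samples")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(1e-12, 1e-12 * max(abs(eigvals.max()), 1.0))
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    pos_sum = eigvals[positive].sum()
    proportion = (
        eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive] * 0.0
    )
    return Ordination(
        sample_ids=dm.sample_ids,
        eigenvalues=eigvals,
        coordinates=coords,
        proportion_explained=proportion,
    )


def build_modified_otu_table(
    table: FeatureTable,
    metadata: CohortMetadata,
    asv_to_otu: Mapping[str, str],
    profiles: Iterable[SharedProfile],
) -> ModifiedOtuTable:
    """Split each infant's per-OTU relative abundance into the parts carried by
    ASVs shared / not shared with the biological mother.

    ``profiles`` must be biological-pair profiles with materialized shared-ASV
    sets (as returned by :func:`matshare.transmission.related_profiles`).
    """
    by_infant: dict[str, SharedProfile] = {}
    for p in profiles:
        if p.shared_asvs is None:
            raise ValueError("profiles must carry shared-ASV sets")
        if metadata.mother_of(p.infant_sample_id) != p.mother_sample_id:
            raise ValueError(
                f"profile for {p.infant_sample_id!r} is not against its "
                "biological mother"
            )
        by_infant[p.infant_sample_id] = p
    infants = [i for i in metadata.infant_ids if i in by_infant]
    missing = set(metadata.infant_ids) - set(infants)
    if missing:
        raise ValueError(f"missing profiles for infants: {sorted(missing)}")
    otus: list[str] = []
    seen: set[str] = set()
    for asv in table.feature_ids:
        otu = asv_to_otu.get(asv)
        if otu is None:
            raise ValueError(f"ASV {asv!r} missing from the OTU mapping")
        if otu not in seen:
            seen.add(otu)
            otus.append(otu)
    otu_pos = {o: i for i, o in enumerate(otus)}
    rel = relative_abundance(table)
    shared = np.zeros((len(otus), len(infants)))
    nonshared = np.zeros((len(otus), len(infants)))
    for col, infant in enumerate(infants):
        s = table.sample_index(infant)
        shared_set = by_infant[infant].shared_asvs
        for row, asv in enumerate(table.feature_ids):
            a = rel[row, s]
            if a == 0:
                continue
            target = shared if asv in shared_set else nonshared
            target[otu_pos[asv_to_otu[asv]], col] += a
    return ModifiedOtuTable(
        infant_ids=tuple(infants),
        otu_ids=tuple(otus),
        shared=shared,
        nonshared=nonshared,
    )


def cluster_infants(
    mot: ModifiedOtuTable,
    k: int = 8,
    linkage_method: str = "average",
    transform: str = "sqrt",
) -> ClusterAssignment:
    """Agglomerative clustering of infants on sqrt-Bray-Curtis distances of the
    origin-split OTU table, cut into exactly ``k`` groups."""
    n = len(mot.infant_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    _, matrix = mot.stacked()
    dm = bray_curtis(matrix, mot.infant_ids, transform=transform)
    if n == 1 or k == n:
        labels = np.arange(n) if k == n else np.zeros(n, dtype=int)
    else:
        z = linkage(dm.condensed(), method=linkage_method)
        labels = cut_tree(z, n_clusters=k).ravel()
    assignments = {s: int(c) + 1 for s, c in zip(mot.infant_ids, labels)}
    return ClusterAssignment(assignments=assignments, k=k)


def cluster_shared_abundance_test(
    assignment: ClusterAssignment,
    profiles: Iterable[SharedProfile],
) -> tuple[pd.DataFrame, list[PairwiseTestResult]]:
    """Per-cluster shared-abundance summaries plus all-pairs Steel-Dwass.

    Clusters with fewer than two members are excluded (with a warning); at
    least two usable clusters are required.
    """
    abundance = {p.infant_sample_id: p.shared_abundance for p in profiles}
    groups: list[np.ndarray] = []
    labels: list[str] = []
    rows = []
    for label in assignment.labels():
        members = assignment.members(label)
        values = np.asarray(
            [abundance[m] for m in members if m in abundance], dtype=float
        )
        if values.size < 2:
            logger.warning("cluster %s has <2 members; excluded from testing", label)
            continue
        groups.append(values)
        labels.append(str(label))
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        rows.append(
            {
                "cluster": label,
                "n": values.size,
                "median": med,
                "q1": q1,
                "q3": q3,
            }
        )
    if len(groups) < 2:
        raise ValueError("need at least two clusters with two or more members")
    pairwise = steel_dwass(groups, labels=labels)
    return pd.DataFrame(rows), pairwise


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    dm.to_frame().to_csv(path, sep="\t", index_label="sample_id")
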