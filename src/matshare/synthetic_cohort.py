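"""Paired mother-infant cohort simulator with planted, covariate-dependent
strain transmission.

Mothers draw one strain ASV per adult OTU from that OTU's strain pool, with
lognormal OTU abundances.  Each infant allocates an expected fraction
``tau_i`` of its community to an exact copy of its own mother's observed
profile, a fraction ``background_rate`` to environmental strains drawn at
random from the adult pools, and the remainder to infant-specific OTU strains.
Reads are drawn multinomially at truncated-normal depths.  Every planted
transmission is recorded in a :class:`TruthLedger`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .feature_tables import (
    MISSING,
    ROLE_INFANT,
    ROLE_MOTHER,
    CohortMetadata,
    FeatureTable,
    TaxonomyMap,
    TaxonRecord,
    relative_abundance,
)

MIN_DEPTH = 500

DEFAULT_FEEDING_EFFECTS: dict[str, float] = {
    "breast": 0.0,
    "mixed": 0.08,
    "formula": 0.15,
}

#: observed cohort frequencies used as default covariate draws
DEFAULT_FEEDING_FREQUENCIES: dict[str, float] = {
    "breast": 0.572,
    "mixed": 0.294,
    "formula": 0.135,
}
_SEX_FREQ = {"female": 0.516, "male": 0.484}
_AGE_FREQ = {"3mo": 0.254, "4mo": 0.701, "5mo+": 0.045}
_DELIVERY_FREQ = {"vaginal": 0.804, "cesarean": 0.196}
_ANTIBIOTICS_FREQ = {"none": 0.955, "within_1mo": 0.045}
_SMOKING_FREQ = {"no": 0.643, "yes": 0.357}


@dataclass(frozen=True)
class SimConfig:
    n_pairs: int = 100
    twin_fraction: float = 0.0
    n_adult_otus: int = 25
    strains_per_otu: int = 8
    n_infant_otus: int = 10
    adult_lognormal_mu: float = 0.0
    adult_lognormal_sigma: float = 1.0
    tau0: float = 0.3
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FEEDING_EFFECTS)
    )
    tau_jitter_sd: float = 0.0
    background_rate: float = 0.02
    depth_mean: float = 5500.0
    depth_sd: float = 1700.0
    feeding_frequencies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FEEDING_FREQUENCIES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if not 0.0 <= self.twin_fraction <= 1.0:
            raise ValueError("twin_fraction must lie in [0, 1]")
        if self.n_adult_otus < 1 or self.strains_per_otu < 1:
            raise ValueError("need at least one adult OTU with one strain")
        if self.n_infant_otus < 0:
            raise ValueError("n_infant_otus must be >= 0")
        if not 0.0 <= self.tau0 <= 1.0:
            raise ValueError("tau0 must lie in [0, 1]")
        if not 0.0 <= self.background_rate <= 1.0:
            raise ValueError("background_rate must lie in [0, 1]")
        shifts = list(self.covariate_effects.values()) or [0.0]
        if self.tau0 + max(shifts) > 1.0 + 1e-12:
            raise ValueError("tau0 + max covariate shift must not exceed 1")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.depth_sd < 0:
            raise ValueError("depth_sd must be >= 0")
        freq = dict(self.feeding_frequencies)
        if not freq or any(v < 0 for v in freq.values()) or sum(freq.values()) <= 0:
            raise ValueError("feeding_frequencies must be non-negative, not all zero")


@dataclass(frozen=True)
class InfantTruth:
    infant_sample_id: str
    mother_sample_id: str
    tau_target: float
    feeding: str
    transmitted_asvs: frozenset[str]


class TruthLedger:
    """Ground truth of a simulation: planted transmitted ASVs and the target
    transmitted fraction for every infant."""

    def __init__(self, records: Mapping[str, InfantTruth]):
        self._records = dict(records)

    def __len__(self) -> int:
        return len(self._records)

    def __getitem__(self, infant_sample_id: str) -> InfantTruth:
        return self._records[infant_sample_id]

    @property
    def infant_ids(self) -> list[str]:
        return list(self._records)

    @property
    def records(self) -> dict[str, InfantTruth]:
        return dict(self._records)


class SimulatedCohort(NamedTuple):
    table: FeatureTable
    metadata: CohortMetadata
    taxonomy: TaxonomyMap
    truth: TruthLedger


def _categorical(rng: np.random.Generator, freq: Mapping[str, float], n: int):
    levels = list(freq)
    p = np.asarray([freq[l] for l in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(levels, size=n, p=p)


def _depths(rng: np.random.Generator, config: SimConfig, n: int) -> np.ndarray:
    raw = rng.normal(config.depth_mean, config.depth_sd, size=n)
    return np.maximum(MIN_DEPTH, np.round(raw)).astype(np.int64)


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Simulate a paired cohort; deterministic (bit-identical) under a fixed seed."""
    rng = np.random.default_rng(config.seed)
    s = config.strains_per_otu
    n_infants = config.n_pairs
    n_twin_mothers = int(round(config.twin_fraction * config.n_pairs / 2.0))
    n_mothers = n_infants - n_twin_mothers
    if n_mothers < 1:
        raise ValueError("twin_fraction leaves no mothers")

    adult_otus = [f"AOTU{j:03d}" for j in range(config.n_adult_otus)]
    infant_otus = [f"IOTU{j:03d}" for j in range(config.n_infant_otus)]
    feature_ids: list[str] = []
    strain_rows: dict[tuple[str, int], int] = {}
    tax_records: dict[str, TaxonRecord] = {}
    for otu in adult_otus + infant_otus:
        for t in range(s):
            strain_rows[(otu, t)] = len(feature_ids)
            asv = f"{otu}.s{t:02d}"
            feature_ids.append(asv)
            tax_records[asv] = TaxonRecord(
                reference_id=otu, identity_pct=99.5, taxon_label=f"g__{otu}"
            )
    n_features = len(feature_ids)

    mother_ids = [f"M{j + 1:04d}" for j in range(n_mothers)]
    infant_ids = [f"I{i + 1:04d}" for i in range(n_infants)]
    # twins attach to the first mothers
    mother_of = [i if i < n_mothers else i - n_mothers for i in range(n_infants)]

    # --- mothers -----------------------------------------------------------
    mother_depths = _depths(rng, config, n_mothers)
    mother_strains = rng.integers(0, s, size=(n_mothers, config.n_adult_otus))
    mother_weights = rng.lognormal(
        config.adult_lognormal_mu,
        config.adult_lognormal_sigma,
        size=(n_mothers, config.n_adult_otus),
    )
    mother_counts = np.zeros((n_features, n_mothers), dtype=np.int64)
    for j in range(n_mothers):
        probs = np.zeros(n_features)
        w = mother_weights[j] / mother_weights[j].sum()
        for a, otu in enumerate(adult_otus):
            probs[strain_rows[(otu, int(mother_strains[j, a]))]] = w[a]
        mother_counts[:, j] = rng.multinomial(int(mother_depths[j]), probs)
    mother_observed = mother_counts / mother_counts.sum(axis=0, keepdims=True)

    # --- infant covariates -------------------------------------------------
    feeding = _categorical(rng, config.feeding_frequencies, n_infants)
    sex = _categorical(rng, _SEX_FREQ, n_infants)
    age = _categorical(rng, _AGE_FREQ, n_infants)
    delivery = _categorical(rng, _DELIVERY_FREQ, n_infants)
    antibiotics = _categorical(rng, _ANTIBIOTICS_FREQ, n_infants)
    smoking = _categorical(rng, _SMOKING_FREQ, n_infants)
    gestational = np.round(np.clip(rng.normal(39.3, 1.3, n_infants), 30, 42), 1)
    birth_weight = np.round(np.clip(rng.normal(3050, 400, n_infants), 1500, None))
    current_weight = np.round(
        np.clip(rng.normal(6734.7, 814.4, n_infants), 3000, None)
    )
    height = np.round(np.clip(rng.normal(63.5, 2.2, n_infants), 50, None), 1)

    # --- infants -----------------------------------------------------------
    infant_depths = _depths(rng, config, n_infants)
    infant_counts = np.zeros((n_features, n_infants), dtype=np.int64)
    truth: dict[str, InfantTruth] = {}
    for i in range(n_infants):
        tau = config.tau0 + float(
            dict(config.covariate_effects).get(str(feeding[i]), 0.0)
        )
        if config.tau_jitter_sd > 0:
            tau += rng.normal(0.0, config.tau_jitter_sd)
        tau = float(np.clip(tau, 0.0, 1.0))
        bg_mass = min(config.background_rate, 1.0 - tau)
        own_mass = max(0.0, 1.0 - tau - bg_mass)

        probs = np.zeros(n_features)
        mom = mother_of[i]
        if tau > 0:
            probs += tau * mother_observed[:, mom]
        if bg_mass > 0:
            w = rng.lognormal(
                config.adult_lognormal_mu,
                config.adult_lognormal_sigma,
                size=config.n_adult_otus,
            )
            w = bg_mass * w / w.sum()
            strains = rng.integers(0, s, size=config.n_adult_otus)
            for a, otu in enumerate(adult_otus):
                probs[strain_rows[(otu, int(strains[a]))]] += w[a]
        if own_mass > 0 and config.n_infant_otus > 0:
            w = rng.lognormal(
                config.adult_lognormal_mu,
                config.adult_lognormal_sigma,
                size=config.n_infant_otus,
            )
            w = own_mass * w / w.sum()
            strains = rng.integers(0, s, size=config.n_infant_otus)
            for a, otu in enumerate(infant_otus):
                probs[strain_rows[(otu, int(strains[a]))]] += w[a]
        total = probs.sum()
        if total <= 0:
            raise ValueError(
                "infeasible config: infant community has no mass "
                "(tau0 = 0, background_rate = 0 and no infant-specific OTUs)"
            )
        probs /= total
        infant_counts[:, i] = rng.multinomial(int(infant_depths[i]), probs)

        transmitted = (
            frozenset(
                feature_ids[r] for r in np.nonzero(mother_observed[:, mom] > 0)[0]
            )
            if tau > 0
            else frozenset()
        )
        truth[infant_ids[i]] = InfantTruth(
            infant_sample_id=infant_ids[i],
            mother_sample_id=mother_ids[mom],
            tau_target=tau,
            feeding=str(feeding[i]),
            transmitted_asvs=transmitted,
        )

    counts = np.hstack([mother_counts, infant_counts])
    sample_ids = mother_ids + infant_ids
    keep = counts.sum(axis=1) > 0  # drop never-observed strain ASVs
    table = FeatureTable(
        feature_ids=tuple(f for f, k in zip(feature_ids, keep) if k),
        sample_ids=tuple(sample_ids),
        counts=counts[keep, :],
    )
    # restrict planted sets to retained features (always a no-op by construction)
    retained = set(table.feature_ids)
    truth = {
        i: InfantTruth(
            infant_sample_id=t.infant_sample_id,
            mother_sample_id=t.mother_sample_id,
            tau_target=t.tau_target,
            feeding=t.feeding,
            transmitted_asvs=frozenset(t.transmitted_asvs & retained),
        )
        for i, t in truth.items()
    }

    rows = []
    for j, m in enumerate(mother_ids):
        rows.append(
            {
                "sample_id": m,
                "subject_id": f"S-{m}",
                "role": ROLE_MOTHER,
                "pair_id": MISSING,
                "sex": MISSING,
                "age_category": MISSING,
                "feeding": MISSING,
                "delivery": MISSING,
                "antibiotics": MISSING,
                "smoking": MISSING,
                "gestational_wk": MISSING,
                "birth_weight_g": MISSING,
                "current_weight_g": MISSING,
                "height_cm": MISSING,
            }
        )
    for i, sid in enumerate(infant_ids):
        rows.append(
            {
                "sample_id": sid,
                "subject_id": f"S-{sid}",
                "role": ROLE_INFANT,
                "pair_id": mother_ids[mother_of[i]],
                "sex": str(sex[i]),
                "age_category": str(age[i]),
                "feeding": str(feeding[i]),
                "delivery": str(delivery[i]),
                "antibiotics": str(antibiotics[i]),
                "smoking": str(smoking[i]),
                "gestational_wk": f"{gestational[i]:.1f}",
                "birth_weight_g": f"{birth_weight[i]:.0f}",
                "current_weight_g": f"{current_weight[i]:.0f}",
                "height_cm": f"{height[i]:.1f}",
            }
        )
    metadata = CohortMetadata(pd.DataFrame(rows))
    taxonomy = TaxonomyMap(
        {a: r for a, r in tax_records.items() if a in retained}
    )
    return SimulatedCohort(table, metadata, taxonomy, TruthLedger(truth))


def planted_shared_fraction(truth: TruthLedger, table: FeatureTable) -> pd.Series:
    """Realized relative abundance of the planted transmitted ASVs per infant."""
    rel = relative_abundance(table)
    feature_pos = {f: i for i, f in enumerate(table.feature_ids)}
    out: dict[str, float] = {}
    for infant in truth.infant_ids:
        rec = truth[infant]
        try:
            col = table.sample_index(infant)
        except KeyError:
            raise ValueError(
                f"infant {infant!r} from the truth ledger is absent from the table"
            ) from None
        missing = [a for a in rec.transmitted_asvs if a not in feature_pos]
        if missing:
            raise ValueError(
                f"transmitted ASVs absent from the table for {infant!r}: "
                f"{sorted(missing)[:3]}..."
            )
        rows = [feature_pos[a] for a in rec.transmitted_asvs]
        out[infant] = float(rel[rows, col].sum()) if rows else 0.0
    return pd.Series(out, dtype=float)


def write_truth(truth: TruthLedger, path: str | Path) -> None:
    rows = [
        {
            "infant_sample_id": r.infant_sample_id,
            "mother_sample_id": r.mother_sample_id,
            "tau_target": r.tau_target,
            "feeding": r.feeding,
            "transmitted_asvs": ",".join(sorted(r.transmitted_asvs)),
        }
        for r in (truth[i] for i in truth.infant_ids)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> TruthLedger:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records: dict[str, InfantTruth] = {}
    for row in frame.itertuples(index=False):
        asvs = frozenset(a for a in str(row.transmitted_asvs).split(",") if a)
        records[row.infant_sample_id] = InfantTruth(
            infant_sample_id=row.infant_sample_id,
            mother_sample_id=row.mother_sample_id,
            tau_target=float(row.tau_target),
            feeding=row.feeding,
            transmitted_asvs=asvs,
        )
    return TruthLedger(records)
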