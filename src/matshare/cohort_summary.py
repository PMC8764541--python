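"""Clinical-variable derivations and Table-1-style cohort summaries.

Percentages use per-variable non-missing denominators and half-up rounding to
one decimal place.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
import pandas as pd

from .feature_tables import CohortMetadata

#: printed current-weight cutoffs (mean -/+ 1 SD of the study cohort, grams)
PAPER_WEIGHT_LOW_CUT = 5920.3
PAPER_WEIGHT_HIGH_CUT = 7549.1

KAUP_LOW = "<16"
KAUP_MID = "16-18"
KAUP_HIGH = ">=18"

_CANONICAL_LEVELS: Mapping[str, list[str]] = {
    "sex": ["female", "male"],
    "age_category": ["3mo", "4mo", "5mo+"],
    "feeding": ["breast", "mixed", "formula"],
    "delivery": ["vaginal", "cesarean"],
    "antibiotics": ["none", "within_1mo"],
    "smoking": ["no", "yes"],
    "gestational": [">=37wk", "<37wk"],
    "birth_weight": [">=2500g", "<2500g"],
    "current_weight": ["low", "normal", "high"],
    "kaup": [KAUP_LOW, KAUP_MID, KAUP_HIGH],
}


def round_half_up(value: float | Decimal, ndigits: int = 1) -> float:
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def _pct(count: int, denominator: int, ndigits: int = 1) -> float:
    quantum = Decimal(1).scaleb(-ndigits)
    exact = Decimal(count) * 100 / Decimal(denominator)
    return float(exact.quantize(quantum, rounding=ROUND_HALF_UP))


def kaup_index(weight_g: float | None, height_cm: float | None) -> float:
    """Infant body-mass index: weight(g) / height(cm)^2 x 10."""
    if weight_g is None or height_cm is None:
        return math.nan
    if isinstance(weight_g, float) and math.isnan(weight_g):
        return math.nan
    if isinstance(height_cm, float) and math.isnan(height_cm):
        return math.nan
    if weight_g <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    return weight_g / height_cm**2 * 10.0


def kaup_category(index: float) -> str | None:
    if index is None or math.isnan(index):
        return None
    if index < 16.0:
        return KAUP_LOW
    if index < 18.0:
        return KAUP_MID
    return KAUP_HIGH


def weight_category(
    weight_g: float | None,
    mean: float | None = None,
    sd: float | None = None,
    *,
    low_cut: float | None = None,
    high_cut: float | None = None,
) -> str | None:
    """Classify a weight as low (< mean - SD), normal (within +/-1 SD,
    boundaries inclusive) or high (> mean + SD).

    Either (mean, sd) or explicit (low_cut, high_cut) thresholds must be given.
    """
    if weight_g is None or (isinstance(weight_g, float) and math.isnan(weight_g)):
        return None
    if low_cut is None or high_cut is None:
        if mean is None or sd is None:
            raise ValueError("provide (mean, sd) or explicit cutoffs")
        if sd <= 0:
            raise ValueError("sd must be positive")
        low_cut, high_cut = mean - sd, mean + sd
    if weight_g < low_cut:
        return "low"
    if weight_g > high_cut:
        return "high"
    return "normal"


def gestational_category(weeks: float | None) -> str | None:
    if weeks is None or (isinstance(weeks, float) and math.isnan(weeks)):
        return None
    return ">=37wk" if weeks >= 37 else "<37wk"


def birth_weight_category(grams: float | None) -> str | None:
    if grams is None or (isinstance(grams, float) and math.isnan(grams)):
        return None
    return ">=2500g" if grams >= 2500 else "<2500g"


def infant_factor_frame(
    metadata: CohortMetadata,
    *,
    weight_thresholds: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Categorical clinical factors per infant (derived categories included).

    Current-weight thresholds default to the cohort mean +/- 1 SD of the
    non-missing weights; pass ``weight_thresholds=(low, high)`` to override
    (e.g. the printed study cutoffs).
    """
    idx = metadata.infant_ids
    out = pd.DataFrame(index=idx)
    for col in ("sex", "age_category", "feeding", "delivery", "antibiotics", "smoking"):
        if col in metadata.frame.columns:
            out[col] = metadata.covariate(col).reindex(idx)
    numeric = {}
    for col in ("gestational_wk", "birth_weight_g", "current_weight_g", "height_cm"):
        if col in metadata.frame.columns:
            numeric[col] = pd.to_numeric(
                metadata.covariate(col).reindex(idx), errors="coerce"
            )
    if "gestational_wk" in numeric:
        out["gestational"] = numeric["gestational_wk"].map(gestational_category)
    if "birth_weight_g" in numeric:
        out["birth_weight"] = numeric["birth_weight_g"].map(birth_weight_category)
    if "current_weight_g" in numeric:
        weights = numeric["current_weight_g"]
        if weight_thresholds is not None:
            low, high = weight_thresholds
        else:
            observed = weights.dropna()
            if len(observed) >= 2 and observed.std(ddof=1) > 0:
                low = observed.mean() - observed.std(ddof=1)
                high = observed.mean() + observed.std(ddof=1)
            else:
                low = high = None
        if low is not None:
            out["current_weight"] = weights.map(
                lambda w: weight_category(w, low_cut=low, high_cut=high)
            )
        if "height_cm" in numeric:
            kaup = [
                kaup_index(w, h) if not (pd.isna(w) or pd.isna(h)) else math.nan
                for w, h in zip(weights, numeric["height_cm"])
            ]
            out["kaup"] = [kaup_category(k) for k in kaup]
    return out


def summarize_cohort(
    metadata: CohortMetadata,
    *,
    weight_thresholds: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Table-1-style frequency table over infants.

    One row per (variable, level): count, non-missing denominator and the
    percentage count/denominator*100 rounded half-up to one decimal.
    Variables with no non-missing values are omitted.
    """
    factors = infant_factor_frame(metadata, weight_thresholds=weight_thresholds)
    rows = []
    for variable in factors.columns:
        values = factors[variable]
        non_missing = values[values.notna() & (values.astype(str) != "")]
        denominator = len(non_missing)
        if denominator == 0:
            continue
        counts = non_missing.value_counts()
        canonical = _CANONICAL_LEVELS.get(variable)
        if canonical:
            levels = [l for l in canonical if l in counts.index] + sorted(
                set(counts.index) - set(canonical)
            )
        else:
            levels = sorted(counts.index)
        for level in levels:
            c = int(counts[level])
            rows.append(
                {
                    "variable": variable,
                    "level": level,
                    "count": c,
                    "denominator": denominator,
                    "pct": _pct(c, denominator),
                }
            )
    return pd.DataFrame(rows)


def summary_markdown(summary: pd.DataFrame) -> str:
    """Render a cohort summary as a small Markdown table."""
    lines = ["| variable | level | n (%) |", "| --- | --- | --- |"]
    for row in summary.itertuples(index=False):
        lines.append(f"| {row.variable} | {row.level} | {row.count} ({row.pct}) |")
    return "\n".join(lines) + "\n"


def get_percentage(summary: pd.DataFrame, variable: str, level: str) -> float:
    """Convenience lookup of one percentage from a cohort summary."""
    match = summary[(summary["variable"] == variable) & (summary["level"] == level)]
    if match.empty:
        raise KeyError(f"no summary row for {variable!r} / {level!r}")
    return float(match["pct"].iloc[0])
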