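"""SD-based category scores and the cumulative heat vulnerability index.

Each standardized factor score is binned into six integer categories by its
distance from the mean in SD units (1 = at least 2 SD below the mean up to
6 = at least 2 SD above), and the cumulative index for a county is the sum of
its category scores over the retained factors: with four factors the index
ranges from 4 to 24, higher meaning more vulnerable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .factor_engine import FactorScores

logger = logging.getLogger(__name__)

#: Category boundaries in SD units. Outer categories are closed (>= 2 SD);
#: z = 0 falls in category 4 so the central categories straddle the mean.
#: bins: 1: z <= -2 | 2: -2 < z <= -1 | 3: -1 < z < 0 | 4: 0 <= z < 1
#:       5: 1 <= z < 2 | 6: z >= 2
_BOUNDARIES = (-2.0, -1.0, 0.0, 1.0, 2.0)


class ContractError(ValueError):
    """Inputs violate an index-construction precondition."""


class AlignmentError(ValueError):
    """The urban and rural indices do not cover a common county set."""


@dataclass
class VulnerabilityIndex:
    """Per-county integer category scores and their cumulative sum."""

    county_ids: list[str]
    categories: np.ndarray  # n x k, entries in 1..6
    cumulative: np.ndarray  # n, row sums
    stratum: str

    @property
    def k(self) -> int:
        return self.categories.shape[1]

    def to_frame(self, area_ids: list[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            self.categories,
            columns=[f"factor_{j+1}_category" for j in range(self.k)],
        )
        df.insert(0, "county_id", self.county_ids)
        if area_ids is not None:
            df.insert(1, "area_id", area_ids)
        df["cumulative_index"] = self.cumulative
        df["stratum"] = self.stratum
        return df


@dataclass
class IndexSummary:
    """Stratified summaries of the cumulative index."""

    median: dict[str, float]
    range: dict[str, tuple[int, int]]
    above_mean_all_factors: dict[str, int]
    per_area_mean: dict[str, dict[str, float]]
    matched_counties: list[str]  # equal urban and rural cumulative values
    unmatched_counties: dict[str, list[str]]  # present in only one stratum


def bin_score(z: float | np.ndarray) -> int | np.ndarray:
    """Map standardized score(s) to the six SD-based integer categories.

    Boundary convention: the outer bounds are closed (z = -2 -> 1, z = 2 -> 6);
    negative inner boundaries are assigned outward (z = -1 -> 2) and
    non-negative boundaries upward (z = 0 -> 4, z = 1 -> 5).
    """
    arr = np.asarray(z, dtype=float)
    if not np.isfinite(arr).all():
        raise ContractError("factor scores must be finite")
    # side='left' puts z == -2 and z == -1 in the lower category; shifting the
    # non-negative boundaries to side='right' puts z == 0, 1, 2 in the upper one
    cats = np.searchsorted(_BOUNDARIES, arr, side="left") + 1
    upper = np.searchsorted(_BOUNDARIES, arr, side="right") + 1
    cats = np.where(arr >= 0.0, upper, cats)
    on_inner_boundary = np.isin(arr, (-1.0, 0.0, 1.0))
    if on_inner_boundary.any():
        logger.info(
            "%d score(s) fell exactly on an inner category boundary",
            int(on_inner_boundary.sum()),
        )
    if np.isscalar(z) or np.ndim(z) == 0:
        return int(cats)
    return cats.astype(int)


def build_index(scores: FactorScores, stratum: str = "urban") -> VulnerabilityIndex:
    """Bin each factor score and sum the integer categories per county."""
    if not scores.standardized:
        raise ContractError("index construction requires standardized factor scores")
    categories = bin_score(scores.scores)
    return VulnerabilityIndex(
        county_ids=list(scores.county_ids),
        categories=categories,
        cumulative=categories.sum(axis=1),
        stratum=stratum,
    )


def _summary_parts(
    index: VulnerabilityIndex,
    scores: FactorScores,
    area_ids: list[str] | None,
) -> tuple[float, tuple[int, int], int, dict[str, float]]:
    median = float(np.median(index.cumulative))
    rng = (int(index.cumulative.min()), int(index.cumulative.max()))
    # standardized scores have mean exactly 0, so "above the mean" is score > 0
    above = int(np.all(scores.scores > 0.0, axis=1).sum())
    per_area: dict[str, float] = {}
    if area_ids is not None:
        s = pd.Series(index.cumulative, index=area_ids)
        per_area = s.groupby(level=0).mean().to_dict()
    return median, rng, above, per_area


def summarize_index(
    urban: VulnerabilityIndex,
    rural: VulnerabilityIndex,
    urban_scores: FactorScores,
    rural_scores: FactorScores,
    area_ids: dict[str, str] | None = None,
) -> IndexSummary:
    """Cross-stratum summary: medians, ranges, above-mean counts, area means,
    and the counties whose urban and rural cumulative values coincide.

    ``area_ids`` maps county_id to its prefecture-level area. Counties present
    in only one stratum are reported under ``unmatched_counties`` rather than
    dropped silently.
    """
    if list(urban.county_ids) != list(urban_scores.county_ids) or list(
        rural.county_ids
    ) != list(rural_scores.county_ids):
        raise AlignmentError("indices and scores must cover identical county lists")

    def areas_for(ids: list[str]) -> list[str] | None:
        if area_ids is None:
            return None
        try:
            return [area_ids[c] for c in ids]
        except KeyError as e:
            raise AlignmentError(f"county {e.args[0]!r} missing from area mapping") from None

    med_u, rng_u, above_u, area_u = _summary_parts(urban, urban_scores, areas_for(urban.county_ids))
    med_r, rng_r, above_r, area_r = _summary_parts(rural, rural_scores, areas_for(rural.county_ids))

    cum_u = dict(zip(urban.county_ids, urban.cumulative))
    cum_r = dict(zip(rural.county_ids, rural.cumulative))
    shared = [c for c in urban.county_ids if c in cum_r]
    matched = [c for c in shared if cum_u[c] == cum_r[c]]
    unmatched = {
        "urban_only": [c for c in urban.county_ids if c not in cum_r],
        "rural_only": [c for c in rural.county_ids if c not in cum_u],
    }
    if unmatched["urban_only"] or unmatched["rural_only"]:
        logger.warning(
            "county sets differ between strata: %d urban-only, %d rural-only",
            len(unmatched["urban_only"]),
            len(unmatched["rural_only"]),
        )
    return IndexSummary(
        median={"urban": med_u, "rural": med_r},
        range={"urban": rng_u, "rural": rng_r},
        above_mean_all_factors={"urban": above_u, "rural": above_r},
        per_area_mean={"urban": area_u, "rural": area_r},
        matched_counties=matched,
        unmatched_counties=unmatched,
    )


def write_index(
    index: VulnerabilityIndex,
    path: str | Path,
    *,
    area_ids: list[str] | None = None,
    delimiter: str = ",",
) -> None:
    index.to_frame(area_ids).to_csv(path, sep=delimiter, index=False)


def export_geojson(
    index: VulnerabilityIndex,
    features_path: str | Path,
    out_path: str | Path,
    *,
    key_property: str = "county_id",
) -> int:
    """Join cumulative index values onto a GeoJSON FeatureCollection.

    Each feature whose ``key_property`` matches a county id gains an ``hvi``
    property; geometry passes through untouched. Returns the number of
    features joined. No polygon data is bundled with the package.
    """
    with open(features_path) as f:
        fc = json.load(f)
    if fc.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    cum = dict(zip(index.county_ids, (int(v) for v in index.cumulative)))
    joined = 0
    for feat in fc.get("features", []):
        key = feat.get("properties", {}).get(key_property)
        if key in cum:
            feat["properties"]["hvi"] = cum[key]
            joined += 1
    with open(out_path, "w") as f:
        json.dump(fc, f)
    if joined < len(cum):
        logger.warning("%d counties had no matching feature", len(cum) - joined)
    return joined
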