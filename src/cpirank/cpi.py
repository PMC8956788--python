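"""The Conservation Priority Index (CPI) and priority classification.

For a lake-country unit with conservation score Cwt, relative rarity RRw
and national surface area Aw (km²),

    CPI = (Cwt × RRw) / (Aw × k)

where k is a scaling constant (default 8, the number of distinct weight
levels among the considered Red List categories).  Surface area enters as
a penalty — a proxy for the cost of conserving the waterbody and for the
greater ecological substitutability available to species in large
systems — so the index favours small lakes holding rare, threatened
species.  CPI is 0 exactly when RRw is 0 (in particular for the only
assessed lake of a country).

Units are classified high priority when CPI strictly exceeds a threshold
(default 0.5), low otherwise; a CPI exactly at the threshold is low,
since the high class is defined by a strict inequality.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .occurrence import LakeRegistry

__all__ = ["compute_cpi", "classify_priority", "rank_units"]

logger = logging.getLogger(__name__)

DEFAULT_K = 8.0
DEFAULT_THRESHOLD = 0.5


def compute_cpi(
    scores: pd.DataFrame,
    rarities: pd.DataFrame,
    registry: LakeRegistry,
    k: float = DEFAULT_K,
) -> pd.DataFrame:
    """Join per-unit scores and rarities and compute CPI and richness density.

    Parameters
    ----------
    scores:
        Output of :func:`cpirank.iucn.conservation_score`.
    rarities:
        Output of :func:`cpirank.rarity.unit_rarity`.
    registry:
        Supplies each unit's country-specific surface area.  Units whose
        area is missing or nonpositive are excluded with a logged
        warning, mirroring the discard of lakes without a determinable
        area upstream.
    k:
        Positive scaling constant.  Doubling it exactly halves every CPI
        and leaves the ranking unchanged.

    Returns a table with columns ``lake, country, richness, cwt, rrw,
    area_km2, cpi, richness_density`` (CPI in units of per km²).
    """
    if k <= 0:
        raise ValueError(f"scaling constant k must be positive, got {k}")
    merged = scores.merge(rarities, on=["lake", "country"], how="inner", validate="1:1")

    areas = []
    keep = []
    for row in merged.itertuples(index=False):
        entry = registry.lookup(row.lake, row.country)
        if entry is None or entry.area_km2 <= 0:
            logger.warning(
                "excluding unit (%s, %s): missing or nonpositive surface area",
                row.lake,
                row.country,
            )
            keep.append(False)
            areas.append(np.nan)
        else:
            keep.append(True)
            areas.append(entry.area_km2)
    merged["area_km2"] = areas
    merged = merged.loc[keep].reset_index(drop=True)

    merged["cpi"] = (merged["cwt"] * merged["rrw"]) / (merged["area_km2"] * k)
    merged["richness_density"] = merged["richness"] / merged["area_km2"]
    cols = ["lake", "country", "richness", "cwt", "rrw", "area_km2", "cpi",
            "richness_density"]
    return merged[cols]


def classify_priority(
    results: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Attach the high/low priority class: high iff cpi > threshold."""
    out = results.copy()
    out["priority_class"] = np.where(out["cpi"] > threshold, "high", "low")
    return out


def rank_units(results: pd.DataFrame) -> pd.DataFrame:
    """Deterministic priority league table.

    Descending CPI; ties broken by descending Cwt, then ascending area,
    then lake name.
    """
    if results.empty:
        return results.copy()
    return results.sort_values(
        ["cpi", "cwt", "area_km2", "lake"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
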