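"""IUCN Red List category handling and the per-unit conservation score.

Every species carries a threat category; the score weights are largest
for extinct categories and smallest for least concern:

    ET = 7, EXw = 6, CR = 5, DD = 5, NE = 5, EN = 4, VU = 3, NT = 2, LC = 1.

Data-deficient (DD) and not-evaluated (NE) species are deliberately
weighted at the critically-endangered level: a species whose status is
unknown is treated as high-concern until assessed, so unlisted species
default to NE rather than being dropped or erroring.

The conservation score of a lake-country unit is

    Cwt = sum over categories of (species count in category) x (weight),

an integer between the unit's richness (all LC) and 7x richness.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import InputError, SchemaError
from .occurrence import LakeCountryUnit

__all__ = [
    "CATEGORIES",
    "DEFAULT_WEIGHTS",
    "normalize_status",
    "load_status_table",
    "conservation_score",
]

#: Canonical categories, most to least threatened.  ET/EXw are the extinct
#: and extinct-in-the-wild categories (standard codes EX/EW are accepted
#: as aliases).
CATEGORIES: tuple[str, ...] = ("ET", "EXw", "CR", "DD", "NE", "EN", "VU", "NT", "LC")

DEFAULT_WEIGHTS: dict[str, int] = {
    "ET": 7,
    "EXw": 6,
    "CR": 5,
    "DD": 5,
    "NE": 5,
    "EN": 4,
    "VU": 3,
    "NT": 2,
    "LC": 1,
}

# Legacy and variant Red List codes seen in the wild.
_ALIASES: dict[str, str] = {
    "EX": "ET",
    "EXTINCT": "ET",
    "EW": "EXw",
    "EXTINCT IN THE WILD": "EXw",
    "LR/NT": "NT",
    "LR/CD": "NT",
    "LR/LC": "LC",
    "CRITICALLY ENDANGERED": "CR",
    "ENDANGERED": "EN",
    "VULNERABLE": "VU",
    "NEAR THREATENED": "NT",
    "LEAST CONCERN": "LC",
    "DATA DEFICIENT": "DD",
    "NOT EVALUATED": "NE",
}

_CANONICAL_BY_FOLD = {c.casefold(): c for c in CATEGORIES}


def normalize_status(raw_code: str | None) -> str:
    """Map a raw status string onto a canonical category.

    Total function: legacy codes such as ``LR/nt`` become NT, the standard
    extinct codes EX/EW become ET/EXw, and anything unknown or missing
    becomes NE (not evaluated).
    """
    if raw_code is None:
        return "NE"
    text = str(raw_code).strip()
    if not text:
        return "NE"
    canonical = _CANONICAL_BY_FOLD.get(text.casefold())
    if canonical is not None:
        return canonical
    return _ALIASES.get(text.upper(), "NE")


def load_status_table(
    source: str | Path | pd.DataFrame, delimiter: str = ","
) -> dict[str, str]:
    """Read a species -> category table (columns ``species_name, category``).

    Raw category strings are normalized on the way in.  Also accepts
    Darwin-Core-ish header variants (``scientificName``, ``iucn_status``).
    """
    if isinstance(source, pd.DataFrame):
        frame = source
    else:
        try:
            frame = pd.read_csv(source, sep=delimiter, dtype=str)
        except (OSError, ValueError) as exc:
            raise InputError(f"cannot read status table {source}: {exc}") from exc
    species_col = next(
        (c for c in ("species_name", "species", "scientificName") if c in frame.columns),
        None,
    )
    cat_col = next(
        (c for c in ("category", "iucn_status", "status") if c in frame.columns), None
    )
    if species_col is None:
        raise SchemaError("status table missing mandatory column: species_name")
    if cat_col is None:
        raise SchemaError("status table missing mandatory column: category")
    return {
        str(row[species_col]).strip(): normalize_status(row[cat_col])
        for _, row in frame.iterrows()
        if str(row[species_col]).strip()
    }


def conservation_score(
    units: Sequence[LakeCountryUnit],
    status: Mapping[str, str],
    weights: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-unit category counts and conservation score Cwt.

    Parameters
    ----------
    units:
        Lake-country units with distinct species sets.
    status:
        species -> canonical category; species absent from the mapping
        default to NE.
    weights:
        Category weights; the shipped defaults implement the standard
        7..1 assignment and can be overridden to consider a different
        category set.

    Returns a table with columns ``lake, country, richness,
    n_<category>..., cwt``; the category counts sum to richness.
    """
    w = dict(DEFAULT_WEIGHTS if weights is None else weights)
    rows = []
    for unit in units:
        counts: Counter[str] = Counter(
            normalize_status(status.get(species)) for species in unit.species
        )
        cwt = sum(counts[c] * w[c] for c in counts)
        row = {"lake": unit.lake, "country": unit.country, "richness": unit.richness}
        row.update({f"n_{c}": counts.get(c, 0) for c in CATEGORIES})
        row["cwt"] = cwt
        rows.append(row)
    columns = ["lake", "country", "richness", *(f"n_{c}" for c in CATEGORIES), "cwt"]
    return pd.DataFrame(rows, columns=columns)
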