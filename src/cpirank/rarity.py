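"""Species relative rarity (SRR) and waterbody relative rarity (RRw).

Rarity is scored within a country: a species found in few of the
country's assessed lakes is rare there, one found in every assessed lake
is not rare at all.  For a species present in Ws of the country's Wt
assessed lakes,

    SRR = 1 - Ws / Wt

so SRR is 0 for a ubiquitous species and approaches 1 for a species
confined to a single lake among many.  A lake's relative rarity RRw is
the plain sum of SRR over its distinct species.  With only one assessed
lake in a country every SRR — and hence every RRw and downstream priority
index — is exactly 0: no within-country comparison is possible.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Sequence

import pandas as pd

from .occurrence import LakeCountryUnit

__all__ = ["species_rarity", "unit_rarity"]


def species_rarity(units: Sequence[LakeCountryUnit]) -> pd.DataFrame:
    """Per-(species, country) relative rarity.

    Wt counts the distinct lakes that survived filtering in the country
    (assessed lakes), not all lakes known to exist there.

    Returns a table with columns ``species_name, country, ws, wt, srr``.
    """
    lakes_per_country: dict[str, set[str]] = defaultdict(set)
    occupancy: Counter[tuple[str, str]] = Counter()
    for unit in units:
        lakes_per_country[unit.country].add(unit.lake)
        for species in unit.species:
            occupancy[(species, unit.country)] += 1

    rows = []
    for (species, country), ws in sorted(occupancy.items()):
        wt = len(lakes_per_country[country])
        rows.append(
            {
                "species_name": species,
                "country": country,
                "ws": ws,
                "wt": wt,
                "srr": 1.0 - ws / wt,
            }
        )
    return pd.DataFrame(rows, columns=["species_name", "country", "ws", "wt", "srr"])


def unit_rarity(
    units: Sequence[LakeCountryUnit], rarities: pd.DataFrame
) -> pd.DataFrame:
    """Per-unit relative rarity: RRw = sum of SRR over the unit's species.

    Returns a table with columns ``lake, country, rrw``.  A unit whose
    every species occurs in all the country's assessed lakes has RRw 0.
    """
    lookup = {
        (row.species_name, row.country): row.srr
        for row in rarities.itertuples(index=False)
    }
    rows = []
    for unit in units:
        total = 0.0
        for species in sorted(unit.species):
            key = (species, unit.country)
            if key not in lookup:
                raise RuntimeError(
                    f"internal error: no rarity entry for species {species!r} "
                    f"in {unit.country!r}"
                )
            total += lookup[key]
        rows.append({"lake": unit.lake, "country": unit.country, "rrw": total})
    return pd.DataFrame(rows, columns=["lake", "country", "rrw"])
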