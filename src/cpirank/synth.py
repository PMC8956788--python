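"""Synthetic occurrence datasets with the structure the index assumes.

The generator emulates the statistical shape of continental-scale lake
occurrence data: many countries, a right-skewed (log-normal) lake-area
distribution, a species–area relationship (per-lake richness roughly
proportional to area^z with multiplicative noise), a mix of
single-lake-endemic and widespread species within each country, and a
Red List category mix dominated by least-concern species (about two
thirds LC).  No species crosses a country border by default, matching
the country-scoped rarity definition.

Also ships the small hand-computable fixture used throughout the tests:
two lakes in one country whose rarity, conservation-score and priority
values can be chained by hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = ["SyntheticConfig", "generate", "worked_fixture", "inject_noise"]

#: Category mix observed in large lake-fish occurrence compilations:
#: about two thirds least concern, with not-evaluated and data-deficient
#: species forming the next largest shares and extinct species very rare.
DEFAULT_IUCN_MIX: dict[str, float] = {
    "LC": 0.669,
    "NE": 0.110,
    "DD": 0.084,
    "CR": 0.048,
    "VU": 0.041,
    "EN": 0.024,
    "NT": 0.021,
    "ET": 0.002,
    "EXw": 0.001,
}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic community generator.

    Parameters
    ----------
    n_countries, lakes_per_country:
        Political structure; lake counts are drawn uniformly in the
        inclusive range.
    area_lognormal_mu, area_lognormal_sigma:
        log-normal surface-area distribution in km² (defaults give a
        median around 55 km² with a heavy right tail — many modest lakes
        and a few great ones, the size structure typical of continental
        lake registries).
    richness_coefficient, richness_area_exponent, richness_noise_sigma:
        Species–area rule: per-lake target richness is
        ``c * area**z`` with log-normal multiplicative noise.
    endemism_fraction:
        Share of species confined to a single lake; the rest are
        widespread within their country (a random subset of ≥ 2 lakes).
    iucn_mix:
        Category probabilities (normalized internally).
    species_pool_size:
        Hard cap on total species; an infeasible combination of richness
        targets and pool size raises :class:`ConfigError`.
    """

    n_countries: int = 8
    lakes_per_country: tuple[int, int] = (4, 12)
    area_lognormal_mu: float = 4.0
    area_lognormal_sigma: float = 1.5
    species_pool_size: int = 4000
    richness_coefficient: float = 5.0
    richness_area_exponent: float = 0.3
    richness_noise_sigma: float = 0.2
    endemism_fraction: float = 0.3
    iucn_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_IUCN_MIX))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ConfigError("n_countries must be >= 1")
        lo, hi = self.lakes_per_country
        if lo < 1 or hi < lo:
            raise ConfigError(f"invalid lakes_per_country range {self.lakes_per_country}")
        if self.species_pool_size < 1:
            raise ConfigError("species_pool_size must be >= 1")
        if self.richness_area_exponent < 0:
            raise ConfigError("richness_area_exponent must be >= 0")
        if not 0 <= self.endemism_fraction <= 1:
            raise ConfigError("endemism_fraction must lie in [0, 1]")
        total = float(sum(self.iucn_mix.values()))
        if total <= 0 or any(p < 0 for p in self.iucn_mix.values()):
            raise ConfigError("iucn_mix must be nonnegative with positive sum")


def _country_names(n: int) -> list[str]:
    return [f"Country{i + 1:02d}" for i in range(n)]


def generate(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw a full synthetic dataset.

    Returns ``(occurrences, statuses, registry)`` as data frames in the
    same CSV schemas the ingestion pipeline consumes (Darwin-Core-like
    occurrence columns; ``species_name, category``;
    ``canonical_name, country, area_km2, synonyms``).  Fully determined
    by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    occ_rows: list[dict] = []
    reg_rows: list[dict] = []
    status_rows: list[dict] = []
    n_species_total = 0

    for ci, country in enumerate(_country_names(config.n_countries)):
        lo, hi = config.lakes_per_country
        n_lakes = int(rng.integers(lo, hi + 1))
        areas = rng.lognormal(config.area_lognormal_mu, config.area_lognormal_sigma, n_lakes)
        lakes = [f"Lake {country}-{j + 1:02d}" for j in range(n_lakes)]
        lat0 = float(rng.uniform(-30, 30))
        lon0 = float(rng.uniform(-20, 50))
        coords = [
            (lat0 + float(rng.normal(0, 2)), lon0 + float(rng.normal(0, 2)))
            for _ in range(n_lakes)
        ]
        for lake, area in zip(lakes, areas):
            reg_rows.append(
                {
                    "canonical_name": lake,
                    "country": country,
                    "area_km2": round(float(area), 4),
                    "synonyms": "",
                }
            )

        noise = rng.lognormal(0.0, config.richness_noise_sigma, n_lakes)
        targets = np.maximum(
            1,
            np.rint(
                config.richness_coefficient
                * areas**config.richness_area_exponent
                * noise
            ).astype(int),
        )
        quotas = targets.copy()
        si = 0
        while quotas.sum() > 0:
            candidates = np.flatnonzero(quotas > 0)
            endemic = (
                rng.random() < config.endemism_fraction or len(candidates) < 2
            )
            weights = quotas[candidates] / quotas[candidates].sum()
            if endemic:
                chosen = [int(rng.choice(candidates, p=weights))]
            else:
                k = int(rng.integers(2, n_lakes + 1))
                k = min(k, len(candidates))
                chosen = [
                    int(c)
                    for c in rng.choice(candidates, size=k, replace=False, p=weights)
                ]
            si += 1
            n_species_total += 1
            if n_species_total > config.species_pool_size:
                raise ConfigError(
                    "species_pool_size too small for the requested richness "
                    f"targets (needed more than {config.species_pool_size})"
                )
            species = f"Genus{ci + 1:02d} species{si:04d}"
            status_rows.append(
                {
                    "species_name": species,
                    "category": _draw_category(rng, config.iucn_mix),
                }
            )
            for j in chosen:
                quotas[j] = max(0, quotas[j] - 1)
                lat, lon = coords[j]
                occ_rows.append(
                    {
                        "scientificName": species,
                        "country": country,
                        "waterBody": lakes[j],
                        "decimalLatitude": round(lat, 4),
                        "decimalLongitude": round(lon, 4),
                        "locality": "",
                    }
                )

    occurrences = pd.DataFrame(
        occ_rows,
        columns=[
            "scientificName",
            "country",
            "waterBody",
            "decimalLatitude",
            "decimalLongitude",
            "locality",
        ],
    )
    statuses = pd.DataFrame(status_rows, columns=["species_name", "category"])
    registry = pd.DataFrame(
        reg_rows, columns=["canonical_name", "country", "area_km2", "synonyms"]
    )
    return occurrences, statuses, registry


def _draw_category(rng: np.random.Generator, mix: Mapping[str, float]) -> str:
    cats = list(mix.keys())
    probs = np.asarray([mix[c] for c in cats], float)
    probs = probs / probs.sum()
    return str(rng.choice(cats, p=probs))


def worked_fixture() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """The two-lake, one-country hand-computable fixture.

    Lake Alpha (10 km²) holds species alpha (LC) and beta (CR); Lake Beta
    (2 km²) holds beta (CR), gamma (EN) and delta (absent from the status
    table, hence defaulting to NE).  Hand chain: SRR(alpha) = SRR(gamma)
    = SRR(delta) = 0.5, SRR(beta) = 0; RRw = 0.5 and 1.0; Cwt = 6 and 14;
    CPI = 0.0375 and 0.875; classes low and high at the default 0.5
    threshold.
    """
    occurrences = pd.DataFrame(
        {
            "scientificName": [
                "Synthofish alpha",
                "Synthofish beta",
                "Synthofish beta",
                "Synthofish gamma",
                "Synthofish delta",
            ],
            "country": ["Freedonia"] * 5,
            "waterBody": [
                "Lake Alpha",
                "Lake Alpha",
                "Lake Beta",
                "Lake Beta",
                "Lake Beta",
            ],
            "decimalLatitude": [1.0, 1.0, 2.0, 2.0, 2.0],
            "decimalLongitude": [30.0, 30.0, 31.0, 31.0, 31.0],
            "locality": [""] * 5,
        }
    )
    statuses = pd.DataFrame(
        {
            "species_name": ["Synthofish alpha", "Synthofish beta", "Synthofish gamma"],
            "category": ["LC", "CR", "EN"],
        }
    )
    registry = pd.DataFrame(
        {
            "canonical_name": ["Lake Alpha", "Lake Beta"],
            "country": ["Freedonia", "Freedonia"],
            "area_km2": [10.0, 2.0],
            "synonyms": ["lac Alpha", ""],
        }
    )
    return occurrences, statuses, registry


def inject_noise(
    occurrences: pd.DataFrame,
    frac_spp_epithets: float = 0.0,
    frac_missing_waterbody: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Append corrupted copies of rows so the cleaning filters have work.

    For each corruption kind, ``round(frac * n)`` source rows are sampled
    (without replacement) and re-emitted corrupted: species truncated to
    ``"Genus spp."`` for the epithet corruption; waterbody, coordinates
    and locality blanked for the missing-waterbody corruption.  Because
    corrupt rows are appended rather than edited, running the filter
    pipeline over the dirtied table removes exactly the injected rows and
    returns the clean table's records.
    """
    for name, frac in (
        ("frac_spp_epithets", frac_spp_epithets),
        ("frac_missing_waterbody", frac_missing_waterbody),
    ):
        if not 0 <= frac <= 1:
            raise ConfigError(f"{name} must lie in [0, 1], got {frac}")
    rng = np.random.default_rng(seed)
    n = len(occurrences)
    out = [occurrences]

    n_spp = int(round(frac_spp_epithets * n))
    if n_spp:
        rows = occurrences.iloc[rng.choice(n, size=n_spp, replace=False)].copy()
        rows["scientificName"] = [
            f"{name.split()[0]} spp." for name in rows["scientificName"]
        ]
        out.append(rows)

    n_missing = int(round(frac_missing_waterbody * n))
    if n_missing:
        rows = occurrences.iloc[rng.choice(n, size=n_missing, replace=False)].copy()
        rows["waterBody"] = ""
        rows["decimalLatitude"] = np.nan
        rows["decimalLongitude"] = np.nan
        rows["locality"] = ""
        out.append(rows)

    return pd.concat(out, ignore_index=True)
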