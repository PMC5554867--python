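"""Per-species dynamics of the most abundant taxa.

The community-level rate machinery applies unchanged to the subset of
trees belonging to one species, giving per-species mortality and
recruitment rates and a dead-vs-recruit count comparison. Species are
additionally annotated with regeneration guilds (pioneer,
light-demanding, shade-tolerant) from a packaged lookup table; the "Sb"
code found in some sources is read as shade-tolerant and the packaged
table records both the raw code and the normalised guild. Names are
matched on the binomial (genus + epithet), so author strings and
infraspecific ranks do not block a match; unmatched species are tagged
``unknown`` and logged.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from forestdyn.census import CensusRegistry, CensusSnapshot
from forestdyn.config import SurveyConfig
from forestdyn.errors import ForestDynError
from forestdyn.measures import basal_area_m2
from forestdyn.rates import (
    CountTestResult,
    dead_recruit_test,
    mortality_rate,
    recruitment_rate,
)

logger = logging.getLogger(__name__)

GUILDS = ("pioneer", "light_demanding", "shade_tolerant", "unknown")


class SpeciesNotFoundError(ForestDynError, KeyError):
    """Species absent from both censuses of the interval."""


@dataclass(frozen=True)
class SpeciesDynamics:
    """One species' interval demography."""

    species: str
    guild: str
    n0: int
    nt: int
    dead: int
    recruits: int
    ba0_m2: float
    bat_m2: float
    t_years: float
    mortality: float
    recruitment: float
    count_test: CountTestResult | None


def top_abundant(snapshot: CensusSnapshot, k: int = 10) -> list[str]:
    """The k most abundant species, ties broken alphabetically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    tally = snapshot.species_abundances()
    ranked = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in ranked[:k]]


def _binomial_key(name: str) -> str:
    """genus+epithet, lowercased, accents stripped — the matching key."""
    ascii_name = (
        unicodedata.normalize("NFKD", str(name)).encode("ascii", "ignore").decode()
    )
    parts = ascii_name.split()
    return " ".join(parts[:2]).lower()


def load_guild_table(path: str | Path | None = None) -> pd.DataFrame:
    """Packaged (or user-supplied) species -> regeneration-guild table."""
    if path is None:
        ref = resources.files("forestdyn.data").joinpath("guilds.csv")
        with resources.as_file(ref) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    if not {"species", "guild"}.issubset(table.columns):
        raise ForestDynError("guild table needs 'species' and 'guild' columns")
    bad = set(table["guild"]) - set(GUILDS)
    if bad:
        raise ForestDynError(f"unknown guild values {sorted(bad)}; expected {GUILDS}")
    return table


def annotate_guilds(
    species: list[str], guild_table: pd.DataFrame | None = None
) -> dict[str, str]:
    """Map each species name to its guild; unmatched -> 'unknown'."""
    table = guild_table if guild_table is not None else load_guild_table()
    lookup = {_binomial_key(row.species): row.guild for row in table.itertuples()}
    out: dict[str, str] = {}
    for name in species:
        guild = lookup.get(_binomial_key(name))
        if guild is None:
            logger.warning("species %r not in guild table; marked unknown", name)
            guild = "unknown"
        out[name] = guild
    return out


def species_interval_rates(
    registry: CensusRegistry,
    species: str,
    census_a: str,
    census_b: str,
    t_years: float | None = None,
    guild: str = "unknown",
    config: SurveyConfig | None = None,
) -> SpeciesDynamics:
    """Interval demography restricted to one species' trees."""
    cfg = config or SurveyConfig()
    if t_years is None:
        t_years = cfg.interval_length(
            census_a, census_b, registry.censuses[census_a], registry.censuses[census_b]
        )
    key = _binomial_key(species)
    n0 = nt = dead = recruits = 0
    ba0 = bat = 0.0
    present = False
    for record in registry.trees.values():
        if _binomial_key(record.species) != key:
            continue
        present = True
        alive_a = record.is_alive_at(census_a)
        alive_b = record.is_alive_at(census_b)
        if alive_a:
            n0 += 1
            ba0 += basal_area_m2(record.dbh_at(census_a))
        if alive_b:
            nt += 1
            bat += basal_area_m2(record.dbh_at(census_b))
        if alive_a and not alive_b:
            dead += 1
        elif alive_b and not alive_a:
            recruits += 1
    if not present:
        raise SpeciesNotFoundError(f"species {species!r} absent from stand {registry.stand_id}")
    m = mortality_rate(n0, dead, t_years) if n0 > 0 else 0.0
    r = recruitment_rate(nt, recruits, t_years) if nt > 0 else 0.0
    test = dead_recruit_test(dead, recruits) if dead + recruits > 0 else None
    return SpeciesDynamics(
        species=species,
        guild=guild,
        n0=n0,
        nt=nt,
        dead=dead,
        recruits=recruits,
        ba0_m2=ba0,
        bat_m2=bat,
        t_years=float(t_years),
        mortality=m,
        recruitment=r,
        count_test=test,
    )
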