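"""In-memory model of a repeated tree census.

A *stand* is a block of contiguous plots surveyed repeatedly. Every tree
is tagged at first inclusion and followed until death, so its life course
through the census series is monotone:

    not_yet_recruited* -> alive+ -> dead*

A :class:`TreeRecord` stores that per-census trajectory for one tag; a
:class:`CensusRegistry` holds all records of a stand together with the
census calendar and plot geometry; a :class:`CensusSnapshot` is the
cross-section of live trees at one census, the input to structure,
diversity and dynamics computations.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

from forestdyn.config import SurveyConfig
from forestdyn.errors import IntegrityError, InvalidMeasurementError
from forestdyn.measures import aggregate_stem_dbh

logger = logging.getLogger(__name__)


class Status(str, enum.Enum):
    """Life-course status of a tagged tree at one census."""

    NOT_YET_RECRUITED = "not_yet_recruited"
    ALIVE = "alive"
    DEAD = "dead"


#: Allowed transitions between consecutive censuses.
_ALLOWED_NEXT = {
    Status.NOT_YET_RECRUITED: {Status.NOT_YET_RECRUITED, Status.ALIVE},
    Status.ALIVE: {Status.ALIVE, Status.DEAD},
    Status.DEAD: {Status.DEAD},
}


@dataclass(frozen=True)
class StemMeasurement:
    """One stem of a (possibly multi-stemmed) tree."""

    tree_id: str
    dbh_cm: float

    def __post_init__(self) -> None:
        if self.dbh_cm <= 0 or not math.isfinite(self.dbh_cm):
            raise InvalidMeasurementError(
                f"stem DBH must be positive, got {self.dbh_cm} for tree {self.tree_id}"
            )


@dataclass(frozen=True)
class Observation:
    """State of one tree at one census."""

    status: Status
    dbh_cm: float | None = None
    stems: tuple[StemMeasurement, ...] | None = None


@dataclass
class TreeRecord:
    """One tagged tree across all censuses of its stand."""

    tree_id: str
    species: str
    plot_id: str
    stand_id: str
    observations: dict[str, Observation] = field(default_factory=dict)

    def status_at(self, census_label: str) -> Status:
        obs = self.observations.get(census_label)
        return obs.status if obs is not None else Status.NOT_YET_RECRUITED

    def dbh_at(self, census_label: str) -> float | None:
        obs = self.observations.get(census_label)
        return obs.dbh_cm if obs is not None else None

    def is_alive_at(self, census_label: str) -> bool:
        return self.status_at(census_label) is Status.ALIVE

    def validate(self, census_order: list[str], inclusion_dbh_cm: float) -> None:
        """Check the monotone life course and DBH invariants.

        Raises :class:`IntegrityError` on a status regression and
        :class:`InvalidMeasurementError` on a live tree without a DBH or
        a stem list inconsistent with its aggregate.
        """
        prev = Status.NOT_YET_RECRUITED
        for label in census_order:
            obs = self.observations.get(label)
            status = obs.status if obs is not None else Status.NOT_YET_RECRUITED
            if status not in _ALLOWED_NEXT[prev]:
                raise IntegrityError(
                    f"tree {self.tree_id}: illegal status transition "
                    f"{prev.value} -> {status.value} at census {label}"
                )
            if status is Status.ALIVE:
                if obs is None or obs.dbh_cm is None:
                    raise InvalidMeasurementError(
                        f"tree {self.tree_id}: alive at {label} without a DBH"
                    )
                if obs.dbh_cm < inclusion_dbh_cm - 1e-9:
                    raise InvalidMeasurementError(
                        f"tree {self.tree_id}: DBH {obs.dbh_cm} below inclusion "
                        f"threshold {inclusion_dbh_cm} at {label}"
                    )
                if obs.stems:
                    agg = aggregate_stem_dbh(s.dbh_cm for s in obs.stems)
                    if not math.isclose(agg, obs.dbh_cm, rel_tol=1e-6, abs_tol=1e-6):
                        raise InvalidMeasurementError(
                            f"tree {self.tree_id}: recorded DBH {obs.dbh_cm} differs "
                            f"from multi-stem aggregate {agg:.4f} at {label}"
                        )
            prev = status


@dataclass(frozen=True)
class TreeObservation:
    """One live tree inside a :class:`CensusSnapshot`."""

    tree_id: str
    species: str
    plot_id: str
    dbh_cm: float


@dataclass(frozen=True)
class CensusSnapshot:
    """All live trees of one stand at one census."""

    stand_id: str
    census_label: str
    census_year: int
    n_plots: int
    plot_area_m2: float
    trees: tuple[TreeObservation, ...]

    @property
    def sampled_area_ha(self) -> float:
        return self.n_plots * self.plot_area_m2 / 10_000.0

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def species_abundances(self) -> dict[str, int]:
        """Species -> individual count tally."""
        tally: dict[str, int] = {}
        for t in self.trees:
            tally[t.species] = tally.get(t.species, 0) + 1
        return tally


@dataclass
class CensusRegistry:
    """All tree records of one stand plus the census calendar.

    ``censuses`` maps census label -> census year, in chronological
    order (insertion order is the census order).
    """

    stand_id: str
    censuses: dict[str, int]
    n_plots: int
    plot_area_m2: float
    trees: dict[str, TreeRecord] = field(default_factory=dict)

    @property
    def census_order(self) -> list[str]:
        return list(self.censuses)

    def add(self, record: TreeRecord) -> None:
        if record.tree_id in self.trees:
            raise IntegrityError(f"duplicate tree id {record.tree_id!r} in stand {self.stand_id}")
        self.trees[record.tree_id] = record

    def validate(self, config: SurveyConfig | None = None) -> None:
        cfg = config or SurveyConfig()
        order = self.census_order
        for record in self.trees.values():
            record.validate(order, cfg.inclusion_dbh_cm)

    def snapshot(self, census_label: str, config: SurveyConfig | None = None) -> CensusSnapshot:
        """Cross-section of live trees at one census.

        Trees below the inclusion threshold are excluded and counted in
        the log (a validated registry contains none).
        """
        cfg = config or SurveyConfig()
        if census_label not in self.censuses:
            raise IntegrityError(
                f"unknown census {census_label!r} for stand {self.stand_id}"
            )
        kept: list[TreeObservation] = []
        n_filtered = 0
        for record in self.trees.values():
            obs = record.observations.get(census_label)
            if obs is None or obs.status is not Status.ALIVE:
                continue
            if obs.dbh_cm is None or obs.dbh_cm < cfg.inclusion_dbh_cm - 1e-9:
                n_filtered += 1
                continue
            kept.append(
                TreeObservation(record.tree_id, record.species, record.plot_id, obs.dbh_cm)
            )
        if n_filtered:
            logger.warning(
                "stand %s census %s: filtered %d live trees below inclusion DBH %.2f cm",
                self.stand_id, census_label, n_filtered, cfg.inclusion_dbh_cm,
            )
        logger.info(
            "stand %s census %s: %d live trees", self.stand_id, census_label, len(kept)
        )
        return CensusSnapshot(
            stand_id=self.stand_id,
            census_label=census_label,
            census_year=self.censuses[census_label],
            n_plots=self.n_plots,
            plot_area_m2=self.plot_area_m2,
            trees=tuple(sorted(kept, key=lambda t: t.tree_id)),
        )
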