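"""Interval demography and compound annual rates.

Between two censuses of the same stand, every tagged tree is a survivor
(alive at both), a death (alive then dead/missing), or a recruit (first
alive at the second census). Basal area decomposes the same way, with
survivors split into those that lost and those that gained section:

    BA_t = BA_0 - BA_dead - BA_decrement + BA_recruits + BA_increment

Annual rates follow the compound-interest convention of the forest
dynamics literature. Over an interval of t years,

    mortality     m    = 100 [1 - ((N0 - D)/N0)^(1/t)]
    recruitment   r    = 100 [1 - (1 - R/Nt)^(1/t)]
    BA loss       L    = 100 [1 - ((BA0 - BA_dead - BA_decr)/BA0)^(1/t)]
    BA gain       G    = 100 [1 - (1 - (BA_recr + BA_incr)/BAt)^(1/t)]
    net change    Ch   = 100 [(x_t/x_0)^(1/t) - 1]
    turnover      T    = (m + r)/2   (abundance), (L + G)/2  (basal area)

The dead-versus-recruit comparison conditions on the total count
n = D + R: if deaths and recruits arrive as two Poisson streams of equal
intensity, D | n is Binomial(n, 1/2). Both the exact two-sided binomial
p-value and the normal approximation Z = (D - R)/sqrt(D + R) are
reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy import stats

from forestdyn.census import CensusRegistry, Status
from forestdyn.config import SurveyConfig
from forestdyn.errors import (
    ConfigurationError,
    IntegrityError,
    InvalidMeasurementError,
    UndefinedStatisticError,
)
from forestdyn.measures import basal_area_m2

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntervalSummary:
    """Demographic bookkeeping between two censuses of one stand."""

    stand_id: str
    census_a: str
    census_b: str
    t_years: float
    n0: int
    nt: int
    survivors: int
    dead: int
    recruits: int
    ba0_m2: float
    bat_m2: float
    ba_dead_m2: float
    ba_decr_m2: float  # survivors that lost basal area
    ba_recr_m2: float
    ba_incr_m2: float  # survivors that gained basal area

    def check_identities(self, tol: float = 1e-6) -> None:
        """Verify count and basal-area conservation identities."""
        if self.survivors != self.n0 - self.dead:
            raise IntegrityError("survivors != N0 - dead")
        if self.nt != self.survivors + self.recruits:
            raise IntegrityError("Nt != survivors + recruits")
        lhs = self.bat_m2
        rhs = (
            self.ba0_m2 - self.ba_dead_m2 - self.ba_decr_m2
            + self.ba_recr_m2 + self.ba_incr_m2
        )
        if abs(lhs - rhs) > tol * max(1.0, abs(lhs)):
            raise IntegrityError(
                f"basal-area identity violated: BAt={lhs:.6f} vs components {rhs:.6f}"
            )


@dataclass(frozen=True)
class RateSet:
    """Annual percentage rates derived from an :class:`IntervalSummary`."""

    mortality: float
    recruitment: float
    ba_loss: float
    ba_gain: float
    turnover_n: float
    turnover_ba: float
    net_change_n: float
    net_change_ba: float


@dataclass(frozen=True)
class CountTestResult:
    """Dead-vs-recruit (or ingrowth-vs-outgrowth) count comparison."""

    z: float
    p_exact: float
    p_normal: float


# ---------------------------------------------------------------------------
# rate formulas


def _check_t(t: float) -> float:
    if t <= 0:
        raise ConfigurationError(f"interval length must be positive, got {t}")
    return float(t)


def mortality_rate(n0: int, dead: int, t: float) -> float:
    """Compound annual mortality, % per year."""
    _check_t(t)
    if n0 <= 0:
        raise IntegrityError("initial count must be positive")
    if dead < 0 or dead > n0:
        raise IntegrityError(f"dead count {dead} outside [0, {n0}]")
    return 100.0 * (1.0 - ((n0 - dead) / n0) ** (1.0 / t))


def recruitment_rate(nt: int, recruits: int, t: float) -> float:
    """Compound annual recruitment, % per year."""
    _check_t(t)
    if nt <= 0:
        raise IntegrityError("final count must be positive")
    if recruits < 0 or recruits > nt:
        raise IntegrityError(f"recruit count {recruits} outside [0, {nt}]")
    return 100.0 * (1.0 - (1.0 - recruits / nt) ** (1.0 / t))


def ba_loss_rate(ba0: float, ba_dead: float, ba_decr: float, t: float) -> float:
    """Compound annual basal-area loss, % per year."""
    _check_t(t)
    if ba0 <= 0:
        raise InvalidMeasurementError("initial basal area must be positive")
    if ba_dead < 0 or ba_decr < 0:
        raise InvalidMeasurementError("loss components must be non-negative")
    remaining = ba0 - ba_dead - ba_decr
    if remaining < 0:
        raise IntegrityError("basal-area losses exceed initial basal area")
    return 100.0 * (1.0 - (remaining / ba0) ** (1.0 / t))


def ba_gain_rate(bat: float, ba_recr: float, ba_incr: float, t: float) -> float:
    """Compound annual basal-area gain, % per year."""
    _check_t(t)
    if bat <= 0:
        raise InvalidMeasurementError("final basal area must be positive")
    if ba_recr < 0 or ba_incr < 0:
        raise InvalidMeasurementError("gain components must be non-negative")
    gained = ba_recr + ba_incr
    if gained > bat:
        raise IntegrityError("basal-area gains exceed final basal area")
    return 100.0 * (1.0 - (1.0 - gained / bat) ** (1.0 / t))


def net_change_rate(x0: float, xt: float, t: float) -> float:
    """Compound annual net change connecting x0 to xt, % per year."""
    _check_t(t)
    if x0 <= 0 or xt <= 0:
        raise InvalidMeasurementError("totals must be positive")
    return 100.0 * ((xt / x0) ** (1.0 / t) - 1.0)


def turnover(rate_a: float, rate_b: float) -> float:
    """Turnover: arithmetic mean of two component rates."""
    if rate_a < 0 or rate_b < 0:
        raise InvalidMeasurementError("turnover components must be non-negative")
    return 0.5 * (rate_a + rate_b)


def dead_recruit_test(dead: int, recruits: int) -> CountTestResult:
    """Equal-intensity test for two event counts.

    Conditional on n = D + R, equal Poisson intensities make
    D ~ Binomial(n, 1/2). Returns the exact two-sided binomial p, the
    signed normal-approximation Z = (D - R)/sqrt(D + R), and its
    two-sided p.
    """
    if dead < 0 or recruits < 0:
        raise IntegrityError("counts must be non-negative")
    n = dead + recruits
    if n == 0:
        raise UndefinedStatisticError("count test undefined for zero events")
    z = (dead - recruits) / math.sqrt(n)
    p_exact = float(stats.binomtest(dead, n, 0.5).pvalue)
    p_normal = float(2.0 * stats.norm.sf(abs(z)))
    return CountTestResult(z=z, p_exact=p_exact, p_normal=min(p_normal, 1.0))


# ---------------------------------------------------------------------------
# interval bookkeeping from a registry


def interval_summary(
    registry: CensusRegistry,
    census_a: str,
    census_b: str,
    t_years: float | None = None,
    config: SurveyConfig | None = None,
) -> IntervalSummary:
    """Tally deaths, recruits, survivors and basal-area components.

    A death is a tree alive at *census_a* and not alive at *census_b*;
    a recruit is alive at *census_b* and not alive at *census_a*.
    Survivor basal-area change is split by sign into decrement and
    increment.
    """
    cfg = config or SurveyConfig()
    order = registry.census_order
    for label in (census_a, census_b):
        if label not in registry.censuses:
            raise IntegrityError(f"unknown census {label!r} for stand {registry.stand_id}")
    if order.index(census_a) >= order.index(census_b):
        raise IntegrityError(f"census {census_a!r} is not earlier than {census_b!r}")
    if t_years is None:
        t_years = cfg.interval_length(
            census_a, census_b, registry.censuses[census_a], registry.censuses[census_b]
        )
    t_years = _check_t(t_years)

    n0 = nt = dead = recruits = survivors = 0
    ba0 = bat = ba_dead = ba_decr = ba_recr = ba_incr = 0.0
    for record in registry.trees.values():
        alive_a = record.is_alive_at(census_a)
        alive_b = record.is_alive_at(census_b)
        if alive_a:
            da = record.dbh_at(census_a)
            if da is None:
                raise IntegrityError(f"tree {record.tree_id}: alive without DBH at {census_a}")
            ba_a = basal_area_m2(da)
            n0 += 1
            ba0 += ba_a
        if alive_b:
            db = record.dbh_at(census_b)
            if db is None:
                raise IntegrityError(f"tree {record.tree_id}: alive without DBH at {census_b}")
            ba_b = basal_area_m2(db)
            nt += 1
            bat += ba_b
        if alive_a and not alive_b:
            dead += 1
            ba_dead += ba_a
        elif alive_b and not alive_a:
            recruits += 1
            ba_recr += ba_b
        elif alive_a and alive_b:
            survivors += 1
            delta = ba_b - ba_a
            if delta >= 0:
                ba_incr += delta
            else:
                ba_decr -= delta

    summary = IntervalSummary(
        stand_id=registry.stand_id,
        census_a=census_a,
        census_b=census_b,
        t_years=t_years,
        n0=n0,
        nt=nt,
        survivors=survivors,
        dead=dead,
        recruits=recruits,
        ba0_m2=ba0,
        bat_m2=bat,
        ba_dead_m2=ba_dead,
        ba_decr_m2=ba_decr,
        ba_recr_m2=ba_recr,
        ba_incr_m2=ba_incr,
    )
    summary.check_identities()
    logger.info(
        "stand %s %s->%s: N %d -> %d (S=%d, D=%d, R=%d), BA %.4f -> %.4f m2",
        registry.stand_id, census_a, census_b, n0, nt, survivors, dead, recruits, ba0, bat,
    )
    return summary


def rates_from_summary(summary: IntervalSummary) -> RateSet:
    """All eight annual percentage rates of one census interval."""
    m = mortality_rate(summary.n0, summary.dead, summary.t_years)
    r = recruitment_rate(summary.nt, summary.recruits, summary.t_years)
    loss = ba_loss_rate(summary.ba0_m2, summary.ba_dead_m2, summary.ba_decr_m2, summary.t_years)
    gain = ba_gain_rate(summary.bat_m2, summary.ba_recr_m2, summary.ba_incr_m2, summary.t_years)
    return RateSet(
        mortality=m,
        recruitment=r,
        ba_loss=loss,
        ba_gain=gain,
        turnover_n=turnover(m, r),
        turnover_ba=turnover(loss, gain),
        net_change_n=net_change_rate(summary.n0, summary.nt, summary.t_years),
        net_change_ba=net_change_rate(summary.ba0_m2, summary.bat_m2, summary.t_years),
    )
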