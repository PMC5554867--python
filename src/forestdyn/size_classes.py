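"""Diameter-class dynamics: binning, flow accounting, and count tests.

Trees are binned into diameter classes of increasing amplitude (default
5-10, >10-20, >20-40, >40-80 cm) to compensate for the reverse-J decline
of abundance with size. Classes are upper-closed; the first class is
lower-closed at the survey's inclusion threshold, so a 10.0 cm tree is in
class 1 and a 10.01 cm tree in class 2. Stems beyond the last break fall
into an overflow class, counted and logged.

Between two censuses each class k exchanges trees through four flows:

    D_k  deaths among the trees in k at the first census
    O_k  absolute outgrowth: survivors leaving k by growth (either
         direction — shrinkage across a boundary counts too)
    R_k  recruits whose first recorded class is k
    I_k  absolute ingrowth: survivors arriving in k from another class

giving the per-class conservation identity

    Nt_k = N0_k - D_k - O_k + R_k + I_k

and globally sum(O) = sum(I) (growth moves trees, never creates them).
Total outgrowth D_k + O_k is compared against total ingrowth R_k + I_k
with the same conditional count test used for deaths vs recruits.

Expected class frequencies under the no-size-effect null scale the
first-census value by the ratio of classed totals,
exp_k = value_k * (Nt_total / N0_total), and observed-vs-expected death
frequencies are tested with the log-likelihood-ratio goodness-of-fit
G-test, G = 2 sum O_i ln(O_i/E_i) on k-1 degrees of freedom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
from scipy import stats

from forestdyn.census import CensusRegistry
from forestdyn.config import SurveyConfig
from forestdyn.errors import IntegrityError, InvalidMeasurementError, UndefinedStatisticError
from forestdyn.rates import CountTestResult, dead_recruit_test, mortality_rate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiameterClassScheme:
    """Upper-closed diameter classes over strictly increasing breaks."""

    breaks_cm: tuple[float, ...] = (5.0, 10.0, 20.0, 40.0, 80.0)
    inclusion_dbh_cm: float = 4.99

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.breaks_cm)
        if len(b) < 2 or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise InvalidMeasurementError("class breaks must be strictly increasing")
        object.__setattr__(self, "breaks_cm", b)

    @property
    def n_classes(self) -> int:
        """Regular classes; index ``n_classes`` is the overflow class."""
        return len(self.breaks_cm) - 1

    @property
    def labels(self) -> list[str]:
        b = self.breaks_cm
        out = [f"≥{b[0]:02.0f}-{b[1]:.0f}"]
        out += [f">{b[i]:.0f}-{b[i + 1]:.0f}" for i in range(1, len(b) - 1)]
        return out

    @classmethod
    def from_config(cls, config: SurveyConfig) -> "DiameterClassScheme":
        return cls(breaks_cm=config.class_breaks_cm, inclusion_dbh_cm=config.inclusion_dbh_cm)


def assign_class(dbh_cm: float, scheme: DiameterClassScheme | None = None) -> int:
    """0-based class index of a DBH; ``scheme.n_classes`` for overflow.

    Membership: class 0 covers inclusion <= dbh <= break_1; class k > 0
    covers break_k < dbh <= break_{k+1}.
    """
    scheme = scheme or DiameterClassScheme()
    d = float(dbh_cm)
    if not math.isfinite(d) or d < scheme.inclusion_dbh_cm - 1e-9:
        raise InvalidMeasurementError(
            f"DBH {dbh_cm} below inclusion threshold {scheme.inclusion_dbh_cm}"
        )
    b = scheme.breaks_cm
    if d <= b[1]:
        return 0
    for k in range(1, len(b) - 1):
        if d <= b[k + 1]:
            return k
    logger.warning("DBH %.2f cm beyond last class break %.0f; overflow class", d, b[-1])
    return scheme.n_classes


@dataclass(frozen=True)
class ClassFlowTable:
    """Per-class counts and flows for one census interval.

    Arrays are indexed by class; the last index is the overflow class
    (usually all zeros).
    """

    stand_id: str
    census_a: str
    census_b: str
    t_years: float
    labels: tuple[str, ...]
    n0: tuple[int, ...]
    nt: tuple[int, ...]
    dead: tuple[int, ...]
    outgrowth: tuple[int, ...]
    recruits: tuple[int, ...]
    ingrowth: tuple[int, ...]

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    @property
    def total_outgrowth(self) -> tuple[int, ...]:
        return tuple(d + o for d, o in zip(self.dead, self.outgrowth))

    @property
    def total_ingrowth(self) -> tuple[int, ...]:
        return tuple(r + i for r, i in zip(self.recruits, self.ingrowth))

    def check_conservation(self) -> None:
        """Per-class conservation and global flow balance, exact."""
        for k in range(self.n_classes):
            lhs = self.nt[k]
            rhs = self.n0[k] - self.dead[k] - self.outgrowth[k] + self.recruits[k] + self.ingrowth[k]
            if lhs != rhs:
                raise IntegrityError(
                    f"class {self.labels[k]}: Nt={lhs} != "
                    f"N0-D-O+R+I={rhs} ({self.n0[k]}-{self.dead[k]}-"
                    f"{self.outgrowth[k]}+{self.recruits[k]}+{self.ingrowth[k]})"
                )
        if sum(self.outgrowth) != sum(self.ingrowth):
            raise IntegrityError(
                f"growth flows unbalanced: sum O={sum(self.outgrowth)} != sum I={sum(self.ingrowth)}"
            )

    def mortality_rates(self) -> tuple[float | None, ...]:
        """Per-class compound annual mortality (% / yr); None where N0=0."""
        return tuple(
            class_mortality_rate(n, d, self.t_years) if n > 0 else None
            for n, d in zip(self.n0, self.dead)
        )

    def growth_tests(self) -> tuple[CountTestResult | None, ...]:
        """Per-class total ingrowth vs total outgrowth count tests."""
        return tuple(
            class_growth_test(ti, to) if ti + to > 0 else None
            for ti, to in zip(self.total_ingrowth, self.total_outgrowth)
        )


def class_flows(
    registry: CensusRegistry,
    census_a: str,
    census_b: str,
    t_years: float | None = None,
    scheme: DiameterClassScheme | None = None,
    config: SurveyConfig | None = None,
) -> ClassFlowTable:
    """Bin every tree of an interval and tally the four per-class flows."""
    cfg = config or SurveyConfig()
    scheme = scheme or DiameterClassScheme.from_config(cfg)
    if census_a not in registry.censuses or census_b not in registry.censuses:
        raise IntegrityError("unknown census label")
    if t_years is None:
        t_years = cfg.interval_length(
            census_a, census_b, registry.censuses[census_a], registry.censuses[census_b]
        )

    k_all = scheme.n_classes + 1  # + overflow
    n0 = [0] * k_all
    nt = [0] * k_all
    dead = [0] * k_all
    outg = [0] * k_all
    recr = [0] * k_all
    ingr = [0] * k_all

    for record in registry.trees.values():
        alive_a = record.is_alive_at(census_a)
        alive_b = record.is_alive_at(census_b)
        ka = kb = None
        if alive_a:
            da = record.dbh_at(census_a)
            if da is None:
                raise IntegrityError(f"tree {record.tree_id}: alive without DBH at {census_a}")
            ka = assign_class(da, scheme)
            n0[ka] += 1
        if alive_b:
            db = record.dbh_at(census_b)
            if db is None:
                raise IntegrityError(f"tree {record.tree_id}: alive without DBH at {census_b}")
            kb = assign_class(db, scheme)
            nt[kb] += 1
        if alive_a and not alive_b:
            dead[ka] += 1
        elif alive_b and not alive_a:
            recr[kb] += 1
        elif alive_a and alive_b and ka != kb:
            outg[ka] += 1
            ingr[kb] += 1

    labels = tuple(scheme.labels + [f">{scheme.breaks_cm[-1]:.0f}"])
    table = ClassFlowTable(
        stand_id=registry.stand_id,
        census_a=census_a,
        census_b=census_b,
        t_years=float(t_years),
        labels=labels,
        n0=tuple(n0),
        nt=tuple(nt),
        dead=tuple(dead),
        outgrowth=tuple(outg),
        recruits=tuple(recr),
        ingrowth=tuple(ingr),
    )
    table.check_conservation()
    if n0[-1] or nt[-1]:
        logger.warning(
            "stand %s: %d/%d trees beyond the last class break at %s/%s",
            registry.stand_id, n0[-1], nt[-1], census_a, census_b,
        )
    return table


def expected_class_frequencies(
    initial_values: Sequence[float],
    n_total_initial: float,
    n_total_final: float,
) -> list[float]:
    """Null expected frequencies: first-census values scaled to the new total.

    exp_k = value_k * (N_final / N_initial); applied both to class counts
    and to class death counts. Preserves the initial proportions.
    """
    if n_total_initial <= 0 or n_total_final <= 0:
        raise InvalidMeasurementError("classed totals must be positive")
    ratio = n_total_final / n_total_initial
    return [float(v) * ratio for v in initial_values]


@dataclass(frozen=True)
class GTestResult:
    g: float
    df: int
    p: float


def g_test(observed: Sequence[float], expected: Sequence[float]) -> GTestResult:
    """Log-likelihood-ratio goodness-of-fit test (no Williams correction).

    G = 2 sum O_i ln(O_i/E_i), with the 0 ln 0 limit taken as 0;
    df = k - 1; p is the upper chi-square tail.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1 or obs.size < 2:
        raise UndefinedStatisticError("observed/expected must be equal-length vectors, k >= 2")
    if np.any(obs < 0):
        raise InvalidMeasurementError("observed counts must be non-negative")
    if np.any(exp <= 0):
        raise InvalidMeasurementError("expected frequencies must be positive")
    mask = obs > 0
    g = 2.0 * float(np.sum(obs[mask] * np.log(obs[mask] / exp[mask])))
    df = obs.size - 1
    return GTestResult(g=g, df=df, p=float(stats.chi2.sf(g, df)))


def class_growth_test(total_ingrowth: int, total_outgrowth: int) -> CountTestResult:
    """Total ingrowth vs total outgrowth, same conditional count test."""
    return dead_recruit_test(total_ingrowth, total_outgrowth)


def class_mortality_rate(n0_k: int, dead_k: int, t: float) -> float:
    """Per-class compound annual mortality (% / yr)."""
    return mortality_rate(n0_k, dead_k, t)
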