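"""Survey configuration and report rounding.

The survey conventions that every downstream computation shares: the DBH
inclusion threshold (trees enter the census when their diameter at breast
height first reaches it), the diameter-class breaks, how many decimal
places reports carry, and explicit census-interval lengths in years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

from forestdyn.errors import ConfigurationError

#: Default inclusion threshold: DBH >= 4.99 cm.
DEFAULT_INCLUSION_DBH_CM = 4.99

#: Default diameter-class breaks (cm); classes have increasing amplitude
#: to compensate for the reverse-J abundance decline of large stems.
DEFAULT_CLASS_BREAKS_CM = (5.0, 10.0, 20.0, 40.0, 80.0)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round *x* to *ndigits* decimals, ties away from zero.

    Report tables use commercial rounding (2.705 -> 2.71, -0.965 -> -0.97),
    not banker's rounding, so ``round()`` is not a substitute.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SurveyConfig:
    """Shared survey conventions.

    Parameters
    ----------
    inclusion_dbh_cm
        Minimum DBH (cm) for a tree to enter the census. Default 4.99.
    class_breaks_cm
        Strictly increasing diameter-class break points (cm). The first
        class is lower-closed at the inclusion threshold; every class is
        upper-closed.
    rounding_dp
        Decimal places used when rendering report tables (half away from
        zero). Default 2.
    interval_years
        Explicit interval lengths, keyed by ``(census_a, census_b)``
        label pairs. Pairs not listed fall back to census-year
        differences.
    """

    inclusion_dbh_cm: float = DEFAULT_INCLUSION_DBH_CM
    class_breaks_cm: tuple[float, ...] = DEFAULT_CLASS_BREAKS_CM
    rounding_dp: int = 2
    interval_years: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.inclusion_dbh_cm <= 0:
            raise ConfigurationError("inclusion_dbh_cm must be positive")
        breaks = tuple(float(b) for b in self.class_breaks_cm)
        if len(breaks) < 2 or any(b >= a for b, a in zip(breaks, breaks[1:])):
            raise ConfigurationError("class_breaks_cm must be strictly increasing")
        object.__setattr__(self, "class_breaks_cm", breaks)
        for pair, t in self.interval_years.items():
            if t <= 0:
                raise ConfigurationError(f"interval length for {pair} must be > 0")

    def interval_length(
        self, label_a: str, label_b: str, year_a: int | None = None, year_b: int | None = None
    ) -> float:
        """Interval length in years for a census pair.

        Explicit configuration wins; otherwise the census-year difference.
        """
        if (label_a, label_b) in self.interval_years:
            return self.interval_years[(label_a, label_b)]
        if year_a is not None and year_b is not None:
            t = float(year_b - year_a)
            if t <= 0:
                raise ConfigurationError(
                    f"census years {year_a} -> {year_b} give non-positive interval"
                )
            return t
        raise ConfigurationError(
            f"no interval length configured for censuses {label_a!r} -> {label_b!r}"
        )

    def round(self, x: float) -> float:
        return round_half_away(x, self.rounding_dp)
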