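"""Elementary DBH conversions.

Multi-stemmed trees carry one equivalent diameter: the square root of the
sum of squared stem DBHs, which preserves total cross-sectional (basal)
area. Basal area itself is the standard forestry conversion
pi * (DBH/200)^2 from centimeters of diameter to square meters.
"""

from __future__ import annotations

import math
from collections.abc import Iterable

from forestdyn.errors import InvalidMeasurementError


def aggregate_stem_dbh(stems: Iterable[float]) -> float:
    """Equivalent single-stem DBH (cm) of a multi-stemmed tree.

    ``sqrt(sum d_i^2)``: the diameter of the circle whose area equals the
    summed stem cross-sections. A single stem is returned unchanged.

    Raises
    ------
    InvalidMeasurementError
        If the stem list is empty or any stem DBH is not positive.
    """
    values = [float(d) for d in stems]
    if not values:
        raise InvalidMeasurementError("multi-stem aggregate requires at least one stem")
    if any(d <= 0 or not math.isfinite(d) for d in values):
        raise InvalidMeasurementError(f"stem DBHs must be positive finite, got {values}")
    return math.sqrt(math.fsum(d * d for d in values))


def basal_area_m2(dbh_cm: float) -> float:
    """Basal area (m^2) of a stem of diameter *dbh_cm* centimeters.

    pi * (dbh/200)^2 — dbh/2 is the radius in cm, /100 converts to m.
    """
    d = float(dbh_cm)
    if d <= 0 or not math.isfinite(d):
        raise InvalidMeasurementError(f"DBH must be positive finite, got {dbh_cm}")
    return math.pi * (d / 200.0) ** 2
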