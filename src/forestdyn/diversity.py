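"""Stand structure and species-diversity summaries.

Structure is reported as stems per hectare and basal area per hectare.
Diversity uses the Shannon index H' in nats per individual and Pielou's
evenness J = H'/ln(S). Two stands' Shannon indices are compared with the
Hutcheson t-test, which equips H' with an analytic sampling variance

    var(H) = [sum p (ln p)^2 - (sum p ln p)^2] / N + (S - 1) / (2 N^2)

and refers t = (H1 - H2) / sqrt(var1 + var2) to a Student-t distribution
with Welch-style effective degrees of freedom. The (S-1)/(2N^2) term is
the finite-sample correction used by the classic implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections.abc import Iterable, Mapping

import numpy as np
from scipy import stats

from forestdyn.census import CensusSnapshot
from forestdyn.errors import ConfigurationError, UndefinedStatisticError
from forestdyn.measures import basal_area_m2


@dataclass(frozen=True)
class StructureSummary:
    """Stand totals and per-hectare structure at one census."""

    n_individuals: int
    density_per_ha: float
    ba_total_m2: float
    ba_per_ha: float


@dataclass(frozen=True)
class DiversityResult:
    """Shannon/Pielou summary of one community."""

    n_individuals: int
    richness: int
    shannon_h: float
    var_h: float
    pielou_j: float | None


@dataclass(frozen=True)
class HutchesonResult:
    t_statistic: float
    df: float
    p_two_sided: float


def _counts(abundances: Iterable[int] | Mapping[str, int]) -> np.ndarray:
    if isinstance(abundances, Mapping):
        abundances = list(abundances.values())
    arr = np.asarray(list(abundances), dtype=float)
    if arr.size and np.any(arr < 0):
        raise UndefinedStatisticError("abundances must be non-negative")
    arr = arr[arr > 0]
    if arr.size == 0:
        raise UndefinedStatisticError("at least one positive abundance required")
    return arr


def shannon(abundances: Iterable[int] | Mapping[str, int]) -> float:
    """Shannon index H' = -sum p_i ln p_i (nats per individual)."""
    n = _counts(abundances)
    p = n / n.sum()
    return float(-(p * np.log(p)).sum())


def pielou(abundances: Iterable[int] | Mapping[str, int]) -> float:
    """Pielou evenness J = H'/ln(S); undefined for fewer than 2 species."""
    n = _counts(abundances)
    if n.size < 2:
        raise UndefinedStatisticError("evenness undefined for a single species")
    return shannon(n) / math.log(n.size)


def shannon_variance(abundances: Iterable[int] | Mapping[str, int]) -> float:
    """Analytic sampling variance of H' (Hutcheson), incl. (S-1)/(2N^2)."""
    n = _counts(abundances)
    N = n.sum()
    S = n.size
    p = n / N
    plnp = p * np.log(p)
    plnp2 = p * np.log(p) ** 2
    var = (plnp2.sum() - plnp.sum() ** 2) / N + (S - 1) / (2.0 * N**2)
    return float(max(var, 0.0))


def hutcheson_t(
    abundances_1: Iterable[int] | Mapping[str, int],
    abundances_2: Iterable[int] | Mapping[str, int],
) -> HutchesonResult:
    """Compare two communities' Shannon indices (two-sided Hutcheson t-test).

    Antisymmetric in its arguments: swapping flips the sign of t and
    leaves p unchanged.
    """
    n1, n2 = _counts(abundances_1), _counts(abundances_2)
    if n1.size < 2 or n2.size < 2:
        raise UndefinedStatisticError("Hutcheson test undefined for single-species communities")
    h1, h2 = shannon(n1), shannon(n2)
    v1, v2 = shannon_variance(n1), shannon_variance(n2)
    pooled = v1 + v2
    if pooled <= 0:
        raise UndefinedStatisticError("zero pooled variance of H")
    t = (h1 - h2) / math.sqrt(pooled)
    df = pooled**2 / (v1**2 / n1.sum() + v2**2 / n2.sum())
    p = 2.0 * stats.t.sf(abs(t), df)
    return HutchesonResult(t_statistic=t, df=float(df), p_two_sided=float(min(p, 1.0)))


def diversity_summary(snapshot: CensusSnapshot) -> DiversityResult:
    """Shannon/Pielou summary of a census snapshot's species tally."""
    tally = snapshot.species_abundances()
    n = _counts(tally)
    return DiversityResult(
        n_individuals=int(n.sum()),
        richness=int(n.size),
        shannon_h=shannon(n),
        var_h=shannon_variance(n),
        pielou_j=pielou(n) if n.size >= 2 else None,
    )


def structure_summary(snapshot: CensusSnapshot) -> StructureSummary:
    """Stem density and basal area, total and per hectare."""
    area = snapshot.sampled_area_ha
    if area <= 0:
        raise ConfigurationError("snapshot sampled area must be positive")
    ba_total = math.fsum(basal_area_m2(t.dbh_cm) for t in snapshot.trees)
    return StructureSummary(
        n_individuals=snapshot.n_trees,
        density_per_ha=snapshot.n_trees / area,
        ba_total_m2=ba_total,
        ba_per_ha=ba_total / area,
    )
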