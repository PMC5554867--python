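"""Synthetic repeated-census generator.

Emulates the statistical structure the pipeline assumes, at desk scale
and with a known ground truth, so every bookkeeping identity and rate
estimator can be validated without field data:

* a stand of contiguous 300 m^2 plots surveying all stems with
  DBH >= 4.99 cm;
* a geometric-series species-abundance distribution (one dominance
  parameter), enough to exercise diversity code without a full
  species-abundance model;
* initial diameters from a shifted exponential (minimum at the
  inclusion threshold), the reverse-J size distribution of uneven-aged
  stands;
* a yearly demographic clock: each live tree dies with probability q,
  survivors add a lognormal diameter increment perturbed by measurement
  noise (occasionally negative, so downward class moves occur, floored
  at the inclusion threshold because tagged trees stay in the survey),
  and Poisson(lambda * n_plots) recruits enter just above the threshold;
* a small fraction of multi-stemmed trees whose recorded DBH is the
  root-sum-of-squares aggregate of their stems.

Identical seeds give identical registries. The
:func:`recovery_experiment` harness closes the loop: simulate, run the
rate pipeline, and compare the estimated mortality against its known
target 100q.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from forestdyn.census import (
    CensusRegistry,
    Observation,
    Status,
    StemMeasurement,
    TreeRecord,
)
from forestdyn.errors import ConfigurationError
from forestdyn.measures import aggregate_stem_dbh
from forestdyn.rates import interval_summary, rates_from_summary

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth parameters of a simulated stand.

    Defaults describe a stand comparable to a ~0.8 ha tropical
    permanent-plot block: 26 plots of 300 m^2, about 1500 trees of 118
    species, 3% annual mortality, one recruit per plot per year, and a
    median diameter increment of 0.15 cm/yr.
    """

    n_plots: int = 26
    plot_area_m2: float = 300.0
    n_species: int = 118
    #: geometric-series dominance parameter in (0, 1)
    abundance_k: float = 0.05
    #: initial stand size (trees alive at the first census)
    n_initial_trees: int = 1500
    #: shifted-exponential initial DBH: threshold + Exp(mean=dbh_scale_cm)
    dbh_scale_cm: float = 5.0
    inclusion_dbh_cm: float = 4.99
    #: per-tree annual death probability
    annual_death_prob: float = 0.03
    #: expected recruits per plot per year
    annual_recruit_rate: float = 1.0
    #: lognormal annual DBH increment: median (cm/yr) and log-sd
    growth_median_cm: float = 0.15
    growth_sigma: float = 0.6
    #: sd of the additive measurement jitter on increments (cm)
    measurement_sd_cm: float = 0.05
    p_multistem: float = 0.05
    #: census years (first is the initial census)
    census_years: tuple[int, ...] = (0, 5, 11)
    stand_id: str = "SIM"
    seed: int = 0

    def validate(self) -> None:
        if self.n_plots < 1 or self.plot_area_m2 <= 0:
            raise ConfigurationError("need at least one plot of positive area")
        if not 0 < self.abundance_k < 1:
            raise ConfigurationError("abundance_k must be in (0, 1)")
        if not 0 <= self.annual_death_prob < 1:
            raise ConfigurationError("annual_death_prob must be in [0, 1)")
        if self.annual_recruit_rate < 0:
            raise ConfigurationError("annual_recruit_rate must be >= 0")
        if not 0 <= self.p_multistem < 1:
            raise ConfigurationError("p_multistem must be in [0, 1)")
        if self.n_species < 1 or self.n_initial_trees < 1:
            raise ConfigurationError("need at least one species and one tree")
        if len(self.census_years) < 2 or any(
            a >= b for a, b in zip(self.census_years, self.census_years[1:])
        ):
            raise ConfigurationError("census_years must be at least two, strictly increasing")
        if self.dbh_scale_cm <= 0 or self.growth_median_cm <= 0 or self.growth_sigma <= 0:
            raise ConfigurationError("size/growth scales must be positive")


def _species_probs(params: SimulationParams) -> np.ndarray:
    k = params.abundance_k
    w = k * (1 - k) ** np.arange(params.n_species)
    return w / w.sum()


def simulate_stand(params: SimulationParams) -> CensusRegistry:
    """Simulate a stand and return its census registry (>= 2 censuses)."""
    params_obj = params
    params_obj.validate()
    rng = np.random.default_rng(params_obj.seed)
    probs = _species_probs(params_obj)
    species_names = [f"Species {i + 1:03d}" for i in range(params_obj.n_species)]
    plot_ids = [f"P{j + 1:02d}" for j in range(params_obj.n_plots)]
    years = params_obj.census_years
    census_labels = [f"c{y}" for y in years]

    registry = CensusRegistry(
        stand_id=params_obj.stand_id,
        censuses={label: int(y) for label, y in zip(census_labels, years)},
        n_plots=params_obj.n_plots,
        plot_area_m2=params_obj.plot_area_m2,
    )

    # live state: tree_id -> [species_idx, plot_idx, dbh, alive, recruited_year]
    next_id = 0

    def new_tree() -> str:
        nonlocal next_id
        next_id += 1
        return f"T{next_id:06d}"

    alive: dict[str, dict] = {}
    threshold = params_obj.inclusion_dbh_cm

    def make_stems(tree_id: str, dbh: float) -> tuple[StemMeasurement, ...] | None:
        """Occasionally split the aggregate into 2-3 consistent stems."""
        if rng.random() >= params_obj.p_multistem:
            return None
        n_stems = int(rng.integers(2, 4))
        w = rng.dirichlet(np.ones(n_stems))
        stems = tuple(
            StemMeasurement(tree_id, float(np.sqrt(w_i) * dbh)) for w_i in w
        )
        assert abs(aggregate_stem_dbh(s.dbh_cm for s in stems) - dbh) < 1e-6
        return stems

    # initial cohort
    n0 = params_obj.n_initial_trees
    sp = rng.choice(params_obj.n_species, size=n0, p=probs)
    pl = rng.integers(0, params_obj.n_plots, size=n0)
    d0 = threshold + rng.exponential(params_obj.dbh_scale_cm, size=n0)
    for i in range(n0):
        tid = new_tree()
        alive[tid] = {"sp": int(sp[i]), "plot": int(pl[i]), "dbh": float(d0[i])}

    dead_at: dict[str, int] = {}  # tree_id -> year of first census observed dead
    records: dict[str, TreeRecord] = {}

    def record_for(tid: str, state: dict) -> TreeRecord:
        rec = records.get(tid)
        if rec is None:
            rec = TreeRecord(
                tree_id=tid,
                species=species_names[state["sp"]],
                plot_id=plot_ids[state["plot"]],
                stand_id=params_obj.stand_id,
            )
            records[tid] = rec
        return rec

    def snapshot(label: str) -> None:
        for tid, state in alive.items():
            rec = record_for(tid, state)
            dbh = state["dbh"]
            stems = make_stems(tid, dbh)
            rec.observations[label] = Observation(Status.ALIVE, dbh, stems)
        for tid in dead_at:
            rec = records.get(tid)
            if rec is not None:
                rec.observations[label] = Observation(Status.DEAD)

    mu = np.log(params_obj.growth_median_cm)
    year = years[0]
    snapshot(census_labels[0])
    for label, until in zip(census_labels[1:], years[1:]):
        while year < until:
            year += 1
            ids = list(alive.keys())
            # deaths
            if params_obj.annual_death_prob > 0 and ids:
                dies = rng.random(len(ids)) < params_obj.annual_death_prob
                for tid, dead in zip(ids, dies):
                    if dead:
                        dead_at[tid] = year
                        del alive[tid]
            # growth with measurement jitter, floored at the threshold
            if alive:
                ids = list(alive.keys())
                incr = rng.lognormal(mu, params_obj.growth_sigma, size=len(ids))
                incr += rng.normal(0.0, params_obj.measurement_sd_cm, size=len(ids))
                for tid, g in zip(ids, incr):
                    alive[tid]["dbh"] = max(threshold, alive[tid]["dbh"] + float(g))
            # recruitment: enter just above the inclusion threshold
            lam = params_obj.annual_recruit_rate * params_obj.n_plots
            n_rec = int(rng.poisson(lam)) if lam > 0 else 0
            if n_rec:
                sp_r = rng.choice(params_obj.n_species, size=n_rec, p=probs)
                pl_r = rng.integers(0, params_obj.n_plots, size=n_rec)
                d_r = threshold + rng.exponential(0.3, size=n_rec)
                for i in range(n_rec):
                    tid = new_tree()
                    alive[tid] = {"sp": int(sp_r[i]), "plot": int(pl_r[i]), "dbh": float(d_r[i])}
        snapshot(label)

    for rec in records.values():
        registry.add(rec)
    registry.validate()
    logger.info(
        "simulated stand %s: %d trees over censuses %s (seed=%d)",
        params_obj.stand_id, len(registry.trees), census_labels, params_obj.seed,
    )
    return registry


def recovery_experiment(
    params: SimulationParams,
    n_reps: int = 200,
    census_pair: tuple[int, int] = (0, 1),
) -> pd.DataFrame:
    """Estimate demographic rates on replicate simulations.

    Runs the census -> interval-summary -> rate pipeline once per
    replicate (fresh seed derived from ``params.seed``) and returns one
    row per replicate with the estimated mortality and recruitment plus
    the theoretical mortality target 100q implied by the compound-rate
    convention at the annual scale.
    """
    if n_reps < 2:
        raise ConfigurationError("n_reps must be >= 2")
    params.validate()
    labels = [f"c{y}" for y in params.census_years]
    a, b = labels[census_pair[0]], labels[census_pair[1]]
    rows = []
    ss = np.random.SeedSequence(params.seed)
    child_seeds = ss.generate_state(n_reps).astype(np.int64)
    for rep in range(n_reps):
        p = replace(params, seed=int(child_seeds[rep] % (2**31 - 1)))
        registry = simulate_stand(p)
        summary = interval_summary(registry, a, b)
        rates = rates_from_summary(summary)
        rows.append(
            {
                "rep": rep,
                "n0": summary.n0,
                "nt": summary.nt,
                "dead": summary.dead,
                "recruits": summary.recruits,
                "mortality": rates.mortality,
                "recruitment": rates.recruitment,
                "target_mortality": 100.0 * params.annual_death_prob,
            }
        )
    frame = pd.DataFrame(rows)
    logger.info(
        "recovery experiment: %d reps, mean m=%.3f (target %.3f), mean r=%.3f",
        n_reps, frame["mortality"].mean(), 100 * params.annual_death_prob,
        frame["recruitment"].mean(),
    )
    return frame
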