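"""Pipeline runner and report tables.

Assembles the full analysis of one stand's census series into five
tidy report tables (structure/diversity per census; interval dynamics;
per-interval diameter-class dynamics; per-species dynamics of the most
abundant taxa; a validation log of invariant checks) and renders them
as CSV with half-away-from-zero rounding at the configured precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd
import yaml

from forestdyn.census import CensusRegistry
from forestdyn.config import SurveyConfig, round_half_away
from forestdyn.diversity import diversity_summary, structure_summary
from forestdyn.errors import ConfigurationError, ForestDynError
from forestdyn.io import read_census_csv, read_dwca
from forestdyn.rates import interval_summary, rates_from_summary, dead_recruit_test
from forestdyn.size_classes import (
    DiameterClassScheme,
    class_flows,
    expected_class_frequencies,
    g_test,
)
from forestdyn.species import annotate_guilds, species_interval_rates, top_abundant

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML round-trippable)."""

    input_path: str
    input_format: str = "csv"  # "csv" | "dwca"
    output_dir: str = "forestdyn_report"
    plot_area_m2: float = 300.0
    n_plots: int | None = None
    stand_id: str | None = None
    #: census-label pairs to analyse; default: consecutive censuses
    intervals: list[tuple[str, str]] | None = None
    #: explicit interval lengths (years), keyed "a:b"
    interval_years: dict[str, float] = dc_field(default_factory=dict)
    inclusion_dbh_cm: float = 4.99
    class_breaks_cm: list[float] = dc_field(default_factory=lambda: [5, 10, 20, 40, 80])
    rounding_dp: int = 2
    top_k_species: int = 10

    def survey_config(self) -> SurveyConfig:
        overrides = {}
        for key, t in self.interval_years.items():
            a, _, b = key.partition(":")
            if not b:
                raise ConfigurationError(f"interval_years key {key!r} must be 'a:b'")
            overrides[(a, b)] = float(t)
        return SurveyConfig(
            inclusion_dbh_cm=self.inclusion_dbh_cm,
            class_breaks_cm=tuple(self.class_breaks_cm),
            rounding_dp=self.rounding_dp,
            interval_years=overrides,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or "input_path" not in raw:
            raise ConfigurationError(f"config {path} must be a mapping with input_path")
        if "intervals" in raw and raw["intervals"] is not None:
            raw["intervals"] = [tuple(p) for p in raw["intervals"]]
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dict(self.__dict__)
        if data["intervals"] is not None:
            data["intervals"] = [list(p) for p in data["intervals"]]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def render_table(frame: pd.DataFrame, rounding_dp: int = 2) -> str:
    """Render a report table as CSV text, rounding floats half away from zero."""
    out = frame.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(
                lambda x: round_half_away(x, rounding_dp) if pd.notna(x) else x
            )
    return out.to_csv(index=False)


def _load(config: RunConfig) -> CensusRegistry:
    path = Path(config.input_path)
    if not path.exists():
        raise ConfigurationError(f"input path {path} does not exist")
    cfg = config.survey_config()
    if config.input_format == "dwca":
        return read_dwca(path, plot_area_m2=config.plot_area_m2,
                         n_plots=config.n_plots, stand_id=config.stand_id, config=cfg)
    if config.input_format == "csv":
        return read_census_csv(path, plot_area_m2=config.plot_area_m2,
                               n_plots=config.n_plots, config=cfg)
    raise ConfigurationError(f"unknown input_format {config.input_format!r}")


def structure_table(registry: CensusRegistry, cfg: SurveyConfig) -> pd.DataFrame:
    rows = []
    for label in registry.census_order:
        snap = registry.snapshot(label, cfg)
        s = structure_summary(snap)
        d = diversity_summary(snap)
        rows.append(
            {
                "stand_id": registry.stand_id,
                "census": label,
                "year": snap.census_year,
                "n_individuals": s.n_individuals,
                "density_per_ha": s.density_per_ha,
                "ba_total_m2": s.ba_total_m2,
                "ba_per_ha": s.ba_per_ha,
                "richness": d.richness,
                "shannon_h": d.shannon_h,
                "pielou_j": d.pielou_j,
            }
        )
    return pd.DataFrame(rows)


def dynamics_table(
    registry: CensusRegistry, pairs: list[tuple[str, str]], cfg: SurveyConfig
) -> pd.DataFrame:
    rows = []
    for a, b in pairs:
        summ = interval_summary(registry, a, b, config=cfg)
        rates = rates_from_summary(summ)
        test = dead_recruit_test(summ.dead, summ.recruits) if summ.dead + summ.recruits else None
        rows.append(
            {
                "stand_id": registry.stand_id,
                "interval": f"{a}-{b}",
                "t_years": summ.t_years,
                "n_initial": summ.n0,
                "n_final": summ.nt,
                "survivors": summ.survivors,
                "dead": summ.dead,
                "recruits": summ.recruits,
                "mortality_pct_yr": rates.mortality,
                "recruitment_pct_yr": rates.recruitment,
                "turnover_n_pct_yr": rates.turnover_n,
                "net_change_n_pct_yr": rates.net_change_n,
                "ba_initial_m2": summ.ba0_m2,
                "ba_final_m2": summ.bat_m2,
                "ba_dead_m2": summ.ba_dead_m2,
                "ba_decr_survivors_m2": summ.ba_decr_m2,
                "ba_recruits_m2": summ.ba_recr_m2,
                "ba_incr_survivors_m2": summ.ba_incr_m2,
                "ba_loss_pct_yr": rates.ba_loss,
                "ba_gain_pct_yr": rates.ba_gain,
                "turnover_ba_pct_yr": rates.turnover_ba,
                "net_change_ba_pct_yr": rates.net_change_ba,
                "dead_recruit_z": test.z if test else None,
                "dead_recruit_p_exact": test.p_exact if test else None,
            }
        )
    return pd.DataFrame(rows)


def class_table(
    registry: CensusRegistry, a: str, b: str, cfg: SurveyConfig
) -> pd.DataFrame:
    scheme = DiameterClassScheme.from_config(cfg)
    table = class_flows(registry, a, b, scheme=scheme, config=cfg)
    classed0, classedt = sum(table.n0), sum(table.nt)
    exp_n = expected_class_frequencies(table.n0, classed0, classedt)
    exp_d = expected_class_frequencies(table.dead, classed0, classedt)
    m_rates = table.mortality_rates()
    tests = table.growth_tests()
    rows = []
    for k in range(table.n_classes):
        if table.n0[k] == 0 and table.nt[k] == 0:
            continue  # usually the empty overflow class
        t = tests[k]
        rows.append(
            {
                "stand_id": registry.stand_id,
                "interval": f"{a}-{b}",
                "class": table.labels[k],
                "n_initial": table.n0[k],
                "n_final": table.nt[k],
                "expected_n": exp_n[k],
                "dead": table.dead[k],
                "expected_dead": exp_d[k],
                "mortality_pct_yr": m_rates[k],
                "outgrowth_abs": table.outgrowth[k],
                "recruits": table.recruits[k],
                "ingrowth_abs": table.ingrowth[k],
                "total_outgrowth": table.total_outgrowth[k],
                "total_ingrowth": table.total_ingrowth[k],
                "growth_z": t.z if t else None,
                "growth_p_exact": t.p_exact if t else None,
            }
        )
    return pd.DataFrame(rows)


def species_table(
    registry: CensusRegistry, pairs: list[tuple[str, str]], cfg: SurveyConfig, top_k: int
) -> pd.DataFrame:
    first = registry.census_order[0]
    top = top_abundant(registry.snapshot(first, cfg), top_k)
    guilds = annotate_guilds(top)
    rows = []
    for name in top:
        row: dict = {"stand_id": registry.stand_id, "species": name, "guild": guilds[name]}
        for label in registry.census_order:
            snap = registry.snapshot(label, cfg)
            row[f"n_{label}"] = snap.species_abundances().get(name, 0)
        for a, b in pairs:
            dyn = species_interval_rates(registry, name, a, b, guild=guilds[name], config=cfg)
            row[f"mortality_{a}_{b}"] = dyn.mortality
            row[f"recruitment_{a}_{b}"] = dyn.recruitment
            row[f"p_exact_{a}_{b}"] = dyn.count_test.p_exact if dyn.count_test else None
        rows.append(row)
    return pd.DataFrame(rows)


def validation_table(
    registry: CensusRegistry, pairs: list[tuple[str, str]], cfg: SurveyConfig
) -> pd.DataFrame:
    """Run every invariant check; one row per check with pass/fail."""
    rows = []

    def check(name: str, fn) -> None:
        try:
            fn()
            rows.append({"check": name, "status": "pass", "detail": ""})
        except ForestDynError as exc:
            rows.append({"check": name, "status": "FAIL", "detail": str(exc)})

    check("registry_life_courses", lambda: registry.validate(cfg))
    for a, b in pairs:
        summ = interval_summary(registry, a, b, config=cfg)
        check(f"interval_identities_{a}_{b}", summ.check_identities)
        table = class_flows(registry, a, b, config=cfg)
        check(f"class_conservation_{a}_{b}", table.check_conservation)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full analysis and write all report CSVs.

    Returns the report tables keyed by name; raises on fewer than two
    censuses or on integrity errors.
    """
    cfg = config.survey_config()
    registry = _load(config)
    if len(registry.censuses) < 2:
        raise ConfigurationError(
            f"stand {registry.stand_id} has {len(registry.censuses)} census(es); "
            "at least two are required to compute dynamics"
        )
    order = registry.census_order
    pairs = config.intervals or list(zip(order, order[1:]))
    for a, b in pairs:
        if a not in registry.censuses or b not in registry.censuses:
            raise ConfigurationError(f"configured interval ({a}, {b}) not in census calendar")

    tables: dict[str, pd.DataFrame] = {
        "structure": structure_table(registry, cfg),
        "dynamics": dynamics_table(registry, pairs, cfg),
        "species": species_table(registry, pairs, cfg, config.top_k_species),
        "validation": validation_table(registry, pairs, cfg),
    }
    for a, b in pairs:
        tables[f"classes_{a}_{b}"] = class_table(registry, a, b, cfg)

    # dead-frequency G-test per interval, against scaled expectations
    g_rows = []
    for a, b in pairs:
        flow = class_flows(registry, a, b, config=cfg)
        classed0, classedt = sum(flow.n0), sum(flow.nt)
        exp_all = expected_class_frequencies(flow.dead, classed0, classedt)
        kept = [(d, e) for d, e, n in zip(flow.dead, exp_all, flow.n0) if n > 0 and e > 0]
        obs = [d for d, _ in kept]
        exp = [e for _, e in kept]
        if len(obs) >= 2:
            res = g_test(obs, exp)
            g_rows.append(
                {"interval": f"{a}-{b}", "G": res.g, "df": res.df, "p": res.p}
            )
    tables["g_tests"] = pd.DataFrame(g_rows)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, frame in tables.items():
        (out / f"{name}.csv").write_text(render_table(frame, config.rounding_dp))
    logger.info("wrote %d report tables to %s", len(tables), out)

    failed = tables["validation"][tables["validation"]["status"] != "pass"]
    if len(failed):
        raise ForestDynError(
            f"{len(failed)} validation checks failed: {list(failed['check'])}"
        )
    return tables
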