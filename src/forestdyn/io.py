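"""Readers and writers for repeated-census tables.

Two on-disk representations are supported:

* a **tidy CSV dialect** — one row per tree x census with columns
  ``stand_id, plot_id, tree_id, species, census_label, census_year,
  status, dbh_cm`` — the package's lossless interchange format; and
* **Darwin Core Archives** (DwC-A) as deposited with biodiversity
  aggregators: a directory or zip with ``meta.xml`` describing a
  tab-separated occurrence core and a MeasurementOrFact extension
  carrying the DBH measurements. One occurrence row per tree per census;
  the same ``occurrenceID`` across event dates identifies the same
  physical tree, and the census calendar is derived from ``eventDate``
  years.

The DwC-A reader is deliberately minimal: local archives only, the two
row types above, DBH preferred over basal-area measurement rows, and
units of cm/mm/m honoured.
"""

from __future__ import annotations

import logging
import math
import zipfile
import xml.etree.ElementTree as ET
from io import StringIO
from pathlib import Path

import pandas as pd

from forestdyn.census import (
    CensusRegistry,
    Observation,
    Status,
    TreeRecord,
)
from forestdyn.config import SurveyConfig
from forestdyn.errors import FormatError, IntegrityError

logger = logging.getLogger(__name__)

CSV_COLUMNS = [
    "stand_id",
    "plot_id",
    "tree_id",
    "species",
    "census_label",
    "census_year",
    "status",
    "dbh_cm",
]

_DWC_NS = "http://rs.tdwg.org/dwc/text/"
_OCCURRENCE_ROWTYPE = "http://rs.tdwg.org/dwc/terms/Occurrence"
_MOF_ROWTYPE = "http://rs.tdwg.org/dwc/terms/MeasurementOrFact"


# ---------------------------------------------------------------------------
# tidy CSV dialect


def write_census_csv(registry: CensusRegistry, path: str | Path) -> None:
    """Serialize a registry to the tidy CSV dialect (lossless at tree level).

    Per-stem measurements are not serialized; the aggregate DBH is.
    """
    rows = []
    for record in registry.trees.values():
        for label, year in registry.censuses.items():
            obs = record.observations.get(label)
            status = obs.status if obs is not None else Status.NOT_YET_RECRUITED
            dbh = obs.dbh_cm if obs is not None else None
            rows.append(
                {
                    "stand_id": registry.stand_id,
                    "plot_id": record.plot_id,
                    "tree_id": record.tree_id,
                    "species": record.species,
                    "census_label": label,
                    "census_year": year,
                    "status": status.value,
                    "dbh_cm": "" if dbh is None else f"{dbh:.6f}",
                }
            )
    frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
    frame = frame.sort_values(["tree_id", "census_year"], kind="stable")
    frame.to_csv(path, index=False)
    logger.info("wrote %d rows to %s", len(frame), path)


def read_census_csv(
    path: str | Path,
    plot_area_m2: float = 300.0,
    n_plots: int | None = None,
    config: SurveyConfig | None = None,
    validate: bool = True,
) -> CensusRegistry:
    """Read the tidy CSV dialect into a :class:`CensusRegistry`.

    ``n_plots`` defaults to the number of distinct plot ids present.

    Raises
    ------
    FormatError
        Missing columns or an unknown status token.
    IntegrityError
        Duplicate (tree_id, census_label) rows, conflicting species or
        plot for one tag, a live row without a DBH, or multiple stands
        in one file.
    """
    frame = pd.read_csv(path, dtype={"plot_id": str, "tree_id": str, "census_label": str})
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"census CSV {path} missing columns: {missing}")

    valid_status = {s.value for s in Status}
    bad = set(frame["status"].dropna()) - valid_status
    if bad:
        raise FormatError(f"unknown status tokens {sorted(bad)}; expected {sorted(valid_status)}")

    stands = frame["stand_id"].dropna().unique()
    if len(stands) > 1:
        raise IntegrityError(f"census CSV {path} mixes stands {list(stands)}")
    stand_id = str(stands[0]) if len(stands) else "stand"

    dup = frame.duplicated(subset=["tree_id", "census_label"])
    if dup.any():
        pairs = frame.loc[dup, ["tree_id", "census_label"]].values.tolist()
        raise IntegrityError(f"duplicate (tree_id, census_label) rows: {pairs[:5]}")

    censuses = (
        frame[["census_label", "census_year"]]
        .drop_duplicates()
        .sort_values("census_year")
    )
    registry = CensusRegistry(
        stand_id=stand_id,
        censuses={str(r.census_label): int(r.census_year) for r in censuses.itertuples()},
        n_plots=n_plots if n_plots is not None else int(frame["plot_id"].nunique()),
        plot_area_m2=plot_area_m2,
    )

    for tree_id, group in frame.groupby("tree_id", sort=True):
        species = group["species"].iloc[0]
        plot = group["plot_id"].iloc[0]
        if group["species"].nunique() > 1 or group["plot_id"].nunique() > 1:
            raise IntegrityError(f"tree {tree_id}: conflicting species/plot across rows")
        record = TreeRecord(str(tree_id), str(species), str(plot), stand_id)
        for row in group.itertuples():
            status = Status(row.status)
            dbh = None if pd.isna(row.dbh_cm) else float(row.dbh_cm)
            if status is Status.ALIVE and dbh is None:
                raise IntegrityError(f"tree {tree_id}: alive at {row.census_label} without DBH")
            record.observations[str(row.census_label)] = Observation(status, dbh)
        registry.add(record)

    logger.info(
        "read %d rows -> %d trees, %d censuses from %s",
        len(frame), len(registry.trees), len(registry.censuses), path,
    )
    if validate:
        registry.validate(config)
    return registry


# ---------------------------------------------------------------------------
# Darwin Core Archive


def _read_archive_file(archive: str | Path, name: str) -> str:
    p = Path(archive)
    if p.is_dir():
        f = p / name
        if not f.exists():
            raise FormatError(f"archive {archive} has no {name}")
        return f.read_text(encoding="utf-8")
    if zipfile.is_zipfile(p):
        with zipfile.ZipFile(p) as zf:
            if name not in zf.namelist():
                raise FormatError(f"archive {archive} has no {name}")
            return zf.read(name).decode("utf-8")
    raise FormatError(f"{archive} is neither a directory nor a zip archive")


def _parse_meta(meta_xml: str) -> dict:
    """Extract file locations and index->term maps from meta.xml."""
    root = ET.fromstring(meta_xml)

    def parse_table(el: ET.Element) -> dict:
        loc = el.find(f"{{{_DWC_NS}}}files/{{{_DWC_NS}}}location")
        if loc is None or not loc.text:
            raise FormatError("meta.xml table without a file location")
        fields = {}
        for f in el.findall(f"{{{_DWC_NS}}}field"):
            fields[int(f.attrib["index"])] = f.attrib["term"]
        id_el = el.find(f"{{{_DWC_NS}}}id")
        if id_el is None:
            id_el = el.find(f"{{{_DWC_NS}}}coreid")
        return {
            "location": loc.text.strip(),
            "fields": fields,
            "id_index": int(id_el.attrib["index"]) if id_el is not None else 0,
        }

    core = root.find(f"{{{_DWC_NS}}}core")
    if core is None or core.attrib.get("rowType") != _OCCURRENCE_ROWTYPE:
        raise FormatError("meta.xml lacks an Occurrence core table")
    mof = None
    for ext in root.findall(f"{{{_DWC_NS}}}extension"):
        if ext.attrib.get("rowType") == _MOF_ROWTYPE:
            mof = ext
            break
    if mof is None:
        raise FormatError("meta.xml lacks a MeasurementOrFact extension")
    return {"core": parse_table(core), "extension": parse_table(mof)}


def _load_table(archive: str | Path, spec: dict) -> pd.DataFrame:
    text = _read_archive_file(archive, spec["location"])
    frame = pd.read_csv(StringIO(text), sep="\t", header=0, dtype=str)
    ncol = frame.shape[1]
    rename = {}
    for idx, term in spec["fields"].items():
        if idx < ncol:
            rename[frame.columns[idx]] = term.rsplit("/", 1)[-1]
    frame.columns = [rename.get(c, c) for c in frame.columns]
    frame["rowid"] = frame.iloc[:, spec["id_index"]].astype(str)
    return frame


def _dbh_from_measurements(mof: pd.DataFrame) -> dict[str, float]:
    """row id -> DBH (cm), preferring diameter over basal-area rows."""
    unit_to_cm = {"cm": 1.0, "centimeters": 1.0, "mm": 0.1, "m": 100.0, "": 1.0}
    out: dict[str, float] = {}
    for row in mof.itertuples():
        mtype = str(getattr(row, "measurementType", "") or "").lower()
        if "diameter" not in mtype and "dbh" not in mtype:
            continue  # e.g. basal-area measurement rows
        try:
            value = float(row.measurementValue)
        except (TypeError, ValueError):
            logger.warning("unparseable measurementValue %r for row %s; skipped",
                           row.measurementValue, row.rowid)
            continue
        unit = str(getattr(row, "measurementUnit", "cm") or "cm").strip().lower()
        factor = unit_to_cm.get(unit)
        if factor is None:
            logger.warning("unknown measurementUnit %r for row %s; assuming cm",
                           unit, row.rowid)
            factor = 1.0
        out[row.rowid] = value * factor
    return out


def read_dwca(
    archive_path: str | Path,
    plot_area_m2: float = 300.0,
    n_plots: int | None = None,
    stand_id: str | None = None,
    config: SurveyConfig | None = None,
    validate: bool = True,
) -> CensusRegistry:
    """Read a Darwin Core Archive into a :class:`CensusRegistry`.

    One occurrence row per tree per census; trees are matched across
    censuses by ``occurrenceID`` and censuses are identified by the year
    of ``eventDate``. DBH comes from MeasurementOrFact rows whose
    ``measurementType`` mentions diameter/DBH (basal-area rows are
    ignored); ``measurementUnit`` is honoured. Rows with unparseable
    event dates are skipped with a warning.
    """
    meta = _parse_meta(_read_archive_file(archive_path, "meta.xml"))
    occ = _load_table(archive_path, meta["core"])
    mof = _load_table(archive_path, meta["extension"])

    for col in ("occurrenceID", "scientificName", "eventDate"):
        if col not in occ.columns:
            raise FormatError(f"occurrence core lacks {col}")

    dbh_by_row = _dbh_from_measurements(mof)

    # census calendar from event-date years
    years: set[int] = set()
    parsed_years: list[int | None] = []
    for raw in occ["eventDate"]:
        try:
            year = int(str(raw)[:4])
            if not 0 <= year <= 9999:
                raise ValueError
        except (TypeError, ValueError):
            logger.warning("unparseable eventDate %r; row skipped", raw)
            parsed_years.append(None)
            continue
        parsed_years.append(year)
        years.add(year)
    occ = occ.assign(year_parsed=parsed_years)

    stand = stand_id or (
        str(occ["datasetName"].iloc[0]) if "datasetName" in occ.columns and len(occ) else "stand"
    )
    registry = CensusRegistry(
        stand_id=stand,
        censuses={str(y): y for y in sorted(years)},
        n_plots=n_plots
        if n_plots is not None
        else (int(occ["locationID"].nunique()) if "locationID" in occ.columns else 1),
        plot_area_m2=plot_area_m2,
    )

    seen: set[tuple[str, int]] = set()
    for row in occ.itertuples():
        if pd.isna(row.year_parsed):  # skipped above; column may be float
            continue
        year = int(row.year_parsed)
        tree_id = str(row.occurrenceID)
        key = (tree_id, year)
        if key in seen:
            raise IntegrityError(
                f"duplicate occurrence for tree {tree_id} at census {year}"
            )
        seen.add(key)
        record = registry.trees.get(tree_id)
        if record is None:
            record = TreeRecord(
                tree_id=tree_id,
                species=str(row.scientificName),
                plot_id=str(getattr(row, "locationID", "") or ""),
                stand_id=stand,
            )
            registry.add(record)
        vitality = str(getattr(row, "vitality", "alive") or "alive").strip().lower()
        if vitality in ("alive", "living", "live"):
            status = Status.ALIVE
        elif vitality == "dead":
            status = Status.DEAD
        else:
            logger.warning("unknown vitality %r for tree %s; treated as alive", vitality, tree_id)
            status = Status.ALIVE
        dbh = dbh_by_row.get(row.rowid)
        if status is Status.ALIVE and (dbh is None or not math.isfinite(dbh)):
            raise IntegrityError(f"tree {tree_id}: live occurrence at {year} without DBH")
        record.observations[str(year)] = Observation(status, dbh)

    logger.info(
        "DwC-A %s: %d occurrences -> %d trees, %d censuses",
        archive_path, len(occ), len(registry.trees), len(registry.censuses),
    )
    if validate:
        registry.validate(config)
    return registry


_META_TEMPLATE = """<?xml version="1.0" encoding="UTF-8"?>
<archive xmlns="http://rs.tdwg.org/dwc/text/">
  <core rowType="http://rs.tdwg.org/dwc/terms/Occurrence" encoding="UTF-8"
        fieldsTerminatedBy="\\t" linesTerminatedBy="\\n" ignoreHeaderLines="1">
    <files><location>occurrence.txt</location></files>
    <id index="0"/>
    <field index="1" term="http://rs.tdwg.org/dwc/terms/occurrenceID"/>
    <field index="2" term="http://rs.tdwg.org/dwc/terms/scientificName"/>
    <field index="3" term="http://rs.tdwg.org/dwc/terms/eventDate"/>
    <field index="4" term="http://rs.tdwg.org/dwc/terms/locationID"/>
    <field index="5" term="http://rs.tdwg.org/dwc/terms/vitality"/>
  </core>
  <extension rowType="http://rs.tdwg.org/dwc/terms/MeasurementOrFact" encoding="UTF-8"
             fieldsTerminatedBy="\\t" linesTerminatedBy="\\n" ignoreHeaderLines="1">
    <files><location>measurementorfact.txt</location></files>
    <coreid index="0"/>
    <field index="1" term="http://rs.tdwg.org/dwc/terms/measurementType"/>
    <field index="2" term="http://rs.tdwg.org/dwc/terms/measurementValue"/>
    <field index="3" term="http://rs.tdwg.org/dwc/terms/measurementUnit"/>
  </extension>
</archive>
"""


def write_dwca(registry: CensusRegistry, directory: str | Path) -> Path:
    """Write a registry as an unzipped DwC-A-shaped fixture directory.

    Emits ``meta.xml``, ``occurrence.txt`` and ``measurementorfact.txt``
    in the layout :func:`read_dwca` consumes (round-trip tested).
    """
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    occ_rows, mof_rows = [], []
    i = 0
    for record in sorted(registry.trees.values(), key=lambda r: r.tree_id):
        for label, year in registry.censuses.items():
            obs = record.observations.get(label)
            if obs is None or obs.status is Status.NOT_YET_RECRUITED:
                continue
            i += 1
            rid = f"r{i:06d}"
            occ_rows.append(
                (rid, record.tree_id, record.species, str(year), record.plot_id,
                 obs.status.value if obs.status is not Status.NOT_YET_RECRUITED else "")
            )
            if obs.dbh_cm is not None:
                mof_rows.append(
                    (rid, "diameter at breast height (DBH)", f"{obs.dbh_cm:.6f}", "cm")
                )
    (out / "meta.xml").write_text(_META_TEMPLATE, encoding="utf-8")
    with open(out / "occurrence.txt", "w", encoding="utf-8") as fh:
        fh.write("id\toccurrenceID\tscientificName\teventDate\tlocationID\tvitality\n")
        for row in occ_rows:
            fh.write("\t".join(row) + "\n")
    with open(out / "measurementorfact.txt", "w", encoding="utf-8") as fh:
        fh.write("id\tmeasurementType\tmeasurementValue\tmeasurementUnit\n")
        for row in mof_rows:
            fh.write("\t".join(row) + "\n")
    logger.info("wrote DwC-A fixture with %d occurrences to %s", len(occ_rows), out)
    return out
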