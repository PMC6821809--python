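"""Tabular input/output for camera-trap survey data.

The analysis consumes four comma-delimited UTF-8 tables:

``records.csv``
    One row per station-level detection: ``station_id,species,date``.
    Two cameras at a station are collapsed upstream — a species detected by
    either camera on a date yields one record.
``stations.csv``
    ``station_id,site_id,landscape_id,x,y,deploy_start,deploy_end`` with
    projected planar coordinates in meters and ISO-8601 dates.
``traits.csv``
    ``unit_id,member_species,iucn,body_mass_g,pair_id`` — one row per
    analysis unit (a species, or a genus-level group such as *Manis* spp.
    pooling species that cannot be told apart on camera-trap images).
    ``member_species`` is a ``;``-separated list of raw species names.
``villages.csv``
    ``x,y`` village points in the same projected coordinate system.

Coordinates must be planar meters: the survey design (2.5 km station
spacing) and the 15 km kernel radius are metric, so tables whose
coordinates look like geographic degrees are rejected rather than silently
projected.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, RowError

IUCN_CATEGORIES = frozenset({"LC", "NT", "VU", "EN", "CR", "DD"})

#: Survey design minimum deployment, in days (inclusive of both end dates).
MIN_DEPLOYMENT_DAYS = 60

RECORD_COLUMNS = ["station_id", "species", "date"]
STATION_COLUMNS = ["station_id", "site_id", "landscape_id", "x", "y",
                   "deploy_start", "deploy_end"]
TRAIT_COLUMNS = ["unit_id", "member_species", "iucn", "body_mass_g", "pair_id"]
VILLAGE_COLUMNS = ["x", "y"]


@dataclass(frozen=True)
class DetectionRecord:
    station_id: str
    unit_id: str
    date: _dt.date


@dataclass(frozen=True)
class Station:
    station_id: str
    site_id: str
    landscape_id: str
    x: float
    y: float
    deploy_start: _dt.date
    deploy_end: _dt.date

    @property
    def deployment_days(self) -> int:
        """Number of active days, counting both end dates."""
        return (self.deploy_end - self.deploy_start).days + 1


@dataclass(frozen=True)
class SpeciesTraits:
    unit_id: str
    iucn: str
    body_mass_g: float
    pair_id: str | None = None
    member_species: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class Village:
    x: float
    y: float


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}; "
                          f"found {list(df.columns)}")


def _parse_date(value, line: int, column: str = "date") -> _dt.date:
    try:
        return _dt.date.fromisoformat(str(value).strip())
    except (ValueError, TypeError) as exc:
        raise RowError(f"unparsable {column} {value!r} ({exc})", line=line) from None


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False,
                         skip_blank_lines=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file, header required") from None
    _require_columns(df, required, path)
    return df


def read_detection_records(path) -> pd.DataFrame:
    """Read station-level detection records.

    Returns a DataFrame with columns ``station_id`` (str), ``species`` (str)
    and ``date`` (:class:`datetime.date`). An empty file with only a header
    yields an empty frame.
    """
    df = _read_csv(path, RECORD_COLUMNS)
    dates = [_parse_date(v, line=i + 2) for i, v in enumerate(df["date"])]
    out = pd.DataFrame({
        "station_id": df["station_id"].str.strip(),
        "species": df["species"].str.strip(),
        "date": dates,
    })
    blank = out["station_id"].eq("") | out["species"].eq("")
    if blank.any():
        raise RowError("blank station_id or species",
                       line=int(np.flatnonzero(blank)[0]) + 2)
    return out


def _coord(value, line: int, column: str) -> float:
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise RowError(f"unparsable coordinate {column}={value!r}", line=line) from None
    if not np.isfinite(v):
        raise RowError(f"non-finite coordinate {column}={value!r}", line=line)
    return v


def _reject_geographic(x: np.ndarray, y: np.ndarray, path) -> None:
    # Planar-meter check: a full table inside lon/lat bounds cannot be a
    # metric survey grid (stations are kilometers apart).
    if len(x) and np.all(np.abs(x) <= 360.0) and np.all(np.abs(y) <= 90.0):
        raise FormatError(
            f"{path}: coordinates look like geographic degrees "
            "(all |x| <= 360 and |y| <= 90); supply projected planar "
            "coordinates in meters — they are not reprojected automatically")


def read_stations(path) -> pd.DataFrame:
    """Read the station table.

    Validates planar coordinates and deployment windows; deployments shorter
    than the 60-day design minimum trigger a warning (not an error, so that
    curtailed deployments remain analyzable with reduced effort).
    """
    df = _read_csv(path, STATION_COLUMNS)
    n = len(df)
    x = np.array([_coord(v, i + 2, "x") for i, v in enumerate(df["x"])])
    y = np.array([_coord(v, i + 2, "y") for i, v in enumerate(df["y"])])
    _reject_geographic(x, y, path)
    start = [_parse_date(v, i + 2, "deploy_start") for i, v in enumerate(df["deploy_start"])]
    end = [_parse_date(v, i + 2, "deploy_end") for i, v in enumerate(df["deploy_end"])]
    out = pd.DataFrame({
        "station_id": df["station_id"].str.strip(),
        "site_id": df["site_id"].str.strip(),
        "landscape_id": df["landscape_id"].str.strip(),
        "x": x, "y": y,
        "deploy_start": start, "deploy_end": end,
    })
    if "canopy" in df.columns:
        # optional pre-computed canopy-closure fraction rides along
        canopy = pd.to_numeric(df["canopy"], errors="coerce")
        bad = canopy.isna() | (canopy < 0) | (canopy > 1)
        if bad.any():
            raise RowError("canopy must be a fraction in [0, 1]",
                           line=int(np.flatnonzero(bad)[0]) + 2)
        out["canopy"] = canopy.to_numpy(dtype=float)
    if out["station_id"].duplicated().any():
        dup = out["station_id"][out["station_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate station_id {dup!r}")
    for i in range(n):
        days = (out["deploy_end"][i] - out["deploy_start"][i]).days + 1
        if days <= 0:
            raise RowError(f"deploy_end before deploy_start for station "
                           f"{out['station_id'][i]!r}", line=i + 2)
        if days < MIN_DEPLOYMENT_DAYS:
            warnings.warn(
                f"station {out['station_id'][i]!r} deployed {days} days, "
                f"below the {MIN_DEPLOYMENT_DAYS}-day design minimum",
                stacklevel=2)
    return out


def read_species_traits(path) -> pd.DataFrame:
    """Read the analysis-unit trait table.

    ``member_species`` is split on ``;`` into a tuple of raw species names;
    an empty field means the unit is itself a single species with the same
    name as ``unit_id``.
    """
    df = _read_csv(path, TRAIT_COLUMNS)
    masses = []
    for i, v in enumerate(df["body_mass_g"]):
        try:
            m = float(v)
        except (TypeError, ValueError):
            raise RowError(f"unparsable body_mass_g {v!r}", line=i + 2) from None
        if not (m > 0) or not np.isfinite(m):
            raise RowError(f"body_mass_g must be > 0, got {v!r}", line=i + 2)
        masses.append(m)
    iucn = df["iucn"].str.strip().str.upper()
    bad = ~iucn.isin(IUCN_CATEGORIES)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise RowError(f"unknown IUCN category {df['iucn'][i]!r} "
                       f"(expected one of {sorted(IUCN_CATEGORIES)})", line=i + 2)
    members = [
        tuple(s.strip() for s in str(m).split(";") if s.strip()) or (u,)
        for u, m in zip(df["unit_id"].str.strip(), df["member_species"])
    ]
    out = pd.DataFrame({
        "unit_id": df["unit_id"].str.strip(),
        "member_species": members,
        "iucn": iucn,
        "body_mass_g": masses,
        "pair_id": df["pair_id"].str.strip().replace("", None),
    })
    if out["unit_id"].duplicated().any():
        dup = out["unit_id"][out["unit_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate unit_id {dup!r}")
    return out


def read_villages(path) -> pd.DataFrame:
    """Read village points (planar meters)."""
    df = _read_csv(path, VILLAGE_COLUMNS)
    x = np.array([_coord(v, i + 2, "x") for i, v in enumerate(df["x"])])
    y = np.array([_coord(v, i + 2, "y") for i, v in enumerate(df["y"])])
    _reject_geographic(x, y, path)
    return pd.DataFrame({"x": x, "y": y})


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers)

def write_detection_records(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["date"] = [d.isoformat() for d in out["date"]]
    cols = [c for c in ("station_id", "species", "unit_id", "date") if c in out]
    out[cols].to_csv(path, index=False)


def write_stations(stations: pd.DataFrame, path) -> None:
    out = stations.copy()
    out["deploy_start"] = [d.isoformat() for d in out["deploy_start"]]
    out["deploy_end"] = [d.isoformat() for d in out["deploy_end"]]
    out[STATION_COLUMNS].to_csv(path, index=False)


def write_species_traits(traits: pd.DataFrame, path) -> None:
    out = traits.copy()
    out["member_species"] = [";".join(m) for m in out["member_species"]]
    out["pair_id"] = out["pair_id"].fillna("")
    out[TRAIT_COLUMNS].to_csv(path, index=False)


def write_villages(villages: pd.DataFrame, path) -> None:
    villages[VILLAGE_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------

def species_to_unit_map(traits: pd.DataFrame) -> dict[str, str]:
    """Map every raw species name to its analysis unit.

    Raises :class:`ConfigurationError` if a species is claimed by two units.
    """
    mapping: dict[str, str] = {}
    for unit, members in zip(traits["unit_id"], traits["member_species"]):
        for sp in members:
            if sp in mapping and mapping[sp] != unit:
                raise ConfigurationError(
                    f"species {sp!r} mapped to both {mapping[sp]!r} and {unit!r}")
            mapping[sp] = unit
    return mapping


def merge_to_analysis_units(records: pd.DataFrame,
                            traits: pd.DataFrame) -> pd.DataFrame:
    """Relabel species records by analysis unit and collapse duplicates.

    Species that cannot be distinguished on camera-trap images (e.g. the two
    *Manis* pangolins) are pooled into one unit; records of merged species at
    the same station on the same date collapse to a single unit-level record.

    Returns a DataFrame with columns ``station_id``, ``unit_id``, ``date``,
    deduplicated on those three columns.
    """
    mapping = species_to_unit_map(traits)
    unknown = sorted(set(records["species"]) - set(mapping))
    if unknown:
        raise ConfigurationError(
            f"species not mapped to any analysis unit: {unknown}")
    out = pd.DataFrame({
        "station_id": records["station_id"],
        "unit_id": records["species"].map(mapping),
        "date": records["date"],
    })
    return (out.drop_duplicates(["station_id", "unit_id", "date"])
               .reset_index(drop=True))
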