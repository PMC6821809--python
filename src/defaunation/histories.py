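"""Pooling dated detection records into occasion-structured histories.

Camera-trap records are pooled into fixed-length sampling occasions
(default 10 days), the unit of replication for the occupancy model.
Occasions are anchored per station at its own deployment start; a trailing
partial occasion is retained, with its effort set to the remaining active
days, rather than discarded — the model carries effort as a detection
covariate, so partial occasions contribute information instead of bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

DEFAULT_OCCASION_LENGTH = 10


@dataclass
class DetectionHistory:
    """Binary detection tensor with aligned effort.

    Attributes
    ----------
    y : ndarray of uint8, shape (n_units, n_stations, n_occasions)
        1 if the unit was recorded at the station during the occasion.
    effort : ndarray of float, shape (n_stations, n_occasions)
        Active camera-days in each occasion, in ``[0, occasion_length]``.
        Zero effort marks occasions after a station's deployment ended;
        ``y`` is structurally zero there.
    units, stations : list of str
        Axis labels for the first two dimensions.
    occasion_length : int
        Occasion length in days.
    """

    y: np.ndarray
    effort: np.ndarray
    units: list[str]
    stations: list[str]
    occasion_length: int = DEFAULT_OCCASION_LENGTH

    def __post_init__(self):
        self.unit_index = {u: i for i, u in enumerate(self.units)}
        self.station_index = {s: j for j, s in enumerate(self.stations)}

    @property
    def n_units(self) -> int:
        return self.y.shape[0]

    @property
    def n_stations(self) -> int:
        return self.y.shape[1]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[2]

    def validate(self) -> None:
        if self.y.shape[1:] != self.effort.shape:
            raise ValueError("y and effort station/occasion axes disagree")
        if np.any((self.effort > 0) & (self.effort > self.occasion_length)):
            raise ValueError("effort exceeds occasion length")
        if np.any(self.y[:, self.effort == 0]):
            raise ValueError("detection recorded in a zero-effort occasion")


def station_effort(deployment_days: int, occasion_length: int) -> np.ndarray:
    """Per-occasion active days for one station.

    >>> station_effort(63, 10)
    array([10., 10., 10., 10., 10., 10.,  3.])
    """
    n_occ = math.ceil(deployment_days / occasion_length)
    eff = np.full(n_occ, float(occasion_length))
    rem = deployment_days - (n_occ - 1) * occasion_length
    eff[-1] = float(rem)
    return eff


def build_detection_history(records: pd.DataFrame,
                            stations: pd.DataFrame,
                            occasion_length: int = DEFAULT_OCCASION_LENGTH,
                            units: list[str] | None = None) -> DetectionHistory:
    """Pool unit-level records into a :class:`DetectionHistory`.

    Parameters
    ----------
    records : DataFrame
        Columns ``station_id``, ``unit_id``, ``date`` (station-level,
        unit-relabeled records).
    stations : DataFrame
        Station table as returned by :func:`defaunation.io.read_stations`.
    occasion_length : int
        Days per occasion.
    units : list of str, optional
        Unit axis; defaults to the sorted units appearing in ``records``.
        Pass the full analysis-unit list to include never-detected units as
        all-zero rows.

    Raises
    ------
    ConfigurationError
        If a record names an unknown station or falls outside its station's
        deployment window.
    """
    if occasion_length < 1:
        raise ValueError("occasion_length must be >= 1 day")
    st_ids = list(stations["station_id"])
    st_pos = {s: j for j, s in enumerate(st_ids)}
    starts = list(stations["deploy_start"])
    ends = list(stations["deploy_end"])
    dep_days = np.array([(e - s).days + 1 for s, e in zip(starts, ends)])

    n_occ = int(np.ceil(dep_days / occasion_length).max()) if len(st_ids) else 0
    effort = np.zeros((len(st_ids), n_occ))
    for j, days in enumerate(dep_days):
        e = station_effort(int(days), occasion_length)
        effort[j, :len(e)] = e

    if units is None:
        units = sorted(set(records["unit_id"]))
    unit_pos = {u: i for i, u in enumerate(units)}

    y = np.zeros((len(units), len(st_ids), n_occ), dtype=np.uint8)
    for row in records.itertuples(index=False):
        j = st_pos.get(row.station_id)
        if j is None:
            raise ConfigurationError(
                f"record references unknown station {row.station_id!r}")
        offset = (row.date - starts[j]).days
        if offset < 0 or row.date > ends[j]:
            raise ConfigurationError(
                f"record ({row.unit_id!r}, {row.station_id!r}, {row.date}) "
                f"outside deployment window {starts[j]}..{ends[j]}")
        i = unit_pos.get(row.unit_id)
        if i is None:
            raise ConfigurationError(
                f"record references unit {row.unit_id!r} absent from the "
                "unit axis")
        y[i, j, offset // occasion_length] = 1

    return DetectionHistory(y=y, effort=effort, units=list(units),
                            stations=st_ids, occasion_length=occasion_length)


def station_presence(history: DetectionHistory) -> pd.DataFrame:
    """Collapse occasions: 1 if the unit was ever recorded at the station.

    Returns a units x stations binary DataFrame — the input to the
    functional-extinction rule, which asks at what fraction of stations a
    unit was recorded at all. Independent of occasion length.
    """
    presence = history.y.any(axis=2).astype(np.uint8)
    return pd.DataFrame(presence, index=history.units, columns=history.stations)


def export_history(history: DetectionHistory, y_path, effort_path) -> None:
    """Write the tensors as wide CSV: one row per unit x station, occasion columns."""
    occ_cols = [f"occ{k + 1}" for k in range(history.n_occasions)]
    rows = []
    for i, u in enumerate(history.units):
        for j, s in enumerate(history.stations):
            rows.append([u, s, *history.y[i, j]])
    pd.DataFrame(rows, columns=["unit_id", "station_id", *occ_cols]).to_csv(
        y_path, index=False)
    eff = pd.DataFrame(history.effort, columns=occ_cols)
    eff.insert(0, "station_id", history.stations)
    eff.to_csv(effort_path, index=False)
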