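"""Domain types and stem-map I/O.

A *stem map* is the universal input of every analysis in this package: an
axis-aligned rectangular plot window (metres) plus one record per mapped
stem.  Stems carry a status code distinguishing live planted trees, live
later-coming populations (LCPs, naturally colonising unplanted trees),
standing dead trees (snags), fallen wood, broken wood, and harvest stumps.

Geometry is planimetric: coordinates are 2-D metres; an elevation column is
parsed if present but ignored by every statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STATUSES = ("live_planted", "live_lcp", "snag", "fallen", "broken", "stump")
LIVE_STATUSES = ("live_planted", "live_lcp")
DEADWOOD_STATUSES = ("snag", "fallen", "broken")

#: census threshold: stems below this DBH are normally not mapped in the field
DBH_CENSUS_THRESHOLD_CM = 1.0

STEM_COLUMNS = (
    "id",
    "x",
    "y",
    "species",
    "dbh",
    "height_or_length",
    "mid_diameter",
    "status",
    "decay",
)

MANDATORY_COLUMNS = ("id", "x", "y", "species", "dbh", "status")


class StandError(Exception):
    """Base class for all stem-map errors."""


class StemMapFormatError(StandError):
    """A file-level problem: missing column, duplicate ids, bad window."""


class StemRowError(StandError):
    """A row-level parse problem; carries the offending 0-based row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class ClassificationError(StandError):
    """A stem could not be assigned to a live/dead group."""


@dataclass(frozen=True)
class PlotWindow:
    """Axis-aligned rectangular plot, coordinates in metres."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise StemMapFormatError(
                f"degenerate window ({self.x_min},{self.y_min})-"
                f"({self.x_max},{self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def short_side(self) -> float:
        return min(self.width, self.height)

    def contains(self, x: float, y: float, tol: float = 0.0) -> bool:
        return (
            self.x_min - tol <= x <= self.x_max + tol
            and self.y_min - tol <= y <= self.y_max + tol
        )


@dataclass
class StemRecord:
    """One mapped stem.

    dbh is d_1.3 (diameter at breast height, cm); ``height_or_length`` is
    tree height for standing stems and piece length for fallen/broken wood
    (m); ``mid_diameter`` is the central diameter d_1/2 of lying deadwood
    (cm), mandatory for broken wood.
    """

    id: str
    x: float
    y: float
    species: str
    status: str
    dbh: float | None = None
    height_or_length: float | None = None
    mid_diameter: float | None = None
    decay: int | None = None

    def validate(self) -> None:
        if self.status not in STATUSES:
            raise StandError(f"stem {self.id}: unknown status {self.status!r}")
        if self.status != "stump":
            if self.dbh is None or not np.isfinite(self.dbh) or self.dbh <= 0:
                raise StandError(
                    f"stem {self.id}: dbh must be positive for status {self.status}"
                )
            if self.dbh <= DBH_CENSUS_THRESHOLD_CM:
                warnings.warn(
                    f"stem {self.id}: dbh {self.dbh} cm at or below the "
                    f"{DBH_CENSUS_THRESHOLD_CM} cm census threshold",
                    stacklevel=2,
                )
        if self.status == "broken" and self.mid_diameter is None:
            raise StandError(f"stem {self.id}: broken wood requires mid_diameter")
        if self.decay is not None and self.decay not in (1, 2, 3, 4, 5):
            raise StandError(f"stem {self.id}: decay grade must be 1-5")


@dataclass
class StemMap:
    """A plot window plus its stems; the input of every analysis stage."""

    window: PlotWindow
    stems: list[StemRecord]
    planted_species: frozenset[str] = field(default_factory=frozenset)
    #: rows rejected at read time: list of (row index, reason)
    rejected: list[tuple[int, str]] = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.planted_species = frozenset(self.planted_species)
        ids = [s.id for s in self.stems]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).loc[lambda s: s.duplicated()].iloc[0]
            raise StemMapFormatError(f"duplicate stem id {dup!r}")

    def __len__(self) -> int:
        return len(self.stems)

    def validate(self) -> None:
        for s in self.stems:
            s.validate()
            if not self.window.contains(s.x, s.y):
                raise StandError(f"stem {s.id} outside the plot window")

    def counts_by_status(self) -> dict[str, int]:
        counts = {s: 0 for s in STATUSES}
        for stem in self.stems:
            counts[stem.status] += 1
        return counts

    def coords(self, ids: Sequence[str] | None = None) -> np.ndarray:
        stems = self.stems if ids is None else [self.by_id(i) for i in ids]
        return np.array([(s.x, s.y) for s in stems], dtype=float).reshape(-1, 2)

    def by_id(self, stem_id: str) -> StemRecord:
        return self._index()[stem_id]

    def _index(self) -> dict[str, StemRecord]:
        idx = getattr(self, "_id_index", None)
        if idx is None or len(idx) != len(self.stems):
            idx = {s.id: s for s in self.stems}
            object.__setattr__(self, "_id_index", idx)
        return idx

    def subset(self, ids: Iterable[str]) -> "StemMap":
        keep = set(ids)
        return StemMap(
            window=self.window,
            stems=[s for s in self.stems if s.id in keep],
            planted_species=self.planted_species,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": s.id,
                "x": s.x,
                "y": s.y,
                "species": s.species,
                "dbh": s.dbh,
                "height_or_length": s.height_or_length,
                "mid_diameter": s.mid_diameter,
                "status": s.status,
                "decay": s.decay,
            }
            for s in self.stems
        ]
        return pd.DataFrame(rows, columns=list(STEM_COLUMNS))


def _parse_float(value, row: int, column: str) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise StemRowError(row, f"non-numeric {column}: {value!r}") from None


def read_stem_map(
    path,
    window: PlotWindow,
    planted_species: Iterable[str] = (),
    *,
    boundary_tol: float = 0.0,
) -> StemMap:
    """Read a comma-separated stem map (UTF-8, header required).

    Column order is irrelevant; missing values are empty strings.  Rows with
    coordinates outside the window (beyond ``boundary_tol``) are rejected
    into ``StemMap.rejected`` rather than raising.  Missing mandatory
    columns, non-numeric coordinates/DBH, and duplicate ids raise.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise StemMapFormatError(f"missing mandatory column {col!r}")

    stems: list[StemRecord] = []
    rejected: list[tuple[int, str]] = []
    for row_idx, row in enumerate(df.to_dict("records")):
        x = _parse_float(row["x"], row_idx, "x")
        y = _parse_float(row["y"], row_idx, "y")
        if x is None or y is None:
            raise StemRowError(row_idx, "missing coordinate")
        if not window.contains(x, y, tol=boundary_tol):
            rejected.append((row_idx, f"coordinates ({x}, {y}) outside window"))
            continue
        decay_raw = row.get("decay", "")
        stem = StemRecord(
            id=str(row["id"]),
            x=x,
            y=y,
            species=str(row["species"]),
            status=str(row["status"]),
            dbh=_parse_float(row["dbh"], row_idx, "dbh"),
            height_or_length=_parse_float(
                row.get("height_or_length", ""), row_idx, "height_or_length"
            ),
            mid_diameter=_parse_float(
                row.get("mid_diameter", ""), row_idx, "mid_diameter"
            ),
            decay=int(float(decay_raw)) if str(decay_raw).strip() != "" else None,
        )
        stems.append(stem)

    stem_map = StemMap(window=window, stems=stems, planted_species=planted_species)
    stem_map.rejected = rejected
    return stem_map


def write_stem_map(stem_map: StemMap, path) -> None:
    """Write the stem map in the same CSV dialect `read_stem_map` accepts."""
    df = stem_map.to_frame()
    df.to_csv(path, index=False, na_rep="")


def write_rejected_report(stem_map: StemMap, path) -> None:
    pd.DataFrame(stem_map.rejected, columns=["row", "reason"]).to_csv(
        path, index=False
    )


def classify_groups(stem_map: StemMap) -> dict[str, list[str]]:
    """Assign every stem to exactly one group.

    Live stems are split by species membership: a live stem of a planted
    species is ``live_planted``; any other live stem is a later-coming
    population (``live_lcp``), regardless of the status token it was read
    with.  Dead stems keep their deadwood status; stumps form their own
    group (they are harvest residue, not deadwood).
    """
    groups: dict[str, list[str]] = {s: [] for s in STATUSES}
    planted = stem_map.planted_species
    for stem in stem_map.stems:
        if stem.status in LIVE_STATUSES:
            if not stem.species.strip():
                raise ClassificationError(f"live stem {stem.id} has empty species")
            group = "live_planted" if stem.species in planted else "live_lcp"
        else:
            group = stem.status
        groups[group].append(stem.id)
    return groups


def deadwood_ids(groups: Mapping[str, Sequence[str]]) -> list[str]:
    """Deadwood = snags + fallen + broken wood; stumps are excluded."""
    out: list[str] = []
    for status in DEADWOOD_STATUSES:
        out.extend(groups.get(status, []))
    return out


def core_buffer_split(
    stem_map: StemMap, buffer_width: float
) -> tuple[list[str], list[str]]:
    """Partition stems into core and buffer sets.

    Core stems lie at least ``buffer_width`` metres from every plot edge;
    edge-near stems only ever act as neighbours/competitors, never as
    reference trees.
    """
    if buffer_width < 0:
        raise StandError("buffer_width must be non-negative")
    if buffer_width >= stem_map.window.short_side / 2:
        raise StandError(
            f"buffer_width {buffer_width} m leaves an empty core in a "
            f"{stem_map.window.width} x {stem_map.window.height} m window"
        )
    w = stem_map.window
    core, buffer = [], []
    for s in stem_map.stems:
        d_edge = min(s.x - w.x_min, w.x_max - s.x, s.y - w.y_min, w.y_max - s.y)
        (core if d_edge >= buffer_width else buffer).append(s.id)
    return core, buffer
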