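"""Nearest-neighbor stand-structure indices.

Each core stem (reference tree i) together with its four nearest neighbors
forms a *structure unit*.  Three classical indices are computed per unit:

- uniform angle index W: fraction of the four consecutive neighbor-azimuth
  gaps smaller than the standard angle (72 deg).  Near 0 for uniform
  (lattice) patterns, about 0.5 for random patterns, near 1 for clusters.
- mingling M: fraction of heterospecific neighbors.
- dominance U: fraction of neighbors with strictly larger DBH than the
  reference; high U marks a suppressed reference tree.

Stems within `buffer_width` of the plot perimeter act only as neighbors,
never as reference trees, which avoids edge bias in the neighbor search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import atan2, tau

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .stand_io import (
    DEADWOOD_STATUSES,
    LIVE_STATUSES,
    StandError,
    StemMap,
    classify_groups,
    core_buffer_split,
)

DEFAULT_ALPHA0_DEG = 72.0
DEFAULT_NEIGHBOR_POOL = LIVE_STATUSES + DEADWOOD_STATUSES  # everything but stumps


@dataclass
class StructureUnit:
    """Reference tree plus its k nearest neighbors, ordered by distance."""

    ref_id: str
    neighbor_ids: list[str]
    distances: np.ndarray
    azimuths: np.ndarray  # radians, measured from +x axis
    ref_species: str
    ref_dbh: float | None
    neighbor_species: list[str]
    neighbor_dbh: list[float | None]


@dataclass
class StructureSummary:
    per_tree: pd.DataFrame  # id, group, W, M, U
    means: pd.DataFrame  # group, n_units, mean_W, mean_M, mean_U


def build_units(
    stem_map: StemMap,
    buffer_width: float = 5.0,
    neighbor_pool: tuple[str, ...] = DEFAULT_NEIGHBOR_POOL,
    reference_ids=None,
    reference_pool: tuple[str, ...] | None = None,
    k: int = 4,
) -> list[StructureUnit]:
    """One structure unit per core reference stem.

    References default to core stems whose status is in `reference_pool`
    (itself defaulting to every non-stump status), or to `reference_ids`
    when given; a reference need not belong to the neighbor pool, so e.g.
    deadwood references can be scored against live-only neighbors.
    Neighbors are the k nearest pool stems by Euclidean distance, reference
    excluded; exact distance ties are broken by id order for determinism.
    """
    pool = sorted(
        (s for s in stem_map.stems if s.status in neighbor_pool), key=lambda s: s.id
    )
    if len(pool) < k + 1:
        raise StandError(f"need at least {k + 1} stems in the neighbor pool")
    pool_ids = [s.id for s in pool]
    coords = np.array([(s.x, s.y) for s in pool])
    tree = cKDTree(coords)

    core, _ = core_buffer_split(stem_map, buffer_width)
    core_set = set(core)
    if reference_ids is None:
        ref_statuses = reference_pool if reference_pool is not None else DEFAULT_NEIGHBOR_POOL
        refs = sorted(
            (
                s
                for s in stem_map.stems
                if s.id in core_set and s.status in ref_statuses
            ),
            key=lambda s: s.id,
        )
    else:
        refs = [stem_map.by_id(i) for i in reference_ids if i in core_set]

    by_id = {s.id: (idx, s) for idx, s in enumerate(pool)}
    units: list[StructureUnit] = []
    n_query = min(len(pool), k + 8)
    for ref in refs:
        ref_xy = np.array([ref.x, ref.y])
        dist, idx = tree.query(ref_xy, k=n_query)
        dist, idx = np.atleast_1d(dist), np.atleast_1d(idx)
        cand = [
            (d, pool_ids[j], j)
            for d, j in zip(dist, idx)
            if pool_ids[j] != ref.id
        ]
        # lexicographic (distance, id): deterministic under exact ties;
        # ids are pre-sorted so pool index order == id order
        cand.sort(key=lambda t: (t[0], t[1]))
        if len(cand) < k:
            raise StandError(f"fewer than {k} neighbors available for {ref.id}")
        chosen = cand[:k]
        # if the kth and (k+1)th candidate tie in distance, widen the search
        if len(cand) > k and cand[k][0] == chosen[-1][0] and n_query < len(pool):
            dist, idx = tree.query(ref_xy, k=len(pool))
            cand = [
                (d, pool_ids[j], j) for d, j in zip(dist, idx) if pool_ids[j] != ref.id
            ]
            cand.sort(key=lambda t: (t[0], t[1]))
            chosen = cand[:k]
        n_ids = [c[1] for c in chosen]
        n_stems = [by_id[i][1] for i in n_ids]
        units.append(
            StructureUnit(
                ref_id=ref.id,
                neighbor_ids=n_ids,
                distances=np.array([c[0] for c in chosen]),
                azimuths=np.array(
                    [atan2(s.y - ref.y, s.x - ref.x) for s in n_stems]
                ),
                ref_species=ref.species,
                ref_dbh=ref.dbh,
                neighbor_species=[s.species for s in n_stems],
                neighbor_dbh=[s.dbh for s in n_stems],
            )
        )
    return units


def uniform_angle(unit: StructureUnit, alpha0_deg: float = DEFAULT_ALPHA0_DEG) -> float:
    """W_i: fraction of consecutive azimuth gaps strictly below alpha0."""
    if np.any(unit.distances <= 0):
        raise StandError(f"unit {unit.ref_id}: neighbor coincides with reference")
    az = np.sort(np.mod(unit.azimuths, tau))
    gaps = np.diff(np.append(az, az[0] + tau))
    alpha0 = np.deg2rad(alpha0_deg)
    return float(np.count_nonzero(gaps < alpha0) / len(gaps))


def mingling(unit: StructureUnit) -> float:
    """M_i: fraction of neighbors of a different species than the reference."""
    return float(
        sum(sp != unit.ref_species for sp in unit.neighbor_species)
        / len(unit.neighbor_species)
    )


def dominance(unit: StructureUnit) -> float:
    """U_i: fraction of neighbors strictly larger in DBH (ties not larger)."""
    if unit.ref_dbh is None or any(d is None for d in unit.neighbor_dbh):
        raise StandError(f"unit {unit.ref_id}: DBH missing")
    return float(
        sum(d > unit.ref_dbh for d in unit.neighbor_dbh) / len(unit.neighbor_dbh)
    )


def csr_uniform_angle_mean(
    n_points: int = 2000,
    window=None,
    n_seeds: int = 20,
    buffer_width: float = 5.0,
    seed: int = 0,
    alpha0_deg: float = DEFAULT_ALPHA0_DEG,
) -> tuple[float, int]:
    """Grand mean W over core trees of seeded CSR stands.

    Calibration experiment for the random-pattern reference interval of the
    uniform angle index: simulates `n_seeds` binomial CSR patterns of
    `n_points` each, computes per-tree W for all core reference trees, and
    returns (grand mean, total number of reference trees).
    """
    from .point_pattern import simulate_csr
    from .stand_io import PlotWindow, StemRecord

    window = window or PlotWindow(0, 0, 100, 80)
    master = np.random.SeedSequence(seed)
    total, count = 0.0, 0
    for stream in master.spawn(n_seeds):
        pts = simulate_csr(n_points, window, np.random.default_rng(stream))
        stems = [
            StemRecord(
                id=f"c{i:05d}", x=float(x), y=float(y), species="sp",
                status="live_planted", dbh=10.0,
            )
            for i, (x, y) in enumerate(pts)
        ]
        stand = StemMap(window=window, stems=stems, planted_species=frozenset({"sp"}))
        for unit in build_units(stand, buffer_width):
            total += uniform_angle(unit, alpha0_deg)
            count += 1
    return total / count, count


def group_means(
    stem_map: StemMap,
    buffer_width: float = 5.0,
    neighbor_pool: tuple[str, ...] = DEFAULT_NEIGHBOR_POOL,
    groups: dict[str, list[str]] | None = None,
    alpha0_deg: float = DEFAULT_ALPHA0_DEG,
    k: int = 4,
) -> StructureSummary:
    """Arithmetic mean W/M/U per group over core reference trees.

    Groups default to the live/dead classification (stumps excluded);
    empty groups are omitted with a warning.
    """
    if groups is None:
        cls = classify_groups(stem_map)
        groups = {g: ids for g, ids in cls.items() if g != "stump"}

    units = build_units(stem_map, buffer_width, neighbor_pool, k=k)
    by_ref = {u.ref_id: u for u in units}

    rows = []
    for group, ids in groups.items():
        g_units = [by_ref[i] for i in ids if i in by_ref]
        if not g_units:
            warnings.warn(f"group {group!r}: no core structure units", stacklevel=2)
            continue
        for u in g_units:
            rows.append(
                {
                    "id": u.ref_id,
                    "group": group,
                    "W": uniform_angle(u, alpha0_deg),
                    "M": mingling(u),
                    "U": dominance(u),
                }
            )
    per_tree = pd.DataFrame(rows, columns=["id", "group", "W", "M", "U"])
    means = (
        per_tree.groupby("group", sort=True)
        .agg(n_units=("id", "size"), mean_W=("W", "mean"), mean_M=("M", "mean"),
             mean_U=("U", "mean"))
        .reset_index()
    )
    return StructureSummary(per_tree=per_tree, means=means)
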