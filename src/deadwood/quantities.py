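"""Deadwood quantity statistics.

Volumes, mean DBH, abundance/proportion tables per deadwood type, and
DBH-class distributions with nonlinear curve fits plus a Kolmogorov-Smirnov
goodness-of-fit check.

Standing stems (and lying wood without a measured central diameter) use the
form-factor volume

    V = (pi / 40000) * d_1.3^2 * (h + 3) * f,     f = 0.4 conifer, 0.2 broadleaf

with d_1.3 in cm and h in m.  Lying wood with a measured central diameter
d_1/2 uses the cylinder form

    V = (pi / 40000) * d_1/2^2 * l.

Regional two-way volume tables can stand in for the closed form through
`VolumeTable`, a (DBH, height) -> volume lookup loaded from CSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .stand_io import DEADWOOD_STATUSES, StandError, StemMap, StemRecord, classify_groups


def tree_volume(dbh, height, broadleaf: bool = False):
    """Single-tree volume (m^3) from DBH (cm) and height (m).

    Vectorised over `dbh`/`height`.  The reduction factor is 0.4 for
    conifers and 0.2 for broadleaved trees, so broadleaf volume is exactly
    half the conifer value at equal dimensions.
    """
    dbh = np.asarray(dbh, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(dbh <= 0) or np.any(height <= 0):
        raise StandError("tree_volume requires positive dbh and height")
    f = 0.2 if broadleaf else 0.4
    out = (np.pi / 40000.0) * dbh**2 * (height + 3.0) * f
    return float(out) if out.ndim == 0 else out


def broken_volume(mid_diameter, length):
    """Cylinder volume (m^3) of lying/broken wood from d_1/2 (cm), l (m)."""
    mid_diameter = np.asarray(mid_diameter, dtype=float)
    length = np.asarray(length, dtype=float)
    if np.any(mid_diameter <= 0) or np.any(length <= 0):
        raise StandError("broken_volume requires positive mid_diameter and length")
    out = (np.pi / 40000.0) * mid_diameter**2 * length
    return float(out) if out.ndim == 0 else out


def mean_dbh(values) -> float:
    """Arithmetic mean DBH (cm); raises on an empty group, never NaN."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise StandError("mean_dbh of an empty group")
    return float(arr.mean())


class VolumeTable:
    """A two-way (DBH x height) -> volume lookup table.

    Stands in for regional yield tables that tabulate single-tree volume by
    diameter and height class; looks up the nearest tabulated (d, h) cell.
    CSV columns: dbh, height, volume.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"dbh", "height", "volume"}
        if not required.issubset(table.columns):
            raise StandError(f"volume table needs columns {sorted(required)}")
        self._table = table.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "VolumeTable":
        return cls(pd.read_csv(path))

    def __call__(self, dbh: float, height: float, broadleaf: bool = False) -> float:
        d = (self._table["dbh"] - dbh) ** 2 + (self._table["height"] - height) ** 2
        return float(self._table.loc[d.idxmin(), "volume"])


def stem_volume(
    stem: StemRecord,
    broadleaf_species: frozenset[str] | set[str] = frozenset(),
    volume_fn=None,
) -> float:
    """Volume of one stem, choosing the applicable formula.

    Broken wood, and fallen wood with a measured central diameter, use the
    cylinder form on d_1/2 and piece length; everything else uses the
    form-factor equation (or `volume_fn` if supplied).  Returns NaN when the
    needed height/length measurement is missing.
    """
    use_cylinder = stem.status == "broken" or (
        stem.status == "fallen" and stem.mid_diameter is not None
    )
    if use_cylinder:
        if stem.height_or_length is None or stem.mid_diameter is None:
            return float("nan")
        return broken_volume(stem.mid_diameter, stem.height_or_length)
    if stem.dbh is None or stem.height_or_length is None:
        return float("nan")
    broadleaf = stem.species in broadleaf_species
    if volume_fn is not None:
        return float(volume_fn(stem.dbh, stem.height_or_length, broadleaf))
    return tree_volume(stem.dbh, stem.height_or_length, broadleaf=broadleaf)


@dataclass
class AbundanceSummary:
    """Per (group x species) counts/volumes/mean DBH plus group totals."""

    by_species: pd.DataFrame  # group, species, count, volume_m3, mean_dbh_cm
    by_group: pd.DataFrame  # group, count, volume_m3, focal_pct
    focal_species: str


def summarize(
    stem_map: StemMap,
    focal_species: str,
    *,
    broadleaf_species: frozenset[str] | set[str] = frozenset(),
    volume_fn=None,
) -> AbundanceSummary:
    """Abundance, volume and mean-DBH summary per deadwood type.

    Groups are the three deadwood types plus their union (``deadwood``);
    the focal percentage is 100 x focal-species count / group count.
    """
    known = {s.species for s in stem_map.stems} | set(stem_map.planted_species)
    if focal_species not in known:
        raise StandError(f"unknown focal species {focal_species!r}")

    groups = classify_groups(stem_map)
    group_ids = {status: list(groups[status]) for status in DEADWOOD_STATUSES}
    group_ids["deadwood"] = [i for ids in group_ids.values() for i in ids]

    sp_rows, grp_rows = [], []
    for group, ids in group_ids.items():
        stems = [stem_map.by_id(i) for i in ids]
        frame = pd.DataFrame(
            {
                "species": [s.species for s in stems],
                "dbh": [np.nan if s.dbh is None else s.dbh for s in stems],
                "volume": [
                    stem_volume(s, broadleaf_species, volume_fn) for s in stems
                ],
            }
        )
        if len(frame):
            for species, sub in frame.groupby("species", sort=True):
                sp_rows.append(
                    {
                        "group": group,
                        "species": species,
                        "count": len(sub),
                        "volume_m3": float(np.nansum(sub["volume"])),
                        "mean_dbh_cm": float(sub["dbh"].mean()),
                    }
                )
        n = len(stems)
        n_focal = sum(s.species == focal_species for s in stems)
        grp_rows.append(
            {
                "group": group,
                "count": n,
                "volume_m3": float(np.nansum(frame["volume"])) if n else 0.0,
                "focal_pct": 100.0 * n_focal / n if n else float("nan"),
            }
        )

    return AbundanceSummary(
        by_species=pd.DataFrame(
            sp_rows, columns=["group", "species", "count", "volume_m3", "mean_dbh_cm"]
        ),
        by_group=pd.DataFrame(grp_rows),
        focal_species=focal_species,
    )


@dataclass
class DBHDistribution:
    """Histogram of DBH over half-open classes [lo, lo+w)."""

    class_width: float
    edges: np.ndarray  # len = n_classes + 1
    midpoints: np.ndarray
    counts: np.ndarray
    values: np.ndarray = field(repr=False)  # raw DBHs, kept for KS tests


def dbh_histogram(values, class_width: float = 2.0, origin: float = 1.0) -> DBHDistribution:
    """Bin DBH values into half-open classes anchored at `origin`.

    A value exactly on a class boundary belongs to the upper class.  Classes
    extend below the origin if needed so every value is counted.
    """
    if class_width <= 0:
        raise StandError("class_width must be positive")
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise StandError("dbh_histogram of an empty sample")
    k = np.floor((arr - origin) / class_width).astype(int)
    k_min, k_max = int(k.min()), int(k.max())
    counts = np.bincount(k - k_min, minlength=k_max - k_min + 1)
    edges = origin + class_width * np.arange(k_min, k_max + 2)
    return DBHDistribution(
        class_width=float(class_width),
        edges=edges,
        midpoints=(edges[:-1] + edges[1:]) / 2.0,
        counts=counts,
        values=arr,
    )


@dataclass
class CurveFit:
    """Nonlinear least-squares fit of a curve family to class counts."""

    family: str  # "normal" | "negative_exponential"
    params: dict[str, float]
    converged: bool
    ks_p: float | None
    message: str = ""

    @property
    def fits(self) -> bool:
        """True when the sample is consistent with the fitted shape (p > 0.05)."""
        return bool(self.converged and self.ks_p is not None and self.ks_p > 0.05)


def _failed_fit(family: str, message: str) -> CurveFit:
    return CurveFit(family=family, params={}, converged=False, ks_p=None, message=message)


def fit_dbh_curve(dist: DBHDistribution, family: str) -> CurveFit:
    """Fit a Gaussian bump or a decaying exponential to the DBH histogram.

    Families: ``normal`` a*exp(-(x-mu)^2 / 2 sigma^2); ``negative_exponential``
    a*exp(-b*x).  The fit is least squares of class counts against class
    midpoints.  Goodness of fit is a KS test of the raw values against the
    fitted shape normalised to a density (the classical p-value, computed
    with the fitted parameters treated as known; see docs for the caveat).
    Degenerate inputs or non-convergence yield ``converged=False``, never an
    exception.
    """
    if family not in ("normal", "negative_exponential"):
        raise StandError(f"unknown curve family {family!r}")
    x = dist.midpoints
    y = dist.counts.astype(float)
    nonempty = int((y > 0).sum())
    if nonempty < 3:
        return _failed_fit(family, f"only {nonempty} non-empty classes")

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if family == "normal":
                mu0 = float(np.average(x, weights=y))
                sd0 = float(np.sqrt(np.average((x - mu0) ** 2, weights=y))) or 1.0
                popt, _ = optimize.curve_fit(
                    lambda t, a, mu, sd: a * np.exp(-((t - mu) ** 2) / (2 * sd**2)),
                    x,
                    y,
                    p0=[y.max(), mu0, sd0],
                    maxfev=5000,
                )
                a, mu, sd = popt
                sd = abs(float(sd))
                if not np.isfinite([a, mu, sd]).all() or sd <= 0:
                    return _failed_fit(family, "degenerate normal fit")
                ks = stats.kstest(dist.values, "norm", args=(float(mu), sd))
                params = {"a": float(a), "mu": float(mu), "sigma": sd}
            else:
                pos = y > 0
                slope, intercept = np.polyfit(x[pos], np.log(y[pos]), 1)
                b0 = max(-slope, 1e-3)
                popt, _ = optimize.curve_fit(
                    lambda t, a, b: a * np.exp(-b * t),
                    x,
                    y,
                    p0=[float(np.exp(intercept)), b0],
                    maxfev=5000,
                )
                a, b = float(popt[0]), float(popt[1])
                if not np.isfinite([a, b]).all() or b <= 0:
                    return _failed_fit(family, "non-decaying exponential fit")
                ks = stats.kstest(dist.values, "expon", args=(0.0, 1.0 / b))
                params = {"a": a, "b": b}
    except (RuntimeError, TypeError, np.linalg.LinAlgError) as exc:
        return _failed_fit(family, f"no convergence: {exc}")

    return CurveFit(
        family=family, params=params, converged=True, ks_p=float(ks.pvalue)
    )
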