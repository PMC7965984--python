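"""Voronoi competitor selection, Hegyi competition index, and logistic
mortality models with AUC rating.

Competitors of tree i are the stems whose Voronoi cells, clipped to the
plot rectangle, share a positive-length edge with i's cell (the "natural
neighbours" of the tessellation).  Competitive pressure is Hegyi's index

    HCI_i = sum_j (d_j / d_i) * (1 / dist_ij)

over those competitors, with d in cm and dist in m: size-ratio weighted
inverse distance, dimensionless in size and 1/m in distance.

Mortality is modelled as a binary response (live = 0, dead = 1) with a
logistic regression p = 1 / (1 + exp(-(beta0 + beta1 * x))) on DBH or on
HCI; discrimination is summarised by the rank-based (Mann-Whitney) AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import Voronoi, QhullError
from sklearn.metrics import roc_auc_score

from .stand_io import (
    DEADWOOD_STATUSES,
    LIVE_STATUSES,
    StandError,
    StemMap,
    classify_groups,
)

#: tessellation pool reconstructing the pre-death stand: live stems plus
#: deadwood at recorded DBH; stumps are excluded
DEFAULT_POOL = LIVE_STATUSES + DEADWOOD_STATUSES


@dataclass
class CompetitorGraph:
    """Symmetric competitor adjacency from the clipped Voronoi tessellation."""

    neighbors: dict[str, list[str]]
    edge_affected: set[str] = field(default_factory=set)

    def __getitem__(self, stem_id: str) -> list[str]:
        return self.neighbors[stem_id]

    def degree(self, stem_id: str) -> int:
        return len(self.neighbors[stem_id])


def _clip_segment_length(p, q, window) -> float:
    """Length of segment pq inside the window rectangle (Liang-Barsky)."""
    d = q - p
    t0, t1 = 0.0, 1.0
    for delta, lo, hi in (
        (d[0], window.x_min - p[0], window.x_max - p[0]),
        (d[1], window.y_min - p[1], window.y_max - p[1]),
    ):
        if delta == 0.0:
            if lo > 0.0 or hi < 0.0:
                return 0.0
            continue
        ta, tb = lo / delta, hi / delta
        if ta > tb:
            ta, tb = tb, ta
        t0, t1 = max(t0, ta), min(t1, tb)
        if t0 >= t1:
            return 0.0
    return float(np.hypot(*(d * (t1 - t0))))


def voronoi_competitors(
    stem_map: StemMap,
    pool: tuple[str, ...] = DEFAULT_POOL,
    edge_tol: float = 1e-9,
    jitter_seed: int = 0,
) -> CompetitorGraph:
    """Competitor graph from the Voronoi tessellation clipped to the window.

    Each Voronoi ridge (including the unbounded ones, extended well past
    the plot) is clipped to the plot rectangle; the two generating stems
    are competitors iff the clipped shared edge has positive length.  Stems
    whose cells are unbounded or reach outside the window are flagged
    ``edge_affected``.  Degenerate (e.g. collinear) configurations are
    retried once with a small deterministic jitter.
    """
    stems = [s for s in stem_map.stems if s.status in pool]
    if len(stems) < 4:
        raise StandError("voronoi_competitors needs at least 4 pool stems")
    ids = [s.id for s in stems]
    pts = np.array([(s.x, s.y) for s in stems], dtype=float)

    try:
        vor = Voronoi(pts)
    except QhullError:
        warnings.warn(
            "degenerate stem configuration; retrying with 1e-6 m jitter",
            stacklevel=2,
        )
        rng = np.random.default_rng(jitter_seed)
        vor = Voronoi(pts + rng.normal(0.0, 1e-6, pts.shape))

    w = stem_map.window
    center = pts.mean(axis=0)
    span = 4.0 * max(w.width, w.height) + np.abs(vor.vertices).max(initial=0.0)

    neighbors: dict[str, set[str]] = {i: set() for i in ids}
    edge_affected: set[str] = set()

    for (p1, p2), (v1, v2) in zip(vor.ridge_points, vor.ridge_vertices):
        if v1 == -1 and v2 == -1:  # cannot occur for >= 3 non-collinear points
            continue
        if v1 == -1 or v2 == -1:
            vfin = vor.vertices[v2 if v1 == -1 else v1]
            t = pts[p2] - pts[p1]
            t = t / np.linalg.norm(t)
            normal = np.array([-t[1], t[0]])
            midpoint = (pts[p1] + pts[p2]) / 2.0
            if np.dot(midpoint - center, normal) < 0:
                normal = -normal
            a, b = vfin, vfin + normal * span
        else:
            a, b = vor.vertices[v1], vor.vertices[v2]
        if _clip_segment_length(np.asarray(a), np.asarray(b), w) > edge_tol:
            neighbors[ids[p1]].add(ids[p2])
            neighbors[ids[p2]].add(ids[p1])

    for point_idx, region_idx in enumerate(vor.point_region):
        region = vor.regions[region_idx]
        if -1 in region or any(
            not w.contains(*vor.vertices[v]) for v in region
        ):
            edge_affected.add(ids[point_idx])

    return CompetitorGraph(
        neighbors={i: sorted(neighbors[i]) for i in ids},
        edge_affected=edge_affected,
    )


def hegyi(stem_map: StemMap, stem_id: str, competitor_ids) -> float:
    """Hegyi competition index of one stem over the given competitors."""
    ref = stem_map.by_id(stem_id)
    if ref.dbh is None or ref.dbh <= 0:
        raise StandError(f"stem {stem_id}: positive DBH required for HCI")
    total = 0.0
    for cid in competitor_ids:
        comp = stem_map.by_id(cid)
        if comp.dbh is None or comp.dbh <= 0:
            raise StandError(f"competitor {cid}: positive DBH required for HCI")
        dist = float(np.hypot(comp.x - ref.x, comp.y - ref.y))
        if dist == 0.0:
            raise StandError(f"stems {stem_id} and {cid} are coincident")
        total += (comp.dbh / ref.dbh) / dist
    return total


def hegyi_all(stem_map: StemMap, graph: CompetitorGraph) -> pd.Series:
    """HCI for every stem in the competitor graph, indexed by id."""
    return pd.Series(
        {i: hegyi(stem_map, i, graph[i]) for i in graph.neighbors},
        name="hci",
    )


def group_mean_hci(
    stem_map: StemMap,
    groups: dict[str, list[str]] | None = None,
    pool: tuple[str, ...] = DEFAULT_POOL,
) -> pd.DataFrame:
    """Arithmetic mean HCI per group (deadwood evaluated pre-death).

    The tessellation reconstructs the pre-death stand: live stems and
    deadwood at their recorded DBH, stumps excluded.  Empty groups are
    omitted.  Columns: group, n, mean_hci.
    """
    graph = voronoi_competitors(stem_map, pool=pool)
    hci = hegyi_all(stem_map, graph)
    if groups is None:
        cls = classify_groups(stem_map)
        groups = {g: ids for g, ids in cls.items() if g != "stump"}
    rows = []
    for group, ids in groups.items():
        vals = hci.reindex([i for i in ids if i in hci.index]).dropna()
        if vals.empty:
            continue
        rows.append({"group": group, "n": len(vals), "mean_hci": float(vals.mean())})
    return pd.DataFrame(rows, columns=["group", "n", "mean_hci"])


def hci_ratio_string(means: pd.DataFrame, group_a: str, group_b: str, ndigits: int = 3) -> str:
    """Format two group means as the conventional 'a:b' pressure ratio."""
    lookup = means.set_index("group")["mean_hci"]
    return f"{round(lookup[group_a], ndigits):g}:{round(lookup[group_b], ndigits):g}"


AUC_RATINGS = (  # (lower bound, rating); boundary values take the upper band
    (0.8, "excellent"),
    (0.6, "good"),
    (0.4, "poor"),
    (0.0, "fail"),
)


def rate_auc(value: float) -> str:
    for lo, rating in AUC_RATINGS:
        if value >= lo:
            return rating
    return "fail"


def auc(status, score) -> tuple[float, str]:
    """Rank-based (Mann-Whitney) AUC with midranks for ties, plus rating."""
    status = np.asarray(status, dtype=int)
    score = np.asarray(score, dtype=float)
    if status.min() == status.max():
        raise StandError("AUC needs both live and dead stems")
    value = float(roc_auc_score(status, score))
    return value, rate_auc(value)


@dataclass
class MortalityFit:
    """Logistic mortality model eta = beta0 + beta1 * x, p = expit(eta)."""

    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    fitted: np.ndarray
    auc: float
    rating: str
    converged: bool
    n: int
    predictor: str = "dbh"
    message: str = ""

    def ci_beta1(self, z: float = 1.959963984540054) -> tuple[float, float]:
        return self.beta1 - z * self.se_beta1, self.beta1 + z * self.se_beta1


def fit_mortality(x, status, predictor: str = "dbh") -> MortalityFit:
    """Maximum-likelihood logistic fit of death (1) vs. survival (0) on x.

    Newton-Raphson, tolerance 1e-8, at most 100 iterations.  Complete
    separation or non-convergence is reported through ``converged=False``
    with infinite-variance diagnostics rather than raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(status, dtype=float)
    if x.shape != y.shape:
        raise StandError("x and status must have equal length")
    if len(y) < 10:
        raise StandError("fit_mortality needs n >= 10")
    if y.min() == y.max():
        raise StandError("fit_mortality needs both live and dead stems")

    X = sm.add_constant(x)
    converged = True
    message = ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(
                method="newton", tol=1e-8, maxiter=100, disp=False
            )
        converged = bool(res.mle_retvals.get("converged", False))
        beta0, beta1 = float(res.params[0]), float(res.params[1])
        se0, se1 = (float(v) for v in res.bse)
        fitted = np.asarray(res.predict(X))
        if not np.isfinite([se0, se1]).all():
            converged = False
            message = "non-finite standard errors (possible separation)"
    except Exception as exc:  # PerfectSeparationError, LinAlgError, ...
        converged = False
        message = f"{type(exc).__name__}: {exc}"
        beta0 = beta1 = se0 = se1 = float("nan")
        fitted = np.full_like(y, np.nan)

    if converged and (fitted.min() < 1e-10 or fitted.max() > 1 - 1e-10):
        converged = False
        message = message or "fitted probabilities at machine bounds (separation)"

    auc_value, rating = auc(y.astype(int), fitted if np.isfinite(fitted).all() else x)
    return MortalityFit(
        beta0=beta0,
        beta1=beta1,
        se_beta0=se0,
        se_beta1=se1,
        fitted=fitted,
        auc=auc_value,
        rating=rating,
        converged=converged,
        n=len(y),
        predictor=predictor,
        message=message,
    )
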