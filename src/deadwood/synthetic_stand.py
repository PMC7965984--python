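"""Seeded generator of synthetic plantation stem maps.

The generator reproduces the statistical structure the downstream analyses
assume, stage by stage:

1. planting on a square lattice (default 2,000 stems/ha) with Gaussian
   positional jitter, species mixed i.i.d. (default 6:1), and establishment
   survival (default 87%);
2. DBH assignment from per-group size models (lognormal by default,
   truncated normal available) and a linear height allometry with noise;
3. competition-driven mortality: each live planted stem dies with logistic
   probability on its Hegyi competition index (a DBH-based mode is also
   available); dead stems become snags / fallen / broken wood;
4. optional thinning: a fixed fraction (default 26%) of live stems with
   DBH >= 9 cm becomes stumps, selected uniformly at random;
5. clustered recruitment of later-coming populations (LCPs) as a Thomas
   process (Poisson parents, Poisson offspring counts, Gaussian offspring
   displacement), plus light density-independent LCP mortality.

Every stage consumes its own RNG substream split from the master seed, so
adding or reconfiguring a stage never perturbs the draws of earlier stages.
`generate_stand` additionally returns a ground-truth ledger (latent HCIs,
death probabilities, stage bookkeeping) sufficient to score parameter
recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit
from scipy.stats import truncnorm

from . import competition
from .stand_io import PlotWindow, StandError, StemMap, StemRecord

_STAGES = ("planted", "dbh", "mortality", "thinning", "lcp", "lcp_dbh", "lcp_mortality")


@dataclass
class DBHModel:
    """Per-group stem diameter model: lognormal or truncated normal (cm)."""

    family: str = "lognormal"
    meanlog: float = 2.5
    sdlog: float = 0.35
    mean: float = 12.0
    sd: float = 4.0
    lower: float = 1.1

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "lognormal":
            return rng.lognormal(self.meanlog, self.sdlog, n)
        if self.family == "truncnorm":
            a = (self.lower - self.mean) / self.sd
            return truncnorm.rvs(
                a, np.inf, loc=self.mean, scale=self.sd, size=n, random_state=rng
            )
        raise StandError(f"unknown DBH family {self.family!r}")


@dataclass
class ThinningConfig:
    dbh_threshold: float = 9.0
    removal_fraction: float = 0.26


@dataclass
class LCPConfig:
    """Thomas-process recruitment of naturally colonising trees."""

    parent_intensity: float = 0.005  # parents / m^2
    mean_offspring: float = 25.0
    cluster_sd: float = 3.0  # m
    species_pool: dict[str, float] = field(
        default_factory=lambda: {
            "schima": 0.30,
            "castanopsis": 0.25,
            "machilus": 0.15,
            "evodia": 0.12,
            "wendlandia": 0.10,
            "litsea": 0.08,
        }
    )
    mortality_fraction: float = 0.02


@dataclass
class MortalityConfig:
    """Logistic death probability on the Hegyi index (or DBH)."""

    beta0: float = -2.5
    beta1: float = 0.8
    mode: str = "hci"  # "hci" | "dbh"


@dataclass
class StandConfig:
    window: PlotWindow = field(default_factory=lambda: PlotWindow(0, 0, 100, 80))
    planting_density: float = 2000.0  # stems / ha
    mix_ratio: dict[str, float] = field(
        default_factory=lambda: {"chinese_fir": 6.0, "michelia": 1.0}
    )
    establishment_survival: float = 0.87
    jitter_sd: float = 0.3  # m of planting-position noise
    thinning: ThinningConfig | None = None
    lcp: LCPConfig | None = field(default_factory=LCPConfig)
    mortality: MortalityConfig | None = field(default_factory=MortalityConfig)
    deadwood_type_probs: dict[str, float] = field(
        default_factory=lambda: {"snag": 0.5, "fallen": 0.4, "broken": 0.1}
    )
    dbh_models: dict[str, DBHModel] = field(
        default_factory=lambda: {
            "planted": DBHModel(meanlog=2.5, sdlog=0.35),
            "lcp": DBHModel(meanlog=1.6, sdlog=0.5),
        }
    )
    #: height = intercept + slope * dbh + N(0, sd), floored at 1.5 m
    allometry: tuple[float, float, float] = (2.0, 0.6, 0.8)
    seed: int = 0

    def validate(self) -> None:
        for name, frac in (
            ("establishment_survival", self.establishment_survival),
        ):
            if not 0.0 <= frac <= 1.0:
                raise StandError(f"{name} must lie in [0, 1]")
        if self.planting_density <= 0:
            raise StandError("planting_density must be positive")
        if self.thinning and not 0.0 <= self.thinning.removal_fraction <= 1.0:
            raise StandError("removal_fraction must lie in [0, 1]")
        total = sum(self.deadwood_type_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise StandError(f"deadwood_type_probs sum to {total}, not 1")
        if any(p < 0 for p in self.deadwood_type_probs.values()):
            raise StandError("deadwood_type_probs must be non-negative")
        if any(v < 0 for v in self.mix_ratio.values()) or not self.mix_ratio:
            raise StandError("mix_ratio must be non-empty and non-negative")


def mixed_stand_config(seed: int = 0) -> StandConfig:
    """An unthinned mixed plantation: 120 x 60 m, intense competition.

    Mortality coefficients are calibrated so the default geometry loses
    roughly 45% of planted stems; the deadwood type split matches a stand
    with snags and fallen wood but no logging-damage breakage.
    """
    return StandConfig(
        window=PlotWindow(0, 0, 120, 60),
        thinning=None,
        mortality=MortalityConfig(beta0=-2.3, beta1=0.8),
        deadwood_type_probs={"snag": 0.545, "fallen": 0.455, "broken": 0.0},
        lcp=LCPConfig(parent_intensity=0.0065, mean_offspring=25.0, cluster_sd=3.0),
        seed=seed,
    )


def thinned_stand_config(seed: int = 0) -> StandConfig:
    """A thinned monoculture: 100 x 80 m, 26% removal at DBH >= 9 cm.

    Lower mortality pressure (thinning has released the survivors), richer
    LCP recruitment, and breakage from felling damage.
    """
    return StandConfig(
        window=PlotWindow(0, 0, 100, 80),
        mix_ratio={"chinese_fir": 1.0},
        thinning=ThinningConfig(dbh_threshold=9.0, removal_fraction=0.26),
        mortality=MortalityConfig(beta0=-3.3, beta1=0.5),
        deadwood_type_probs={"snag": 0.51, "fallen": 0.30, "broken": 0.19},
        lcp=LCPConfig(
            parent_intensity=0.011,
            mean_offspring=30.0,
            cluster_sd=3.0,
            mortality_fraction=0.025,
        ),
        seed=seed,
    )


def _copy_map(stem_map: StemMap) -> StemMap:
    return StemMap(
        window=stem_map.window,
        stems=[StemRecord(**vars(s)) for s in stem_map.stems],
        planted_species=stem_map.planted_species,
    )


def _draw_species(rng, mix_ratio: dict[str, float], n: int) -> list[str]:
    names = sorted(mix_ratio)
    probs = np.array([mix_ratio[k] for k in names], dtype=float)
    probs /= probs.sum()
    return [names[i] for i in rng.choice(len(names), size=n, p=probs)]


def generate_planted(config: StandConfig, rng: np.random.Generator) -> StemMap:
    """Jittered square lattice of live planted stems after establishment."""
    config.validate()
    w = config.window
    spacing = float(np.sqrt(10000.0 / config.planting_density))
    if 2.0 * config.jitter_sd > spacing:
        warnings.warn(
            f"jitter_sd {config.jitter_sd} m large for {spacing:.2f} m spacing",
            stacklevel=2,
        )
    xs = np.arange(w.x_min + spacing / 2.0, w.x_max, spacing)
    ys = np.arange(w.y_min + spacing / 2.0, w.y_max, spacing)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pos = np.column_stack([gx.ravel(), gy.ravel()])
    pos = pos + rng.normal(0.0, config.jitter_sd, pos.shape)
    eps = 1e-6
    pos[:, 0] = np.clip(pos[:, 0], w.x_min + eps, w.x_max - eps)
    pos[:, 1] = np.clip(pos[:, 1], w.y_min + eps, w.y_max - eps)

    species = _draw_species(rng, config.mix_ratio, len(pos))
    keep = rng.random(len(pos)) < config.establishment_survival

    stems = [
        StemRecord(
            id=f"P{k:05d}",
            x=float(pos[k, 0]),
            y=float(pos[k, 1]),
            species=species[k],
            status="live_planted",
        )
        for k in np.flatnonzero(keep)
    ]
    return StemMap(
        window=w, stems=stems, planted_species=frozenset(config.mix_ratio)
    )


def assign_dbh(
    stem_map: StemMap,
    config: StandConfig,
    rng: np.random.Generator,
    group: str = "planted",
    statuses: tuple[str, ...] = ("live_planted",),
) -> StemMap:
    """Draw DBH from the group's size model and heights from the allometry."""
    out = _copy_map(stem_map)
    model = config.dbh_models[group]
    targets = [s for s in out.stems if s.status in statuses and s.dbh is None]
    dbh = model.sample(len(targets), rng)
    b0, b1, sd = config.allometry
    heights = np.maximum(1.5, b0 + b1 * dbh + rng.normal(0.0, sd, len(targets)))
    for stem, d, h in zip(targets, dbh, heights):
        stem.dbh = float(max(d, 1.05))
        stem.height_or_length = float(h)
    return out


def _kill(stem: StemRecord, dead_type: str) -> None:
    stem.status = dead_type
    if dead_type == "broken":
        stem.mid_diameter = round(0.7 * stem.dbh, 3)
        stem.height_or_length = (
            round(0.6 * stem.height_or_length, 3) if stem.height_or_length else None
        )
    elif dead_type == "fallen":
        stem.mid_diameter = round(0.75 * stem.dbh, 3)


def apply_competition_mortality(
    stem_map: StemMap, config: StandConfig, rng: np.random.Generator
) -> tuple[StemMap, dict]:
    """Relabel live planted stems that die under competitive pressure.

    Death probability is expit(beta0 + beta1 * HCI_i) with HCI from the
    Voronoi competitor graph over all currently live stems (mode "dbh"
    substitutes DBH for HCI).  Returns the new map plus ground truth
    (per-stem predictor, death probability, realised deaths).
    """
    mort = config.mortality
    out = _copy_map(stem_map)
    targets = sorted(
        (s for s in out.stems if s.status == "live_planted"), key=lambda s: s.id
    )
    if not targets or mort is None:
        return out, {"predictor": {}, "death_prob": {}, "dead_ids": []}

    if mort.mode == "hci":
        graph = competition.voronoi_competitors(
            out, pool=("live_planted", "live_lcp")
        )
        hci = competition.hegyi_all(out, graph)
        x = np.array([hci[s.id] for s in targets])
    elif mort.mode == "dbh":
        x = np.array([s.dbh for s in targets], dtype=float)
    else:
        raise StandError(f"unknown mortality mode {mort.mode!r}")

    p = expit(mort.beta0 + mort.beta1 * x)
    u = rng.random(len(targets))
    died = u < p

    types = sorted(config.deadwood_type_probs)
    probs = np.array([config.deadwood_type_probs[t] for t in types])
    type_draws = rng.choice(len(types), size=len(targets), p=probs)

    dead_ids = []
    for stem, dead, t_idx in zip(targets, died, type_draws):
        if dead:
            _kill(stem, types[t_idx])
            dead_ids.append(stem.id)

    truth = {
        "predictor": {s.id: float(v) for s, v in zip(targets, x)},
        "death_prob": {s.id: float(v) for s, v in zip(targets, p)},
        "dead_ids": dead_ids,
        "mode": mort.mode,
        "beta0": mort.beta0,
        "beta1": mort.beta1,
    }
    return out, truth


def apply_thinning(
    stem_map: StemMap, config: StandConfig, rng: np.random.Generator
) -> tuple[StemMap, dict]:
    """Turn round(removal_fraction * n_eligible) eligible live stems into stumps.

    Eligible: live stems with DBH >= the threshold; selection is uniform
    without replacement.  No eligible stems is a warned no-op.
    """
    thin = config.thinning
    out = _copy_map(stem_map)
    if thin is None:
        return out, {"thinned_ids": []}
    eligible = sorted(
        (
            s
            for s in out.stems
            if s.status in ("live_planted", "live_lcp")
            and s.dbh is not None
            and s.dbh >= thin.dbh_threshold
        ),
        key=lambda s: s.id,
    )
    n_remove = int(round(thin.removal_fraction * len(eligible)))
    if not eligible:
        warnings.warn("thinning requested but no eligible stems", stacklevel=2)
        return out, {"thinned_ids": []}
    chosen = rng.choice(len(eligible), size=n_remove, replace=False)
    thinned_ids = []
    for idx in sorted(chosen):
        stem = eligible[idx]
        stem.status = "stump"
        thinned_ids.append(stem.id)
    return out, {"thinned_ids": thinned_ids}


def recruit_lcp(
    stem_map: StemMap, config: StandConfig, rng: np.random.Generator
) -> tuple[StemMap, dict]:
    """Add clustered later-coming stems via a Thomas process.

    Poisson(parent_intensity * area) parents uniform in the window; each
    parent spawns Poisson(mean_offspring) offspring displaced by isotropic
    Gaussian noise (sd = cluster_sd); offspring outside the window are
    discarded.
    """
    lcp = config.lcp
    out = _copy_map(stem_map)
    if lcp is None:
        return out, {"parents": [], "n_recruits": 0}
    w = out.window
    n_parents = rng.poisson(lcp.parent_intensity * w.area)
    parents = simulate_parents = rng.random((n_parents, 2))
    parents = np.column_stack(
        [
            w.x_min + simulate_parents[:, 0] * w.width,
            w.y_min + simulate_parents[:, 1] * w.height,
        ]
    )
    names = sorted(lcp.species_pool)
    probs = np.array([lcp.species_pool[k] for k in names], dtype=float)
    probs /= probs.sum()

    stems = []
    k = 0
    for px, py in parents:
        m = rng.poisson(lcp.mean_offspring)
        offs = np.column_stack([px, py]) + rng.normal(0.0, lcp.cluster_sd, (m, 2))
        inside = (
            (offs[:, 0] > w.x_min)
            & (offs[:, 0] < w.x_max)
            & (offs[:, 1] > w.y_min)
            & (offs[:, 1] < w.y_max)
        )
        for ox, oy in offs[inside]:
            sp = names[int(rng.choice(len(names), p=probs))]
            stems.append(
                StemRecord(
                    id=f"L{k:05d}", x=float(ox), y=float(oy), species=sp,
                    status="live_lcp",
                )
            )
            k += 1
    out.stems.extend(stems)
    out = StemMap(
        window=out.window, stems=out.stems, planted_species=out.planted_species
    )
    return out, {"parents": parents.tolist(), "n_recruits": len(stems)}


def apply_lcp_mortality(
    stem_map: StemMap, config: StandConfig, rng: np.random.Generator
) -> tuple[StemMap, dict]:
    """Density-independent LCP mortality: each live LCP dies i.i.d.

    Because recruitment is clustered, the resulting LCP deadwood inherits
    the clustered spatial signature.
    """
    out = _copy_map(stem_map)
    lcp = config.lcp
    if lcp is None or lcp.mortality_fraction <= 0:
        return out, {"dead_ids": []}
    targets = sorted(
        (s for s in out.stems if s.status == "live_lcp"), key=lambda s: s.id
    )
    died = rng.random(len(targets)) < lcp.mortality_fraction
    types = sorted(config.deadwood_type_probs)
    probs = np.array([config.deadwood_type_probs[t] for t in types])
    type_draws = rng.choice(len(types), size=len(targets), p=probs)
    dead_ids = []
    for stem, dead, t_idx in zip(targets, died, type_draws):
        if dead:
            _kill(stem, types[t_idx])
            dead_ids.append(stem.id)
    return out, {"dead_ids": dead_ids}


def generate_stand(config: StandConfig) -> tuple[StemMap, dict]:
    """Full pipeline: plant, size, kill, thin, recruit, size and thin LCPs.

    Deterministic given ``config.seed``; returns the stem map and a
    ground-truth ledger of every latent quantity needed to score recovery
    of the generating parameters.
    """
    config.validate()
    streams = dict(
        zip(_STAGES, np.random.SeedSequence(config.seed).spawn(len(_STAGES)))
    )
    rngs = {k: np.random.default_rng(v) for k, v in streams.items()}

    stand = generate_planted(config, rngs["planted"])
    n_planted = len(stand)
    stand = assign_dbh(stand, config, rngs["dbh"], group="planted")
    stand, mortality_truth = apply_competition_mortality(
        stand, config, rngs["mortality"]
    )
    stand, thinning_truth = apply_thinning(stand, config, rngs["thinning"])
    stand, lcp_truth = recruit_lcp(stand, config, rngs["lcp"])
    stand = assign_dbh(
        stand, config, rngs["lcp_dbh"], group="lcp", statuses=("live_lcp",)
    )
    stand, lcp_mort_truth = apply_lcp_mortality(stand, config, rngs["lcp_mortality"])

    ledger = {
        "seed": config.seed,
        "n_planted_established": n_planted,
        "mortality": mortality_truth,
        "thinning": thinning_truth,
        "lcp": lcp_truth,
        "lcp_mortality": lcp_mort_truth,
        "counts": stand.counts_by_status(),
        "config": _config_dict(config),
    }
    return stand, ledger


def _config_dict(config: StandConfig) -> dict:
    d = asdict(config)
    d["window"] = vars(config.window)
    d["planted_species"] = sorted(config.mix_ratio)
    return d
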