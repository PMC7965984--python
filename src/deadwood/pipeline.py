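"""End-to-end analysis pipeline and the printed-count verification table.

`run` sequences the full stand analysis from a config (stem-map file or
synthetic generator settings) and writes a report bundle: abundance
summary, DBH distributions with curve fits, PCF envelopes per deadwood
group, structure-index means, HCI table, and mortality fits, plus a
machine-readable JSON index.  Stages are independent: a failure in one is
recorded and the rest still run.

`verify_census_counts` recomputes a set of stand-level proportions from
embedded census counts (stem totals per group from two reference plots, a
mixed and a thinned Chinese fir plantation) and checks them against the
expected percentages at two-decimal precision — arithmetic identities that
double as a smoke test of the proportion bookkeeping.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import competition, neighborhood, point_pattern, quantities
from .stand_io import (
    DEADWOOD_STATUSES,
    PlotWindow,
    StemMap,
    classify_groups,
    read_stem_map,
    write_stem_map,
)
from .synthetic_stand import (
    DBHModel,
    LCPConfig,
    MortalityConfig,
    StandConfig,
    ThinningConfig,
    generate_stand,
)


@dataclass
class AnalysisConfig:
    """Everything `run` needs; exactly one of stem_map_path / synthetic."""

    stem_map_path: str | None = None
    window: PlotWindow | None = None
    planted_species: tuple[str, ...] = ("chinese_fir", "michelia")
    synthetic: StandConfig | None = None
    focal_species: str = "chinese_fir"
    broadleaf_species: tuple[str, ...] = ()
    buffer_width: float = 5.0
    class_width: float = 2.0
    class_origin: float = 1.0
    curve_families: tuple[str, ...] = ("normal", "negative_exponential")
    pcf_groups: tuple[str, ...] = ("snag", "fallen", "broken", "deadwood")
    pcf_r_step: float = 0.25
    pcf_r_max: float | None = None  # default: half short side
    pcf_n_sim: int = 999
    pcf_min_points: int = 10
    pcf_correction: str = "isotropic"
    mortality_groupings: tuple[str, ...] = ("all", "planted", "lcp")
    seed: int = 0

    def validate(self) -> None:
        if (self.stem_map_path is None) == (self.synthetic is None):
            raise ValueError("config needs exactly one of stem_map_path / synthetic")
        if self.stem_map_path is not None and self.window is None:
            raise ValueError("a stem-map file needs an explicit plot window")


def load_config(path) -> AnalysisConfig:
    """Load an AnalysisConfig from YAML (or JSON, a YAML subset)."""
    raw = yaml.safe_load(Path(path).read_text())
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> AnalysisConfig:
    kwargs = dict(raw)
    if "window" in kwargs and kwargs["window"] is not None:
        kwargs["window"] = PlotWindow(**kwargs["window"])
    if "synthetic" in kwargs and kwargs["synthetic"] is not None:
        kwargs["synthetic"] = stand_config_from_dict(kwargs["synthetic"])
    for key in (
        "planted_species",
        "broadleaf_species",
        "curve_families",
        "pcf_groups",
        "mortality_groupings",
    ):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return AnalysisConfig(**kwargs)


def stand_config_from_dict(raw: dict) -> StandConfig:
    kwargs = dict(raw)
    if "window" in kwargs:
        kwargs["window"] = PlotWindow(**kwargs["window"])
    if kwargs.get("thinning") is not None:
        kwargs["thinning"] = ThinningConfig(**kwargs["thinning"])
    if kwargs.get("lcp") is not None:
        kwargs["lcp"] = LCPConfig(**kwargs["lcp"])
    if kwargs.get("mortality") is not None:
        kwargs["mortality"] = MortalityConfig(**kwargs["mortality"])
    if "dbh_models" in kwargs:
        kwargs["dbh_models"] = {
            g: DBHModel(**m) for g, m in kwargs["dbh_models"].items()
        }
    if "allometry" in kwargs:
        kwargs["allometry"] = tuple(kwargs["allometry"])
    kwargs.pop("planted_species", None)
    return StandConfig(**kwargs)


def _group_points(stem_map: StemMap, groups: dict, group: str) -> np.ndarray:
    """Coordinates of a PCF group; 'deadwood' pools the three dead types,
    'deadwood_lcp' selects dead stems of unplanted species."""
    if group == "deadwood":
        ids = [i for s in DEADWOOD_STATUSES for i in groups[s]]
    elif group == "deadwood_lcp":
        ids = [
            i
            for s in DEADWOOD_STATUSES
            for i in groups[s]
            if stem_map.by_id(i).species not in stem_map.planted_species
        ]
    else:
        ids = list(groups[group])
    return stem_map.coords(ids)


def run(config: AnalysisConfig, out_dir) -> dict:
    """Run every analysis stage and write the report bundle to `out_dir`.

    Returns the JSON index (also written as index.json).  Deterministic
    given the config seed.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    index: dict = {"seed": config.seed, "stages": {}, "outputs": {}}

    def stage(name):
        def decorator(fn):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fn()
                index["stages"][name] = "ok"
                log.append(f"{name}: ok")
            except Exception as exc:
                index["stages"][name] = f"error: {exc}"
                log.append(f"{name}: ERROR {exc}")
            return fn

        return decorator

    # --- input -----------------------------------------------------------
    if config.synthetic is not None:
        stand_cfg = config.synthetic
        stem_map, ledger = generate_stand(stand_cfg)
        write_stem_map(stem_map, out / "stem_map.csv")
        (out / "ground_truth.json").write_text(json.dumps(ledger, indent=1))
        index["outputs"]["stem_map"] = "stem_map.csv"
        log.append(f"simulated stand: {len(stem_map)} stems, seed {stand_cfg.seed}")
    else:
        stem_map = read_stem_map(
            config.stem_map_path, config.window, config.planted_species
        )
        log.append(
            f"read {len(stem_map)} stems from {config.stem_map_path} "
            f"({len(stem_map.rejected)} rows rejected)"
        )

    groups = classify_groups(stem_map)
    index["counts"] = {g: len(ids) for g, ids in groups.items()}

    # --- abundance -------------------------------------------------------
    @stage("abundance")
    def _abundance():
        summary = quantities.summarize(
            stem_map,
            config.focal_species,
            broadleaf_species=frozenset(config.broadleaf_species),
        )
        summary.by_species.to_csv(out / "abundance_by_species.csv", index=False)
        summary.by_group.to_csv(out / "abundance_by_group.csv", index=False)
        index["outputs"]["abundance"] = [
            "abundance_by_species.csv",
            "abundance_by_group.csv",
        ]

    # --- DBH distributions + fits ---------------------------------------
    @stage("dbh_distributions")
    def _dbh():
        rows = []
        for group in ("deadwood", "snag", "fallen", "broken"):
            ids = (
                [i for s in DEADWOOD_STATUSES for i in groups[s]]
                if group == "deadwood"
                else groups[group]
            )
            values = [
                stem_map.by_id(i).dbh for i in ids if stem_map.by_id(i).dbh
            ]
            if len(values) < 3:
                continue
            dist = quantities.dbh_histogram(
                values, config.class_width, config.class_origin
            )
            for family in config.curve_families:
                fit = quantities.fit_dbh_curve(dist, family)
                rows.append(
                    {
                        "group": group,
                        "n": len(values),
                        "family": family,
                        "converged": fit.converged,
                        "ks_p": fit.ks_p,
                        "fits": fit.fits,
                        **{f"param_{k}": v for k, v in fit.params.items()},
                    }
                )
        pd.DataFrame(rows).to_csv(out / "dbh_fits.csv", index=False)
        index["outputs"]["dbh_fits"] = "dbh_fits.csv"

    # --- PCF envelopes ---------------------------------------------------
    @stage("point_pattern")
    def _pcf():
        files = []
        r_max = (
            config.pcf_r_max
            if config.pcf_r_max is not None
            else stem_map.window.short_side / 2.0
        )
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0x9C4]).generate_state(1)
        )
        for group in config.pcf_groups:
            pts = _group_points(stem_map, groups, group)
            if len(pts) < config.pcf_min_points:
                log.append(f"pcf[{group}]: skipped, only {len(pts)} points")
                continue
            est_probe = point_pattern.pcf_estimate(
                pts, stem_map.window, [r_max], correction=config.pcf_correction
            )
            r_grid = point_pattern.default_r_grid(
                stem_map.window,
                r_step=config.pcf_r_step,
                r_max=r_max,
                bandwidth=est_probe.bandwidth,
            )
            est, env = point_pattern.csr_envelope(
                pts,
                stem_map.window,
                r_grid,
                n_sim=config.pcf_n_sim,
                rng=rng,
                correction=config.pcf_correction,
            )
            labels, runs = point_pattern.classify_pattern(est, env)
            fname = f"pcf_{group}.csv"
            pd.DataFrame(
                {
                    "r": est.r_grid,
                    "g_hat": est.g_hat,
                    "lower": env.lower,
                    "upper": env.upper,
                    "label": labels,
                }
            ).to_csv(out / fname, index=False)
            files.append(fname)
            log.append(f"pcf[{group}]: {point_pattern.summarize_runs(runs)}")
        index["outputs"]["pcf"] = files

    # --- structure indices ----------------------------------------------
    @stage("structure")
    def _structure():
        summary = neighborhood.group_means(
            stem_map, buffer_width=config.buffer_width
        )
        summary.per_tree.to_csv(out / "structure_per_tree.csv", index=False)
        summary.means.to_csv(out / "structure_means.csv", index=False)
        index["outputs"]["structure"] = [
            "structure_per_tree.csv",
            "structure_means.csv",
        ]

    # --- competition ------------------------------------------------------
    @stage("competition")
    def _hci():
        means = competition.group_mean_hci(stem_map)
        means.to_csv(out / "hci_means.csv", index=False)
        index["outputs"]["hci"] = "hci_means.csv"

    # --- mortality --------------------------------------------------------
    @stage("mortality")
    def _mortality():
        planted = set(groups["live_planted"])
        lcp = set(groups["live_lcp"])
        dead = {i for s in DEADWOOD_STATUSES for i in groups[s]}
        dead_planted = {
            i for i in dead if stem_map.by_id(i).species in stem_map.planted_species
        }
        selections = {
            "all": (planted | lcp, dead),
            "planted": (planted, dead_planted),
            "lcp": (lcp, dead - dead_planted),
        }
        results = {}
        for name in config.mortality_groupings:
            live_ids, dead_ids = selections[name]
            ids = sorted(live_ids) + sorted(dead_ids)
            x = [stem_map.by_id(i).dbh for i in ids]
            y = [0] * len(live_ids) + [1] * len(dead_ids)
            if len(set(y)) < 2 or len(y) < 10:
                results[name] = {"error": "too few stems in one class"}
                continue
            fit = competition.fit_mortality(x, y)
            results[name] = {
                "n": fit.n,
                "beta0": fit.beta0,
                "beta1": fit.beta1,
                "se_beta0": fit.se_beta0,
                "se_beta1": fit.se_beta1,
                "auc": fit.auc,
                "rating": fit.rating,
                "converged": fit.converged,
            }
        (out / "mortality.json").write_text(json.dumps(results, indent=1))
        index["outputs"]["mortality"] = "mortality.json"

    (out / "index.json").write_text(json.dumps(index, indent=1, sort_keys=True))
    (out / "run.log").write_text("\n".join(log) + "\n")
    return index


# --- printed-count verification ------------------------------------------

#: (name, numerator, denominator, expected %) — each an arithmetic identity
#: on census counts from the two reference plots
PRINTED_COUNTS = (
    ("mixed_deadwood_share_of_stems", 558, 2467, 22.61),
    ("mixed_fir_mortality_rate", 536, 1191, 45.0),
    ("thinned_total_mortality_rate", 218, 3302, 6.60),
    ("mixed_fir_share_of_snags", 284, 304, 93.42),
    ("mixed_fir_share_of_fallen", 252, 254, 99.21),
    ("thinned_fir_share_of_snags", 71, 111, 63.96),
    ("thinned_fir_share_of_broken", 40, 41, 97.56),
    ("thinned_fir_share_of_deadwood", 162, 218, 74.31),
    ("thinned_fir_loss_fraction", 801, 1455, 55.05),
)


def verify_census_counts() -> pd.DataFrame:
    """Recompute each embedded census proportion and compare at 2 decimals.

    The comparison allows one unit in the last printed decimal, which
    absorbs truncation-vs-rounding differences in the reference values.
    """
    rows = []
    for name, num, den, expected in PRINTED_COUNTS:
        computed = round(100.0 * num / den, 2)
        rows.append(
            {
                "name": name,
                "numerator": num,
                "denominator": den,
                "computed_pct": computed,
                "expected_pct": expected,
                "match": bool(abs(computed - expected) <= 0.01 + 1e-9),
            }
        )
    return pd.DataFrame(rows)
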