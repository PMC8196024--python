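"""Experiment drivers: parameter grids, result tables, and summaries.

Each experiment expands a flat parameter grid into long-format rows (one
row per parameter combination and replicate/analytic evaluation, with all
inputs echoed), runs the corresponding analytic or Monte Carlo operation,
and returns a pandas DataFrame that round-trips through CSV.  Per-cell
seeds are spawned deterministically from the master seed, so the same
config always yields byte-identical output.
"""
from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abm, dynamics
from .core import GameParams, Institution, SimulationParams, get_norm

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "summarize",
    "validate_against_analytics",
    "load_config",
    "EXPERIMENTS",
]

log = logging.getLogger("reciprosim")

EXPERIMENTS = ("basins", "coop_sweep", "fixation", "stability", "growth_map", "economics")

# keys that are swept as grids; everything else is scalar
_GRID_KEYS = ("norm", "Q", "q", "board", "b", "c", "e1", "e2", "E", "b_over_c", "f_Za")

_DEFAULTS = dict(
    norm="stern_judging", Q=2, q=0.1, board="external",
    b=5.0, c=1.0, e1=0.02, e2=0.02, E=0.0,
    N=50, w=1.0, mu=0.025, generations=4000, burn_in=2000,
    replicates=200, seed=0, f_Za=1.0 / 50.0, resolution=15,
    invader="adherence", initial_adherents=1, p_discovery=0.0,
    b_over_c=None,
)


@dataclass
class ExperimentConfig:
    """A named experiment over a parameter grid.

    ``params`` maps config keys to scalars or lists (lists are swept as a
    full factorial grid over the keys in ``_GRID_KEYS``).  Unknown keys are
    rejected before any computation.
    """

    experiment: str
    params: dict = field(default_factory=dict)
    output_dir: Path | None = None

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; choose from {EXPERIMENTS}"
            )
        unknown = set(self.params) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = {**_DEFAULTS, **self.params}
        for key, value in merged.items():
            if isinstance(value, (list, tuple)) and key not in _GRID_KEYS:
                raise ValueError(f"config key {key!r} cannot be a grid")
        self.params = merged

    def grid(self):
        """Yield (index, dict) for every grid cell, validating values."""
        keys = [k for k in _GRID_KEYS if isinstance(self.params.get(k), (list, tuple))]
        values = [self.params[k] for k in keys]
        scalars = {k: v for k, v in self.params.items() if k not in keys}
        for idx, combo in enumerate(itertools.product(*values)) if keys else enumerate([()]):
            cell = dict(scalars)
            cell.update(dict(zip(keys, combo)))
            yield idx, cell

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(
            {"experiment": self.experiment, "params": self.params},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> ExperimentConfig:
    """Load a flat YAML/JSON config with an 'experiment' key."""
    raw = yaml.safe_load(Path(path).read_text())
    experiment = raw.pop("experiment")
    return ExperimentConfig(experiment=experiment, params=raw)


def _cell_objects(cell):
    b = cell["b"]
    if cell.get("b_over_c"):
        b = cell["b_over_c"] * cell["c"]
    game = GameParams(b=b, c=cell["c"], e1=cell["e1"], e2=cell["e2"])
    inst = Institution(Q=cell["Q"], q=cell["q"], board=cell["board"])
    return get_norm(cell["norm"]), game, inst


def _cell_seed(master: int, cell_idx: int) -> int:
    return int(np.random.SeedSequence(master).generate_state(cell_idx + 1, dtype=np.uint32)[-1])


_ECHO = ("norm", "Q", "q", "board", "b", "c", "e1", "e2", "E")


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Dispatch an experiment over its grid and return the long table.

    If ``config.output_dir`` is set, also writes ``<experiment>.csv`` and a
    ``<experiment>_summary.json`` carrying the config hash.
    """
    rows = []
    fn = {
        "basins": _run_basins_cell,
        "coop_sweep": _run_coop_cell,
        "fixation": _run_fixation_cell,
        "stability": _run_stability_cell,
        "growth_map": _run_growth_cell,
        "economics": _run_economics_cell,
    }[config.experiment]
    cells = list(config.grid())
    log.info("experiment %s: %d grid cells, config %s",
             config.experiment, len(cells), config.config_hash())
    for idx, cell in cells:
        seed = _cell_seed(int(cell["seed"]), idx)
        for row in fn(cell, seed):
            echo = {k: cell[k] for k in _ECHO}
            rows.append({**echo, **row})
    table = pd.DataFrame(rows)
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        csv_path = out / f"{config.experiment}.csv"
        table.to_csv(csv_path, index=False)
        summary = {
            "experiment": config.experiment,
            "config_hash": config.config_hash(),
            "rows": len(table),
        }
        (out / f"{config.experiment}_summary.json").write_text(json.dumps(summary, indent=2))
        log.info("wrote %s (%d rows)", csv_path, len(table))
    return table


def _run_basins_cell(cell, seed):
    norm, game, inst = _cell_objects(cell)
    report = dynamics.find_equilibria_and_basins(
        norm, game, inst, resolution=int(cell["resolution"])
    )
    for eq in report.equilibria:
        yield {
            "f_X": eq.freqs[0], "f_Y": eq.freqs[1], "f_Z": eq.freqs[2],
            "stable": eq.stable, "basin_fraction": eq.basin_fraction,
            "cooperation": eq.cooperation,
            "unclassified_fraction": report.unclassified_fraction,
        }


def _sim_params(cell, seed, mu=None):
    return SimulationParams(
        N=int(cell["N"]), w=cell["w"], mu=cell["mu"] if mu is None else mu,
        E=cell["E"], generations=int(cell["generations"]),
        burn_in=int(cell["burn_in"]), replicates=int(cell["replicates"]), seed=seed,
    )


def _run_coop_cell(cell, seed):
    norm, game, inst = _cell_objects(cell)
    res = abm.simulate_stationary_cooperation(norm, game, _sim_params(cell, seed), inst)
    for rep, value in enumerate(res.per_replicate):
        yield {"replicate": rep, "cooperation": float(value)}


def _run_fixation_cell(cell, seed, invader=None):
    norm, game, inst = _cell_objects(cell)
    sim = _sim_params(cell, seed, mu=0.0)
    res = abm.estimate_fixation_probability(
        norm, game, sim, inst,
        initial_adherents=cell["initial_adherents"],
        invader=invader or cell["invader"],
    )
    yield {
        "fixation_probability": res.probability,
        "ci_low": res.ci[0], "ci_high": res.ci[1],
        "n_fixed": res.n_fixed, "replicates": res.replicates,
        "mean_good_at_intro": res.mean_good_at_intro,
        "neutral_benchmark": 1.0 / sim.N,
    }


def _run_stability_cell(cell, seed):
    yield from _run_fixation_cell(cell, seed, invader="private")


def _run_growth_cell(cell, seed):
    norm, game, inst = _cell_objects(cell)
    gr = dynamics.adherent_growth_rate(cell["f_Za"], norm, game, inst)
    yield {
        "b_over_c": game.b / game.c, "f_Za": cell["f_Za"],
        "growth_rate": gr.rate, "payoff_difference": gr.payoff_difference,
    }


def _run_economics_cell(cell, seed):
    norm, game, inst = _cell_objects(cell)
    f_Za = cell["f_Za"]
    cr = dynamics.critical_ratio(norm, game, inst, (0.0, 0.0, f_Za, 1.0 - f_Za))
    econ = dynamics.institution_economics(
        game.b, game.c, cr.rho, int(cell["N"]), inst.Q, cell["p_discovery"]
    )
    yield {
        "rho": cr.rho, "orientation": cr.orientation,
        "tax": econ.tax, "bribe_bound": econ.bribe_bound,
        "self_sustaining": econ.self_sustaining,
    }


def summarize(table: pd.DataFrame, groupby, value_col: str, *, kind: str = "mean") -> pd.DataFrame:
    """Grouped summaries with the two CI conventions used throughout.

    ``kind='mean'``: mean with +/- 2 standard errors.  ``kind='proportion'``:
    Bernoulli column summarized with a 95% binomial (Wilson) CI.  Groups
    with a single observation get NaN mean-CIs and a warning; empty input
    raises.
    """
    if table.empty:
        raise ValueError("cannot summarize an empty table")
    groupby = list(groupby)
    out = []
    for keys, grp in table.groupby(groupby, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        vals = grp[value_col].to_numpy(dtype=float)
        n = len(vals)
        row = dict(zip(groupby, keys))
        row["n"] = n
        if kind == "mean":
            m = float(vals.mean())
            if n > 1:
                se = float(vals.std(ddof=1) / math.sqrt(n))
                row.update(mean=m, se=se, ci_low=m - 2 * se, ci_high=m + 2 * se)
            else:
                log.warning("group %s has a single observation; CI undefined", keys)
                row.update(mean=m, se=math.nan, ci_low=math.nan, ci_high=math.nan)
        elif kind == "proportion":
            from statsmodels.stats.proportion import proportion_confint

            k = int(vals.sum())
            lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
            row.update(proportion=k / n, ci_low=float(lo), ci_high=float(hi))
        else:
            raise ValueError(f"unknown summary kind {kind!r}")
        out.append(row)
    return pd.DataFrame(out)


def validate_against_analytics(
    sim_summary: pd.DataFrame,
    analytic: pd.DataFrame,
    *,
    on,
    sim_col: str = "mean",
    se_col: str = "se",
    analytic_col: str = "prediction",
    tolerance_se: float = 2.0,
) -> pd.DataFrame:
    """Flag simulation means further than ``tolerance_se`` standard errors
    from their matched analytic predictions.  Raises if the parameter sets
    do not match one-to-one."""
    if sim_summary.empty or analytic.empty:
        raise ValueError("both tables must be nonempty")
    merged = sim_summary.merge(analytic, on=list(on), how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        bad = merged.loc[merged["_merge"] != "both", list(on)]
        raise ValueError(f"mismatched parameter sets:\n{bad}")
    merged = merged.drop(columns="_merge")
    merged["deviation_se"] = (merged[sim_col] - merged[analytic_col]).abs() / merged[se_col]
    merged["passed"] = merged["deviation_se"] <= tolerance_se
    return merged
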