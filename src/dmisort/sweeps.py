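"""Scenario presets, parameter sweeps and TSV output.

A sweep is a grid over scenario parameters (recombination rate, population
size, founding contribution, epistasis, dominance, architecture), run at a
fixed replicate count per cell.  All randomness descends from one base
seed: cell i uses ``SeedSequence(base_seed, spawn_key=(i,))``, so any cell
is re-runnable in isolation and a finished sweep is bit-reproducible.

Presets encode the parameter grids of the published experiments this
package re-creates (probability-of-hybrid-speciation curves over
recombination and admixture fraction, lethal-epistasis grids, timing
grids, and the introgression-barrier grid).
"""

from __future__ import annotations

import itertools
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import SimulationConfig, run_replicates, single_dmi_config
from .fitness import FitnessParams
from .haplotypes import PARENTAL1
from .introgression import introgression_experiment
from .linkage import CANONICAL_ORDERS, LinkageArchitecture
from .observables import OUTCOME_CLASSES, summarize_outcomes

logger = logging.getLogger("dmisort")

#: default recombination grid of the probability curves
R_GRID = (0.0005, 0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 1 / 3, 0.5)

IP_GRID = tuple(np.round(np.arange(0.1, 0.91, 0.1), 2))


@dataclass
class SweepSpec:
    """Grid specification: every cell fully determines a simulation config."""

    name: str
    base: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    replicates: int = 1000
    base_seed: int = 0
    kind: str = "outcomes"  # "outcomes" or "introgression"

    def cells(self) -> list[dict]:
        """All grid cells as parameter dicts (base overridden by grid values)."""
        keys = list(self.grid)
        out = []
        for values in itertools.product(*(self.grid[k] for k in keys)):
            cell = dict(self.base)
            cell.update(dict(zip(keys, values)))
            out.append(cell)
        return out


def config_from_params(params: dict) -> SimulationConfig:
    """Build a SimulationConfig from a flat scenario-parameter dict.

    Recognized keys: architecture (canonical name, "single-dmi" or
    "separate-chromosomes"), r, N (None for deterministic), i_p, i_q, s,
    epsilon, dominance, max_generations.
    """
    s = params.get("s", 0.001)
    fp = FitnessParams.symmetric(
        s=s,
        epsilon=params.get("epsilon", -0.2),
        dominance=params.get("dominance", "codominant"),
    )
    arch_name = params.get("architecture", "Adjacent ABAB")
    r = params.get("r", 0.5)
    kwargs = {}
    for key in ("N", "i_p", "i_q", "max_generations"):
        if key in params:
            kwargs[key] = params[key]
    if arch_name == "single-dmi":
        return single_dmi_config(r, params=fp, **kwargs)
    if arch_name == "separate-chromosomes":
        arch = LinkageArchitecture.separate_chromosomes(r, r)
    else:
        arch = LinkageArchitecture.equidistant(arch_name, r)
    return SimulationConfig(params=fp, arch=arch, **kwargs)


def _outcome_row(cell: dict, summary) -> dict:
    row = dict(cell)
    row["n_replicates"] = summary.n_replicates
    for cls in OUTCOME_CLASSES:
        row[f"p[{cls}]"] = summary.table.loc[cls, "probability"]
    row["p_hybrid"] = summary.table.loc["hybrid", "probability"]
    row["p_hybrid_ci_low"] = summary.table.loc["hybrid", "ci_low"]
    row["p_hybrid_ci_high"] = summary.table.loc["hybrid", "ci_high"]
    row["hybrid_mean_fixation_time"] = summary.table.loc["hybrid", "mean_fixation_time"]
    row["hybrid_se_fixation_time"] = summary.table.loc["hybrid", "se_fixation_time"]
    return row


def _introgression_row(cell: dict, spec: SweepSpec, seed, n_tests: int) -> dict:
    fp = FitnessParams.symmetric(
        s=cell.get("s", 0.001),
        epsilon=cell.get("epsilon", -0.2),
        dominance=cell.get("dominance", "codominant"),
    )
    arch_name = cell.get("architecture", "Adjacent ABAB")
    r = cell.get("r", 0.5)
    if arch_name == "separate-chromosomes":
        arch = LinkageArchitecture.separate_chromosomes(r, r)
    else:
        arch = LinkageArchitecture.equidistant(arch_name, r)
    res = introgression_experiment(
        fp,
        arch,
        N=cell.get("N", 5000),
        reps=spec.replicates,
        base_seed=seed,
        migrant=cell.get("migrant", PARENTAL1),
        n_tests=n_tests,
    )
    row = dict(cell)
    row.update(
        n_replicates=res.n_replicates,
        p_fix=res.p_fix,
        ci_low=res.ci_low,
        ci_high=res.ci_high,
        relative=res.relative,
        p_value=res.p_value,
        significant=res.significant,
        n_tests=res.n_tests,
    )
    return row


def run_sweep(
    spec: SweepSpec, out: str | os.PathLike | None = None, resume: bool = True
) -> pd.DataFrame:
    """Run every cell of a sweep; one summary row per cell.

    Deterministic given the base seed.  When ``out`` is given, rows are
    appended to the TSV as cells finish and, on rerun, already-present
    cells are skipped (per-cell resumability).  A failing cell is reported
    in its row's ``error`` column and the sweep continues.
    """
    cells = spec.cells()
    done: set[int] = set()
    if out is not None and resume and os.path.exists(out):
        prev = pd.read_csv(out, sep="\t", comment="#")
        done = set(prev["cell"].astype(int))
        logger.info("resuming sweep %s: %d/%d cells done", spec.name, len(done), len(cells))
    elif out is not None:
        with open(out, "w") as fh:
            fh.write(f"# dmisort {__version__} sweep\n")
            for key, val in asdict(spec).items():
                fh.write(f"# {key}: {val}\n")
    rows = []
    header_written = bool(done)
    for i, cell in enumerate(cells):
        if i in done:
            continue
        seed = np.random.SeedSequence(spec.base_seed, spawn_key=(i,))
        row: dict = {"cell": i}
        try:
            if spec.kind == "introgression":
                row.update(_introgression_row(cell, spec, seed, n_tests=len(cells)))
            else:
                config = config_from_params(cell)
                records = run_replicates(config, spec.replicates, base_seed=seed)
                row.update(_outcome_row(cell, summarize_outcomes(records)))
            row["error"] = ""
        except Exception as exc:  # noqa: BLE001 — per-cell isolation
            logger.warning("cell %d of sweep %s failed: %s", i, spec.name, exc)
            row.update(cell)
            row["error"] = str(exc)
        rows.append(row)
        if out is not None:
            pd.DataFrame([row]).to_csv(
                out, sep="\t", index=False, mode="a", header=not header_written
            )
            header_written = True
        logger.info("sweep %s: cell %d/%d done", spec.name, i + 1, len(cells))
    return pd.DataFrame(rows)


def preset(name: str) -> SweepSpec:
    """Named parameter grids of the package's standard experiments."""
    presets = {
        "fig3": SweepSpec(
            name="fig3",
            base={"architecture": "single-dmi", "N": 5000, "s": 0.001, "epsilon": -0.2},
            grid={
                "dominance": ["codominant", "recessive"],
                "r": [0.005, 0.05, 0.5],
                "i_p": list(IP_GRID),
            },
        ),
        "fig4": SweepSpec(
            name="fig4",
            base={
                "architecture": "separate-chromosomes",
                "N": 5000,
                "s": 0.001,
                "epsilon": -0.2,
            },
            grid={
                "dominance": ["codominant", "recessive"],
                "r": [0.0005, 0.005, 0.05, 0.5],
                "i_p": list(IP_GRID),
            },
        ),
        "fig5": SweepSpec(
            name="fig5",
            base={"s": 0.001, "epsilon": -0.2, "dominance": "codominant", "i_p": 0.5},
            grid={
                "architecture": list(CANONICAL_ORDERS),
                "N": [50, 500, 5000, 50000],
                "r": list(R_GRID),
            },
        ),
        "fig7": SweepSpec(
            name="fig7",
            base={"s": 0.001, "epsilon": -0.2, "N": 5000},
            grid={
                "architecture": ["Adjacent ABAB", "Adjacent ABBA", "Nested ABAB"],
                "dominance": ["codominant", "recessive"],
                "r": list(R_GRID),
                "i_p": list(IP_GRID),
            },
        ),
        "s10": SweepSpec(
            name="s10",
            base={"s": 0.001, "epsilon": -0.2, "dominance": "recessive", "i_p": 0.5},
            grid={
                "architecture": list(CANONICAL_ORDERS),
                "N": [50, 500, 5000, 50000],
                "r": list(R_GRID),
            },
        ),
        "s14": SweepSpec(
            name="s14",
            base={"s": 0.001, "epsilon": -0.99, "i_p": 0.5, "architecture": "Adjacent ABAB"},
            grid={
                "dominance": ["codominant", "recessive"],
                "N": [5000, 50000],
                "r": list(R_GRID),
            },
        ),
        "s15": SweepSpec(
            name="s15",
            base={"s": 0.001, "i_p": 0.5},
            grid={
                "architecture": ["Adjacent ABAB", "Adjacent ABBA", "Crossed AABB"],
                "dominance": ["codominant", "recessive"],
                "epsilon": [-0.2, -0.99],
                "N": [50, 500, 5000, 50000],
                "r": list(R_GRID),
            },
        ),
        "s5": SweepSpec(
            name="s5",
            kind="introgression",
            base={"s": 0.001, "N": 5000, "architecture": "Adjacent ABAB"},
            grid={
                "dominance": ["codominant", "recessive"],
                "epsilon": [-0.2, -0.99],
                "r": [0.005, 0.05, 0.1, 0.5],
            },
            replicates=100_000,
        ),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(presets)}")
    return presets[name]


def _plain(obj):
    """Recursively coerce numpy scalars so YAML stays plain."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def spec_to_yaml(spec: SweepSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(asdict(spec)), fh, sort_keys=False)


def spec_from_yaml(path) -> SweepSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SweepSpec(**data)
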