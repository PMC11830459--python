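"""Grid sweeps over O2 x pH and parameter sweeps over (p, k_def, I).

The default grid spans log10[O2] from -12 to -3 in steps of 0.2 and pH
from 2 to 12 in steps of 0.5 — 46 x 21 = 966 conditions. Within one pH
row the oxygen axis is traversed in order and each solve warm-starts from
its neighbour, which cuts the per-condition cost substantially. All
sweeps are deterministic: re-running a configuration reproduces the
tables byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import ChemError, Environment, ThermoTable, nitrogen_thermo_table
from .enumeration import ReactionSet, reaction_frame
from .networks import (
    NitrogenNetwork,
    RATING_FACTORS,
    classify_key_reaction,
    enzyme_network,
    transitive_closure,
)
from .pipeline import run_condition

__all__ = [
    "SweepConfig",
    "run_grid",
    "average_overlap",
    "average_overlap_sweep",
    "key_reaction_frequency",
    "write_outputs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SweepConfig:
    """Grid and parameter ranges for a sweep.

    Grids are inclusive of both bounds (up to floating-point rounding).
    ``weighted=False`` switches the BEP weighting off (k_i = k_def for
    every reaction).
    """

    log10_o2_min: float = -12.0
    log10_o2_max: float = -3.0
    log10_o2_step: float = 0.2
    ph_min: float = 2.0
    ph_max: float = 12.0
    ph_step: float = 0.5
    p_values: tuple = (0.2,)
    k_def_values: tuple = (1.0,)
    influx_values: tuple = (1e-5,)
    efflux: float = 1e-3
    temperature: float = 288.15
    initial_conc: float = 1e-5
    top_k: int = 10
    theta: float = 0.9999
    weighted: bool = True
    tol: float = 1e-6
    horizon: float = 1e7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.log10_o2_step <= 0 or self.ph_step <= 0:
            raise ChemError("grid steps must be positive")
        if not self.p_values or not self.k_def_values or not self.influx_values:
            raise ChemError("parameter value lists must be non-empty")

    def o2_values(self) -> np.ndarray:
        n = int(round((self.log10_o2_max - self.log10_o2_min) / self.log10_o2_step))
        return 10.0 ** (self.log10_o2_min + self.log10_o2_step * np.arange(n + 1))

    def ph_values(self) -> np.ndarray:
        n = int(round((self.ph_max - self.ph_min) / self.ph_step))
        return self.ph_min + self.ph_step * np.arange(n + 1)

    def n_conditions(self) -> int:
        return len(self.o2_values()) * len(self.ph_values())

    @classmethod
    def from_dict(cls, d: dict) -> "SweepConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ChemError(f"unknown sweep-config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("p_values", "k_def_values", "influx_values"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SweepConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ChemError("sweep config must be a YAML mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("p_values", "k_def_values", "influx_values"):
            d[key] = list(d[key])
        return d


def _weighted_env(cfg: SweepConfig, o2, ph, p, k_def, influx) -> Environment:
    return Environment(
        o2=float(o2),
        ph=float(ph),
        temperature=cfg.temperature,
        influx=float(influx),
        efflux=cfg.efflux,
        k_def=float(k_def),
        p=float(p),
        initial_conc=cfg.initial_conc,
        bep_weighted=cfg.weighted,
    )


def run_grid(
    cfg: SweepConfig,
    rs: ReactionSet,
    table: ThermoTable | None = None,
    enzyme: NitrogenNetwork | None = None,
) -> pd.DataFrame:
    """Solve every grid condition for every parameter combination.

    One row per condition: environment, convergence, the state-species
    concentrations, D_enz/D_com for all three rating factors, the major
    species and the theta-key reactions. Per-condition failures are
    logged and recorded (``converged=False``), never fatal, unless every
    condition fails.
    """
    table = table or nitrogen_thermo_table()
    enz = enzyme or enzyme_network()
    rows = []
    n_fail = 0
    t0 = time.monotonic()
    for p in cfg.p_values:
        for k_def in cfg.k_def_values:
            for influx in cfg.influx_values:
                for ph in cfg.ph_values():
                    warm = None
                    for o2 in cfg.o2_values():
                        env = _weighted_env(cfg, o2, ph, p, k_def, influx)
                        row = {
                            "log10_o2": float(np.log10(o2)),
                            "ph": float(ph),
                            "p": float(p),
                            "k_def": float(k_def),
                            "influx": float(influx),
                            "weighted": cfg.weighted,
                        }
                        try:
                            res = run_condition(
                                rs, env, table,
                                top_k=cfg.top_k, theta=cfg.theta, enzyme=enz,
                                initial=warm,
                                tol=cfg.tol, horizon=cfg.horizon,
                            )
                        except ChemError as exc:
                            n_fail += 1
                            logger.warning(
                                "condition log10[O2]=%.2f pH=%.2f failed: %s",
                                row["log10_o2"], ph, exc,
                            )
                            row.update(converged=False, residual=np.nan)
                            rows.append(row)
                            warm = None
                            continue
                        ss = res.steady_state
                        warm = ss.conc if ss.converged else None
                        row.update(
                            converged=bool(ss.converged),
                            residual=float(ss.residual),
                        )
                        for sid, c in zip(ss.state_ids, ss.conc):
                            row[f"conc_{sid}"] = float(c)
                        for f in RATING_FACTORS:
                            row[f"d_enz_{f}"] = res.d_enz[f]
                            row[f"d_com_{f}"] = res.d_com[f]
                            row[f"n_links_{f}"] = len(res.superior[f])
                        row["major_species"] = ";".join(sorted(res.major))
                        row["n_key"] = len(res.key)
                        row["key_reactions"] = ";".join(rid for _, rid, _ in res.key)
                        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out) and not out["converged"].any():
        raise ChemError("every sweep condition failed")
    logger.info(
        "sweep: %d conditions, %d failures, %.1f s",
        len(out), n_fail, time.monotonic() - t0,
    )
    return out


def average_overlap(result: pd.DataFrame, factor: str = "power") -> pd.DataFrame:
    """Mean D_com and D_enz per (p, k_def, influx, weighted) combination.

    Non-converged conditions are excluded; the exclusion count is
    reported per combination.
    """
    col_com, col_enz = f"d_com_{factor}", f"d_enz_{factor}"
    groups = []
    for keys, grp in result.groupby(["p", "k_def", "influx", "weighted"]):
        ok = grp[grp["converged"].astype(bool)]
        groups.append(
            {
                "p": keys[0],
                "k_def": keys[1],
                "influx": keys[2],
                "weighted": keys[3],
                f"mean_{col_com}": ok[col_com].mean() if len(ok) else np.nan,
                f"mean_{col_enz}": ok[col_enz].mean() if len(ok) else np.nan,
                "n_converged": len(ok),
                "n_excluded": len(grp) - len(ok),
            }
        )
    return pd.DataFrame(groups)


def average_overlap_sweep(
    cfg: SweepConfig,
    rs: ReactionSet,
    table: ThermoTable | None = None,
    include_unweighted: bool = False,
) -> pd.DataFrame:
    """Run the grid for every (p, k_def) pair and average D_com/D_enz.

    With ``include_unweighted`` an extra sweep with k_i = k_def (no BEP
    weighting) is appended, one row per k_def.
    """
    result = run_grid(cfg, rs, table)
    avg = average_overlap(result)
    if include_unweighted:
        flat_cfg = dataclasses.replace(cfg, weighted=False, p_values=(0.0,))
        avg = pd.concat(
            [avg, average_overlap(run_grid(flat_cfg, rs, table))],
            ignore_index=True,
        )
    return avg


def key_reaction_frequency(
    result: pd.DataFrame,
    rs: ReactionSet,
    table: ThermoTable | None = None,
    enzyme: NitrogenNetwork | None = None,
) -> pd.DataFrame:
    """How often each reaction is a theta-key reaction across conditions.

    Counts conditions (converged only) in which each reaction appears in
    the key set, with its relation to the enzyme/community networks.
    """
    table = table or nitrogen_thermo_table()
    enz = enzyme or enzyme_network()
    com = transitive_closure(enz)
    by_id = {rxn.id: rxn for rxn in rs}
    counts: dict = {}
    ok = result[result["converged"].astype(bool)]
    for cell in ok["key_reactions"]:
        if not isinstance(cell, str) or not cell:
            continue
        for rid in cell.split(";"):
            counts[rid] = counts.get(rid, 0) + 1
    rows = []
    for rid, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        rxn = by_id[rid]
        rows.append(
            {
                "reaction_id": rid,
                "count": n,
                "relation": classify_key_reaction(rxn, enz, com, table),
            }
        )
    return pd.DataFrame(rows, columns=["reaction_id", "count", "relation"])


def write_outputs(
    outdir,
    cfg: SweepConfig,
    result: pd.DataFrame,
    rs: ReactionSet,
    table: ThermoTable | None = None,
) -> None:
    """Write the sweep table, reaction table, networks and a run manifest."""
    table = table or nitrogen_thermo_table()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.to_csv(outdir / "sweep.csv", index=False)
    reaction_frame(rs, table).to_csv(outdir / "reactions.csv", index=False)
    enz = enzyme_network()
    enz.write_graphml(outdir / "enzyme_network.graphml")
    transitive_closure(enz).write_graphml(outdir / "community_network.graphml")
    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    manifest = {
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_reactions": len(rs),
        "n_conditions": int(len(result)),
        "n_converged": int(result["converged"].astype(bool).sum()) if len(result) else 0,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
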