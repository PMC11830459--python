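"""End-to-end convenience layer: curated tables -> reactions -> steady
state -> networks -> overlap statistics for a single condition."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chem import (
    Environment,
    ThermoTable,
    nitrogen_extra_reactions,
    nitrogen_half_reactions,
    nitrogen_thermo_table,
)
from .dynamics import SteadyState, major_species, solve_steady_state
from .enumeration import ReactionSet, append_extra, enumerate_all
from .networks import (
    NitrogenNetwork,
    RATING_FACTORS,
    enzyme_network,
    key_reactions,
    overlap,
    superior_network,
    transitive_closure,
)

__all__ = ["build_nitrogen_reaction_set", "ConditionResult", "run_condition"]


def build_nitrogen_reaction_set(
    table: ThermoTable | None = None,
    include_extras: bool = True,
    log: list | None = None,
) -> ReactionSet:
    """The full directed nitrogen reaction set from the packaged tables.

    Curated extras already implied by the couple combinations are skipped
    (and logged): the shipped couple table contains protonation-variant
    couples whose differences reproduce the acid-base equilibria.
    """
    table = table or nitrogen_thermo_table()
    rs = enumerate_all(nitrogen_half_reactions(table), log=log)
    if include_extras:
        rs = append_extra(
            rs, nitrogen_extra_reactions(table), skip_duplicates=True, log=log
        )
    return rs


@dataclass
class ConditionResult:
    """Everything the graph analysis derives from one steady state."""

    env: Environment
    steady_state: SteadyState
    superior: dict            # factor -> NitrogenNetwork
    d_enz: dict               # factor -> overlap with enzyme network
    d_com: dict               # factor -> overlap with community network
    major: set
    key: list                 # (index, reaction_id, power) triples
    enzyme: NitrogenNetwork
    community: NitrogenNetwork


def run_condition(
    rs: ReactionSet,
    env: Environment,
    table: ThermoTable | None = None,
    *,
    top_k: int = 10,
    theta: float = 0.9999,
    enzyme: NitrogenNetwork | None = None,
    initial: np.ndarray | None = None,
    **solver_kwargs,
) -> ConditionResult:
    """Solve one environment and compute the full network comparison."""
    table = table or nitrogen_thermo_table()
    enz = enzyme or enzyme_network()
    com = transitive_closure(enz)
    ss = solve_steady_state(rs, env, table, initial=initial, **solver_kwargs)
    superior = {
        f: superior_network(rs, ss, table, factor=f, k=top_k)
        for f in RATING_FACTORS
    }
    d_enz = {
        f: (overlap(enz, net) if len(net) else float("nan"))
        for f, net in superior.items()
    }
    d_com = {
        f: (overlap(com, net) if len(net) else float("nan"))
        for f, net in superior.items()
    }
    return ConditionResult(
        env=env,
        steady_state=ss,
        superior=superior,
        d_enz=d_enz,
        d_com=d_com,
        major=major_species(ss),
        key=key_reactions(ss, theta),
        enzyme=enz,
        community=com,
    )
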