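"""Systematic construction of the directed reaction set.

Every unordered pair of reduction couples is combined twice — once with
each member run as the reduction — so each net redox reaction enters in
both directions. Duplicate canonical forms (which arise whenever two
couple pairs are linearly dependent) are removed keeping the first
occurrence, and curated non-redox reactions (acid-base equilibria and the
like) are appended afterwards.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .chem import (
    ChemError,
    HalfReaction,
    Reaction,
    ThermoTable,
    canonicalize,
    check_balance,
    delta_r_G0,
    equation_string,
    format_stoich_field,
)

__all__ = ["ReactionSet", "combine", "enumerate_all", "append_extra", "stoich_matrix"]


class ReactionSet:
    """Ordered, duplicate-free collection of canonical directed reactions."""

    def __init__(self, reactions: Iterable[Reaction] = ()):
        self.reactions: list[Reaction] = []
        self.index: dict[tuple, int] = {}
        for rxn in reactions:
            self.add(rxn)

    def add(self, rxn: Reaction) -> bool:
        """Add a reaction unless its canonical form is already present.

        Returns True if added, False if it was a duplicate.
        """
        canon = canonicalize(rxn)
        key = canon._key()
        if key in self.index:
            return False
        self.index[key] = len(self.reactions)
        self.reactions.append(canon)
        return True

    def __len__(self) -> int:
        return len(self.reactions)

    def __iter__(self):
        return iter(self.reactions)

    def __getitem__(self, i: int) -> Reaction:
        return self.reactions[i]

    def ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def position(self, rxn: Reaction) -> int | None:
        return self.index.get(canonicalize(rxn)._key())


def combine(red: HalfReaction, ox: HalfReaction, electron_id: str = "e-") -> Reaction:
    """Couple two half-reactions into a full, electron-free redox reaction.

    ``red`` runs as written (a reduction); ``ox`` runs in reverse (an
    oxidation). Both are scaled to the least common multiple of their
    electron numbers so the electrons cancel exactly.
    """
    if red.stoich == ox.stoich:
        raise ChemError(
            f"cannot combine {red.id!r} with itself: the result is the null reaction"
        )
    lcm = math.lcm(red.n_e, ox.n_e)
    s_red, s_ox = lcm // red.n_e, lcm // ox.n_e
    stoich: dict = {}
    for sid, c in red.stoich.items():
        stoich[sid] = stoich.get(sid, 0) + Fraction(c * s_red)
    for sid, c in ox.stoich.items():
        stoich[sid] = stoich.get(sid, 0) - Fraction(c * s_ox)
    stoich = {sid: c for sid, c in stoich.items() if c != 0}
    if electron_id in stoich:
        raise ChemError(
            f"combine({red.id}, {ox.id}): electrons did not cancel "
            f"(residual {stoich[electron_id]})"
        )
    if not stoich:
        raise ChemError(f"combine({red.id}, {ox.id}): null reaction")
    rxn = Reaction(
        id=f"{red.id}|{ox.id}",
        stoich=stoich,
        provenance=(red.id, ox.id, "forward"),
        category="redox_combination",
    )
    if not rxn.reactants or not rxn.products:
        raise ChemError(f"combine({red.id}, {ox.id}): one-sided reaction")
    return canonicalize(rxn)


def enumerate_all(
    halves: Sequence[HalfReaction],
    electron_id: str = "e-",
    log: list | None = None,
) -> ReactionSet:
    """All directed combinations of distinct couples, deduplicated.

    Pairs are visited in input order; for each unordered pair both directed
    reactions are formed (first member reduced, then second member
    reduced). Output order — and hence every reaction index downstream —
    is a pure function of the input table. Null combinations are skipped
    and recorded in ``log`` when given.
    """
    ids = [h.id for h in halves]
    if len(set(ids)) != len(ids):
        raise ChemError("half-reaction ids must be unique")
    rs = ReactionSet()
    for h1, h2 in itertools.combinations(halves, 2):
        for red, ox in ((h1, h2), (h2, h1)):
            try:
                rs.add(combine(red, ox, electron_id=electron_id))
            except ChemError as exc:
                if log is not None:
                    log.append(f"skipped {red.id}+{ox.id}: {exc}")
    return rs


def append_extra(
    base: ReactionSet,
    extra: Iterable[Reaction],
    *,
    skip_duplicates: bool = False,
    log: list | None = None,
) -> ReactionSet:
    """Append curated reactions, preserving the no-duplicates invariant.

    A canonical-form collision is an error by default (curated additions
    are expected to be disjoint from the combinatorial set). With
    ``skip_duplicates`` the colliding extra is dropped and recorded in
    ``log`` instead — needed when a couple table already implies some of
    the curated chemistry (e.g. protonation equilibria arising as
    differences of protonation-variant couples).
    """
    out = ReactionSet(base.reactions)
    for rxn in extra:
        canon = canonicalize(rxn)
        pos = out.position(canon)
        if pos is not None:
            if skip_duplicates:
                if log is not None:
                    log.append(
                        f"extra {rxn.id!r} already present as {out[pos].id!r}"
                    )
                continue
            raise ChemError(
                f"extra reaction {rxn.id!r} duplicates {out[pos].id!r}"
            )
        out.add(canon)
    return out


def stoich_matrix(rs: ReactionSet, table: ThermoTable) -> np.ndarray:
    """Net stoichiometry of the state species, shape (n_state, n_reactions).

    Rows follow the fixed state-species order of the table; O2, H+ and
    H2O are not state variables and are excluded.
    """
    C = np.zeros((len(table.state_ids), len(rs)))
    for i, rxn in enumerate(rs):
        for sid, c in rxn.stoich.items():
            k = table.state_index.get(sid)
            if k is not None:
                C[k, i] = float(c)
    return C


def reaction_frame(rs: ReactionSet, table: ThermoTable):
    """Summary table (id, equation, category, dG0) as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": rs.ids(),
            "equation": [equation_string(r) for r in rs],
            "category": [r.category for r in rs],
            "dG0_kJ_mol": [delta_r_G0(r, table) for r in rs],
            "stoich": [format_stoich_field(r.stoich) for r in rs],
        }
    )
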