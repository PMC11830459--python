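"""Directed nitrogen-transformation graphs and overlap statistics.

Reactions induce links between nitrogen species (every reactant paired
with every nitrogen product); reaction subsets selected by steady-state
ratings induce the "energetically superior" network, which is compared
against the enzyme-level network (13 curated enzymatic transformations,
nitrogen fixation excluded) and the community-level network (its
transitive closure: every conversion achievable by chaining enzymatic
steps across community members).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .chem import ChemError, Reaction, ThermoTable
from .dynamics import SteadyState
from .enumeration import ReactionSet

__all__ = [
    "NitrogenNetwork",
    "RATING_FACTORS",
    "links_from_reaction",
    "superior_network",
    "key_reactions",
    "enzyme_network",
    "transitive_closure",
    "overlap",
    "classify_key_reaction",
]

#: Rating factors for ranking reactions at a steady state: power P,
#: rate r, or negative in-situ Gibbs energy -dG.
RATING_FACTORS = ("power", "rate", "neg_delta_G")


@dataclass(frozen=True)
class NitrogenNetwork:
    """A directed graph over nitrogen species.

    ``links`` are ordered (source, target) pairs; ``nodes`` are the link
    endpoints plus any isolated nodes given explicitly. Self-loops are
    forbidden.
    """

    links: frozenset
    nodes: frozenset = frozenset()
    label: str = ""

    def __post_init__(self) -> None:
        links = frozenset((str(u), str(v)) for u, v in self.links)
        for u, v in links:
            if u == v:
                raise ChemError(f"self-loop {u!r} not allowed")
        nodes = frozenset(self.nodes) | {u for u, _ in links} | {v for _, v in links}
        object.__setattr__(self, "links", links)
        object.__setattr__(self, "nodes", nodes)

    def __len__(self) -> int:
        return len(self.links)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.links))
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def write_dot(self, path) -> None:
        g = self.to_networkx()
        lines = ["digraph {"]
        for n in sorted(g.nodes):
            lines.append(f'  "{n}";')
        for u, v in sorted(g.edges):
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def links_from_reaction(rxn: Reaction, table: ThermoTable) -> set:
    """All (reactant, product) pairs of state species, identical pairs
    excluded — every reactant is paired with every nitrogen by-product,
    regardless of how the atoms actually move."""
    state = table.state_index
    sources = [s for s, c in rxn.stoich.items() if c < 0 and s in state]
    targets = [s for s, c in rxn.stoich.items() if c > 0 and s in state]
    return {(u, v) for u in sources for v in targets if u != v}


def _ranked_indices(values: np.ndarray, ids: Sequence[str]) -> list:
    """Indices sorted by value descending, ties broken by ascending id
    (deterministic regardless of input order)."""
    return sorted(range(len(ids)), key=lambda i: (-values[i], ids[i]))


def _rating_values(ss: SteadyState, factor: str) -> np.ndarray:
    if factor == "power":
        return ss.P
    if factor == "rate":
        return ss.r
    if factor == "neg_delta_G":
        return -ss.dG
    raise ChemError(f"unknown rating factor {factor!r}; expected one of {RATING_FACTORS}")


def superior_network(
    rs: ReactionSet,
    ss: SteadyState,
    table: ThermoTable,
    factor: str = "power",
    k: int = 10,
) -> NitrogenNetwork:
    """Union of links of the top-``k`` reactions under a rating factor.

    ``neg_delta_G`` ranks by the in-situ steady-state Gibbs energy (most
    negative first), not the standard-state value.
    """
    if k > len(rs):
        raise ChemError(f"k = {k} exceeds the {len(rs)} rated reactions")
    values = _rating_values(ss, factor)
    links: set = set()
    for i in _ranked_indices(values, ss.reaction_ids)[:k]:
        links |= links_from_reaction(rs[i], table)
    return NitrogenNetwork(links=frozenset(links), label=f"superior_{factor}_top{k}")


def key_reactions(ss: SteadyState, theta: float) -> list:
    """Minimal prefix of power-ranked reactions supplying a fraction
    ``theta`` of the total positive power P_tot = sum_i max(0, P_i).

    Returns (index, reaction_id, power) triples in rank order; reactions
    with non-positive power never qualify. Empty when P_tot = 0.
    """
    if not (0.0 <= theta <= 1.0):
        raise ChemError("theta must lie in [0, 1]")
    p_tot = float(np.sum(np.maximum(0.0, ss.P)))
    if p_tot <= 0.0 or theta == 0.0:
        return []
    order = _ranked_indices(ss.P, ss.reaction_ids)
    out, cum = [], 0.0
    for i in order:
        if ss.P[i] <= 0:
            break
        out.append((i, ss.reaction_ids[i], float(ss.P[i])))
        cum += float(ss.P[i])
        if cum >= theta * p_tot:
            break
    return out


def _default_enzyme_csv() -> io.StringIO:
    return io.StringIO(
        resources.files("nitronet.data").joinpath("enzyme_links.csv").read_text()
    )


def enzyme_network(links_file=None, expected_links: int | None = 13) -> NitrogenNetwork:
    """The enzyme-level network read from a link table (id, source, target).

    The packaged default encodes the 13 enzymatic nitrogen transformations
    (DNRA, denitrification, nitrification, hydroxylamine oxidation and the
    ANAMMOX hydrazine route), with nitrogen fixation deliberately absent.
    """
    if links_file is None:
        fh, close = _default_enzyme_csv(), False
    elif hasattr(links_file, "read"):
        fh, close = links_file, False
    else:
        fh, close = open(links_file, newline=""), True
    try:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"id", "source", "target"}.issubset(
            reader.fieldnames
        ):
            raise ChemError("enzyme link table: need columns id, source, target")
        links = []
        for ln, row in enumerate(reader, start=2):
            u, v = row["source"].strip(), row["target"].strip()
            if not u or not v:
                raise ChemError(f"enzyme link table line {ln}: empty endpoint")
            links.append((u, v))
    finally:
        if close:
            fh.close()
    if len(set(links)) != len(links):
        raise ChemError("enzyme link table: duplicate links")
    if expected_links is not None and len(links) != expected_links:
        raise ChemError(
            f"enzyme link table holds {len(links)} links, expected {expected_links}"
        )
    return NitrogenNetwork(links=frozenset(links), label="enzyme")


def transitive_closure(net: NitrogenNetwork) -> NitrogenNetwork:
    """Link (u, w) present iff a directed path u -> ... -> w exists.

    Superset of the input links; idempotent. This is the community-level
    network when applied to the enzyme-level one.
    """
    g = nx.transitive_closure(net.to_networkx(), reflexive=False)
    # nodes on directed cycles gain (u, u) links; a species is never its
    # own transformation product, so drop them
    links = frozenset((u, v) for u, v in g.edges if u != v)
    return NitrogenNetwork(
        links=links, nodes=frozenset(net.nodes),
        label=(net.label + "_closure") if net.label else "closure",
    )


def overlap(reference: NitrogenNetwork, superior: NitrogenNetwork) -> float:
    """Edge overlap rate |E_ref ∩ E_sup| / |E_sup|, in [0, 1]."""
    if len(superior.links) == 0:
        raise ChemError("overlap undefined for an empty superior network")
    return len(reference.links & superior.links) / len(superior.links)


def classify_key_reaction(
    rxn: Reaction,
    enz: NitrogenNetwork,
    com: NitrogenNetwork,
    table: ThermoTable,
) -> str:
    """Relate a reaction's link set to the enzyme and community networks.

    ``all_links_in_enzyme`` when every link is a single enzymatic step;
    ``all_links_in_community`` when every link is at least achievable by
    chaining enzymatic steps; ``not_in_community`` otherwise.
    """
    links = links_from_reaction(rxn, table)
    if not links:
        raise ChemError(f"reaction {rxn.id!r} induces no nitrogen links")
    if links <= enz.links:
        return "all_links_in_enzyme"
    if links <= com.links:
        return "all_links_in_community"
    return "not_in_community"
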