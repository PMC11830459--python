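"""Random balanced chemical systems with known ground truth.

These abstract systems exercise every pipeline stage — enumeration,
dynamics, networks — without the curated nitrogen tables. Species carry a
core element Q (the nitrogen analogue, conserved among state species)
plus optional H and O balanced by proton/water analogues, so every
generated half-reaction is element- and charge-balanced by construction.
Formation energies are random, which suffices for the properties under
test (balance algebra, detailed balance, mass conservation); no attempt
is made to mimic real nitrogen thermochemistry.

The equilibrium audit is the key consistency check: in a closed system
the BEP weighting must leave equilibria untouched, so at steady state
every reaction with an uncapped rate constant has a vanishing in-situ
Gibbs energy and elemental mass is conserved, at every weight p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chem import (
    ChemError,
    Environment,
    HalfReaction,
    Species,
    ThermoTable,
    balance_couple,
    check_balance,
)
from .dynamics import SteadyState, solve_steady_state
from .enumeration import ReactionSet, enumerate_all

__all__ = ["SyntheticSpec", "generate_system", "equilibrium_audit", "AuditReport",
           "ladder_system", "planted_overlap_system", "synthetic_environment"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a random balanced system.

    ``style`` selects the system class:

    * ``"aqueous"`` — species carry random Q/H/O compositions and charges;
      couples are closed with the proton/water/electron bookkeeping
      species exactly like the nitrogen couples. Exercises the balance
      and enumeration algebra in full generality.
    * ``"ladder"`` — all species share the composition Q with strictly
      descending charges, so every couple is a pure 1-2 electron
      transfer. The bimolecular couple-pair reactions then span the full
      stoichiometric rank and equilibrate fast, which makes the closed
      system reach true equilibrium within a practical horizon — the
      property the equilibrium audit needs. (Aqueous-style systems
      instead freeze into long-lived quasi-steady glasses whenever a
      species' equilibrium abundance is astronomically small.)

    ``dGf_range`` (kJ mol^-1) bounds the random formation energies; the
    default +/-8 kJ/mol (a few RT) keeps equilibrium abundance spreads
    resolvable while giving equilibrium constants far from unity.
    """

    n_species: int = 6
    n_half_reactions: int = 8
    dGf_range: tuple = (-8.0, 8.0)
    max_core_atoms: int = 2
    style: str = "aqueous"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ChemError("need at least two species")
        if self.n_half_reactions < 1:
            raise ChemError("need at least one half-reaction")
        if self.style not in ("aqueous", "ladder"):
            raise ChemError(f"unknown style {self.style!r}")


def _aqueous_species(spec, rng) -> list:
    species = []
    for i in range(spec.n_species):
        species.append(
            Species(
                id=f"S{i:02d}",
                name=f"synthetic species {i}",
                element_counts={
                    "Q": int(rng.integers(1, spec.max_core_atoms + 1)),
                    "H": int(rng.integers(0, 4)),
                    "O": int(rng.integers(0, 3)),
                },
                charge=int(rng.integers(-2, 3)),
                delta_f_G0=float(rng.uniform(*spec.dGf_range)),
                role="nitrogen_species",
                source="synthetic",
            )
        )
    return species


def _ladder_species(spec, rng) -> list:
    return [
        Species(
            id=f"S{i:02d}",
            name=f"ladder species {i}",
            element_counts={"Q": 1},
            charge=spec.n_species - 1 - i,
            delta_f_G0=float(rng.uniform(*spec.dGf_range)),
            role="nitrogen_species",
            source="synthetic",
        )
        for i in range(spec.n_species)
    ]


def generate_system(spec: SyntheticSpec) -> tuple:
    """Random species plus balanced reduction couples, deterministic per seed.

    Returns ``(ThermoTable, [HalfReaction])``. Every couple is balanced by
    construction (element balance closed with the proton/water analogues,
    charge with the electron). Ladder systems always include the adjacent
    1-electron couples so the system is connected. Raises when the
    requested number of couples cannot be balanced within a bounded
    number of attempts.
    """
    rng = np.random.default_rng(spec.seed)
    builders = {"aqueous": _aqueous_species, "ladder": _ladder_species}
    species = builders[spec.style](spec, rng)
    species += [
        Species("Hp", "proton analogue", {"H": 1}, 1, 0.0, "proton"),
        Species("Wat", "water analogue", {"H": 2, "O": 1}, 0,
                float(rng.uniform(*spec.dGf_range)), "water"),
        Species("El", "electron", {}, -1, 0.0, "electron"),
    ]
    table = ThermoTable(species)

    halves: list[HalfReaction] = []
    seen = set()

    def try_add(ox: str, red: str) -> bool:
        try:
            half = balance_couple(
                ox, red, table, core_element="Q",
                half_id=f"c{len(halves):02d}_{ox}_{red}",
            )
        except ChemError:
            return False
        key = tuple(sorted(half.stoich.items()))
        if key in seen:
            return False
        seen.add(key)
        halves.append(half)
        return True

    if spec.style == "ladder":
        # adjacent 1-electron couples guarantee a connected fast backbone
        for i in range(spec.n_species - 1):
            try_add(f"S{i:02d}", f"S{i + 1:02d}")

    attempts, max_attempts = 0, 200 * spec.n_half_reactions
    while len(halves) < spec.n_half_reactions:
        attempts += 1
        if attempts > max_attempts:
            raise ChemError(
                f"could not balance {spec.n_half_reactions} couples in "
                f"{max_attempts} attempts (got {len(halves)})"
            )
        i, j = sorted(rng.choice(spec.n_species, size=2, replace=False))
        if spec.style == "ladder" and j - i > 2:
            continue  # keep electron numbers (and lcm scalings) small
        a, b = f"S{i:02d}", f"S{j:02d}"
        if not try_add(a, b):
            try_add(b, a)
    return table, halves


def synthetic_environment(
    table: ThermoTable,
    *,
    p: float = 0.5,
    open_system: bool = False,
    influx: float = 1e-5,
    efflux: float = 1e-3,
    temperature: float = 288.15,
    ph: float = 7.0,
) -> Environment:
    """An environment matched to a synthetic table (no oxygen species;
    the o2 slot is inert but must be positive)."""
    return Environment(
        o2=1.0,
        ph=ph,
        temperature=temperature,
        influx=influx if open_system else 0.0,
        efflux=efflux if open_system else 0.0,
        p=p,
    )


@dataclass
class AuditReport:
    """Outcome of a closed-system equilibrium audit.

    ``max_abs_dG`` is taken over reactions with uncapped rate constants
    at the integrated end state; ``kinetic_agreement`` is the worst
    log-deviation between that end state and the independently computed
    exact equilibrium over resolvable species — the measure that the
    *dynamics* found the equilibrium, not just the algebra.
    """

    max_abs_dG: float
    mass_drift: float
    kinetic_agreement: float
    converged: bool
    n_capped: int
    steady_state: SteadyState
    passed: bool


def equilibrium_audit(
    table: ThermoTable,
    halves: Sequence[HalfReaction],
    *,
    p: float = 0.5,
    tolerance: float = 1e-4,
    mass_tolerance: float = 1e-8,
    agreement_tolerance: float = 0.25,
    resolvable_floor: float = 1e-12,
    temperature: float = 288.15,
    initial_conc: float = 1e-5,
    rtol: float = 1e-10,
    horizon: float = 1e9,
) -> AuditReport:
    """Relax the closed system (I = D = 0) and check detailed balance.

    The trajectory is integrated to steady state; the audit passes iff
    (a) the integrator converged; (b) |dG_i| of every reaction with an
    uncapped rate constant is below ``tolerance`` at the end state; (c)
    conserved elemental totals drifted less than ``mass_tolerance``
    relative; and (d) every species resolvable at equilibrium (abundance
    above ``resolvable_floor``) agrees with the independently computed
    exact equilibrium to ``agreement_tolerance`` in log space —
    thermodynamically inconsistent kinetics fail this by tens of log
    units. Designed for ladder-style systems, whose fast bimolecular
    backbone spans the full stoichiometric rank and therefore reaches
    true equilibrium within the horizon; non-convergence is reported,
    not raised.
    """
    from .dynamics import CompiledSystem, equilibrium_state

    rs = enumerate_all(halves, electron_id="El")
    env = Environment(
        o2=1.0, ph=7.0, temperature=temperature,
        influx=0.0, efflux=0.0, k_def=1.0, p=p,
        initial_conc=initial_conc, conc_floor=1e-300,
    )
    ss = solve_steady_state(rs, env, table, rtol=rtol, tol=1e-9, horizon=horizon)

    active = ~ss.capped
    max_dG = float(np.max(np.abs(ss.dG[active]))) if active.any() else 0.0

    sys_ = CompiledSystem(rs, table, env)
    eq = equilibrium_state(sys_, ss.conc)
    if eq is None:
        agreement = math.inf
    else:
        resolvable = eq > resolvable_floor
        agreement = (
            float(
                np.max(
                    np.abs(
                        np.log(np.maximum(ss.conc[resolvable], 1e-300))
                        - np.log(eq[resolvable])
                    )
                )
            )
            if resolvable.any()
            else 0.0
        )

    A = table.element_matrix(["Q"])  # conserved core element only
    x0 = np.full(len(table.state_ids), initial_conc)
    drift = 0.0
    for row in A:
        tot0 = float(row @ x0)
        if tot0 > 0:
            drift = max(drift, abs(float(row @ ss.conc) - tot0) / tot0)

    passed = (
        ss.converged
        and max_dG < tolerance
        and drift < mass_tolerance
        and agreement < agreement_tolerance
    )
    return AuditReport(
        max_abs_dG=max_dG,
        mass_drift=drift,
        kinetic_agreement=agreement,
        converged=ss.converged,
        n_capped=int(ss.capped.sum()),
        steady_state=ss,
        passed=passed,
    )


def planted_overlap_system() -> tuple:
    """A system where the thermodynamically best route is 'planted'.

    The energy-rich feed E can be dissipated through two competing
    disproportionation channels of identical kinetic order in E:

    * 2E + 3H+ -> A + G + W  — strongly exergonic, but carrying a fixed
      [H+]^3 kinetic penalty (three proton uptakes);
    * 2E -> F + G            — mildly exergonic, penalty-free.

    The rate ratio is (k_strong/k_mild) * [H+]^3, independent of every
    dynamic concentration. Without thermodynamic weighting (p = 0) the
    rate constants are equal and the mild channel out-powers the planted
    one by ~1e6 at pH 2; at strong weighting the BEP boost
    exp(p*ddG/RT) ~ 1e13 overwhelms the proton penalty and the planted
    channel dominates. The recovered top-power network then matches the
    planted link set {(E,A), (E,G)} exactly — a miniature of the full
    pipeline's weighting-drives-overlap behaviour.

    Returns ``(table, halves, planted_network, environment_kwargs)``.
    """
    from .networks import NitrogenNetwork

    species = [
        Species("A", "deep sink", {"Q": 1, "H": 1}, 1, -120.0, "nitrogen_species"),
        Species("F", "shallow sink", {"Q": 1, "O": 1}, -2, -40.0, "nitrogen_species"),
        Species("G", "spent shuttle", {"Q": 1, "O": 1}, 0, 80.0, "nitrogen_species"),
        Species("E", "energy-rich feed", {"Q": 1, "O": 1}, -1, 80.0, "nitrogen_species"),
        Species("Hp", "proton analogue", {"H": 1}, 1, 0.0, "proton"),
        Species("Wat", "water analogue", {"H": 2, "O": 1}, 0, 0.0, "water"),
        Species("El", "electron", {}, -1, 0.0, "electron"),
    ]
    table = ThermoTable(species)
    halves = [
        balance_couple("E", "A", table, "Q", "E/A"),
        balance_couple("E", "F", table, "Q", "E/F"),
        balance_couple("G", "E", table, "Q", "G/E"),
    ]
    planted = NitrogenNetwork(
        links=frozenset({("E", "A"), ("E", "G")}), label="planted"
    )
    env_kwargs = dict(o2=1.0, ph=2.0, influx=1e-5, efflux=1e-3)
    return table, halves, planted, env_kwargs


def ladder_system(
    dGf_steps: Sequence[float] = (45.0, 15.0, -15.0, -45.0),
) -> tuple:
    """A redox ladder of same-composition species for closed-form checks.

    Species L0..Ln share one Q atom and descend in both charge and
    formation energy, so every couple is a pure electron transfer and
    every combined reaction is isomerisation-like (A + D -> B + C). The
    exact equilibrium point is computable from the formation energies.
    """
    n = len(dGf_steps)
    species = [
        Species(
            id=f"L{i}",
            name=f"ladder species {i}",
            element_counts={"Q": 1},
            charge=n - 1 - i,
            delta_f_G0=float(g),
            role="nitrogen_species",
        )
        for i, g in enumerate(dGf_steps)
    ]
    species += [
        Species("Hp", "proton analogue", {"H": 1}, 1, 0.0, "proton"),
        Species("Wat", "water analogue", {"H": 2, "O": 1}, 0, 0.0, "water"),
        Species("El", "electron", {}, -1, 0.0, "electron"),
    ]
    table = ThermoTable(species)
    halves = [
        balance_couple(f"L{i}", f"L{j}", table, core_element="Q",
                       half_id=f"L{i}/L{j}")
        for i in range(n)
        for j in range(i + 1, n)
    ]
    for h in halves:
        assert check_balance(h, table) == []
    return table, halves
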