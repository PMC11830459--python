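"""Species, reactions and Gibbs-energy arithmetic for aqueous redox networks.

The chemistry handled here is deliberately small: a set of aqueous solutes
(by default the eleven inorganic nitrogen compounds from nitrate down to
ammonia) together with the bookkeeping species O2, H+, H2O and the electron.
Reactions are represented with exact rational stoichiometry so that
balancing, canonicalization and duplicate detection are exact operations,
never tolerance-based.

Conventions
-----------
* Stoichiometric coefficients are negative for reactants and positive for
  products.
* Standard Gibbs energies of formation are in kJ mol^-1 at 1 M aqueous
  standard state (unit activity for water; zero by convention for H+ and
  the electron).
* A :class:`HalfReaction` is an electron-explicit reduction couple
  (electrons on the reactant side); a :class:`Reaction` is electron-free
  and strictly directed — a reaction and its reverse are distinct values.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "R_KJ",
    "Species",
    "ThermoTable",
    "HalfReaction",
    "Reaction",
    "Environment",
    "check_balance",
    "balance_couple",
    "canonicalize",
    "reverse",
    "delta_r_G0",
    "delta_r_G",
    "equation_string",
    "parse_stoich_field",
    "format_stoich_field",
    "load_species_csv",
    "load_half_reactions_csv",
    "load_reactions_csv",
    "nitrogen_thermo_table",
    "nitrogen_half_reactions",
    "nitrogen_extra_reactions",
]

#: Gas constant in kJ mol^-1 K^-1.
R_KJ = 8.314e-3

#: Molar mass of O2, g mol^-1.
O2_MOLAR_MASS = 32.0


def o2_mg_per_l_to_molar(mg_per_l: float) -> float:
    """Dissolved O2 in mg L^-1 -> mol L^-1 (10 mg/L, the typical surface-
    water saturation ceiling, is 3.1e-4 M)."""
    return mg_per_l * 1e-3 / O2_MOLAR_MASS

ELEMENTS = ("N", "H", "O")

ROLES = ("nitrogen_species", "oxygen", "proton", "water", "electron")

#: Fixed ordering of the eleven nitrogen state variables; every
#: concentration vector in the package follows this order.
NITROGEN_ORDER = (
    "NO3-",
    "NO2-",
    "NO",
    "N2O",
    "N2",
    "NH2OH",
    "NH3OH+",
    "N2H4",
    "N2H5+",
    "NH4+",
    "NH3",
)


class ChemError(ValueError):
    """Raised for malformed species, reactions or tables."""


@dataclass(frozen=True)
class Species:
    """A chemical entity with composition, charge and formation energy.

    Parameters
    ----------
    id:
        Short symbol, e.g. ``"NO3-"``. Used as the key everywhere.
    element_counts:
        Map element symbol -> non-negative atom count. Elements with a
        zero count may be omitted.
    charge:
        Signed integer charge.
    delta_f_G0:
        Standard Gibbs energy of formation, kJ mol^-1 (0 for H+ and e-).
    role:
        One of ``nitrogen_species`` (dynamic state variable), ``oxygen``
        and ``proton`` (environmentally fixed), ``water`` (unit activity)
        or ``electron`` (bookkeeping only).
    """

    id: str
    name: str
    element_counts: Mapping[str, int]
    charge: int
    delta_f_G0: float
    role: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ChemError(f"species {self.id!r}: unknown role {self.role!r}")
        counts = {e: int(c) for e, c in self.element_counts.items() if int(c) != 0}
        if any(c < 0 for c in counts.values()):
            raise ChemError(f"species {self.id!r}: negative element count")
        if not counts and self.role != "electron":
            raise ChemError(f"species {self.id!r}: empty composition")
        object.__setattr__(self, "element_counts", counts)
        if self.role in ("proton", "electron") and self.delta_f_G0 != 0.0:
            raise ChemError(
                f"species {self.id!r}: formation energy of {self.role} must be 0"
            )

    def count(self, element: str) -> int:
        return self.element_counts.get(element, 0)


class ThermoTable:
    """Ordered species collection with formation energies.

    State species (role ``nitrogen_species``) come first and define the
    ordering of every concentration vector; the remaining bookkeeping
    species (oxygen/proton/water/electron) follow.
    """

    def __init__(self, species: Sequence[Species], reference_temperature: float = 298.15):
        ids = [s.id for s in species]
        if len(set(ids)) != len(ids):
            raise ChemError("duplicate species ids in thermodynamic table")
        self.species: tuple[Species, ...] = tuple(species)
        self.reference_temperature = float(reference_temperature)
        self._by_id = {s.id: s for s in self.species}
        self.state_ids: tuple[str, ...] = tuple(
            s.id for s in self.species if s.role == "nitrogen_species"
        )
        self.state_index = {sid: k for k, sid in enumerate(self.state_ids)}

    def __contains__(self, sid: str) -> bool:
        return sid in self._by_id

    def __getitem__(self, sid: str) -> Species:
        try:
            return self._by_id[sid]
        except KeyError:
            raise ChemError(f"unknown species id {sid!r}") from None

    def __len__(self) -> int:
        return len(self.species)

    def get(self, sid: str) -> Species | None:
        return self._by_id.get(sid)

    def single(self, role: str) -> Species:
        """Return the unique species with the given role."""
        hits = [s for s in self.species if s.role == role]
        if len(hits) != 1:
            raise ChemError(f"expected exactly one {role!r} species, found {len(hits)}")
        return hits[0]

    def element_matrix(self, elements: Sequence[str] = ELEMENTS):
        """Atom counts of the state species, shape (n_elements, n_state)."""
        import numpy as np

        return np.array(
            [[self[sid].count(e) for sid in self.state_ids] for e in elements],
            dtype=float,
        )

    def validate_nitrogen(self) -> None:
        """Check the table against the fixed eleven-species nitrogen layout."""
        if self.state_ids != NITROGEN_ORDER:
            raise ChemError(
                "nitrogen table must list exactly the 11 nitrogen species "
                f"in the canonical order; got {self.state_ids}"
            )
        for role in ("oxygen", "proton", "water", "electron"):
            self.single(role)


def _normalize_stoich(stoich: Mapping[str, Fraction | int]) -> dict:
    out = {}
    for sid, coef in stoich.items():
        c = Fraction(coef)
        if c != 0:
            out[sid] = c
    return out


@dataclass(frozen=True)
class HalfReaction:
    """An electron-explicit reduction couple with integer stoichiometry.

    The electron species appears with a negative coefficient (electrons
    consumed by the reduction); ``n_e`` is the number transferred.
    """

    id: str
    stoich: Mapping[str, int]
    n_e: int

    def __post_init__(self) -> None:
        stoich = {sid: int(c) for sid, c in self.stoich.items() if int(c) != 0}
        object.__setattr__(self, "stoich", stoich)
        if self.n_e <= 0:
            raise ChemError(f"half-reaction {self.id!r}: n_e must be positive")


@dataclass(frozen=True)
class Reaction:
    """A balanced, electron-free, *directed* reaction.

    ``provenance`` is either a ``(reducing_half_id, oxidizing_half_id,
    direction)`` triple or the tag ``"extra"`` for curated additions.
    Forward and reverse directions are distinct Reaction values.
    """

    id: str
    stoich: Mapping[str, Fraction]
    provenance: tuple | str = "extra"
    category: str = "other"

    def __post_init__(self) -> None:
        object.__setattr__(self, "stoich", _normalize_stoich(self.stoich))

    @property
    def reactants(self) -> dict:
        return {sid: -c for sid, c in self.stoich.items() if c < 0}

    @property
    def products(self) -> dict:
        return {sid: c for sid, c in self.stoich.items() if c > 0}

    def canonical_key(self) -> tuple:
        return canonicalize(self)._key()

    def _key(self) -> tuple:
        return tuple(sorted((sid, c) for sid, c in self.stoich.items()))


def reverse(rxn: Reaction, new_id: str | None = None) -> Reaction:
    """The reaction run in the opposite direction (signs flipped)."""
    prov = rxn.provenance
    if isinstance(prov, tuple) and len(prov) == 3:
        prov = (prov[0], prov[1], "reverse" if prov[2] == "forward" else "forward")
    return Reaction(
        id=new_id or rxn.id + "_rev",
        stoich={sid: -c for sid, c in rxn.stoich.items()},
        provenance=prov,
        category=rxn.category,
    )


def check_balance(
    rxn: Reaction | HalfReaction,
    table: ThermoTable,
    elements: Sequence[str] | None = None,
) -> list[str]:
    """Element and charge balance violations; an empty list means balanced.

    For half-reactions each electron counts as charge -1. Violations name
    the element (or ``charge``) and the signed imbalance (products minus
    reactants).
    """
    if elements is None:
        elems: set[str] = set()
        for sid in rxn.stoich:
            elems.update(table[sid].element_counts)
        elements = sorted(elems)
    violations = []
    for e in elements:
        net = sum(Fraction(c) * table[sid].count(e) for sid, c in rxn.stoich.items())
        if net != 0:
            violations.append(f"element {e}: imbalance {net}")
    net_charge = sum(Fraction(c) * table[sid].charge for sid, c in rxn.stoich.items())
    if net_charge != 0:
        violations.append(f"charge: imbalance {net_charge}")
    if isinstance(rxn, HalfReaction):
        e_coef = next(
            (c for sid, c in rxn.stoich.items() if table[sid].role == "electron"), 0
        )
        if e_coef != -rxn.n_e:
            violations.append(
                f"n_e: declared {rxn.n_e}, electron coefficient {e_coef}"
            )
    return violations


def canonicalize(rxn: Reaction) -> Reaction:
    """Canonical form: integer coefficients divided by their gcd, species
    in sorted id order, direction preserved. Idempotent."""
    if not rxn.stoich:
        return rxn
    denoms = [Fraction(c).denominator for c in rxn.stoich.values()]
    scale = math.lcm(*denoms)
    ints = {sid: int(c * scale) for sid, c in rxn.stoich.items()}
    g = math.gcd(*(abs(v) for v in ints.values()))
    stoich = {sid: Fraction(v, g) for sid, v in sorted(ints.items())}
    return Reaction(id=rxn.id, stoich=stoich, provenance=rxn.provenance, category=rxn.category)


def delta_r_G0(rxn: Reaction | HalfReaction, table: ThermoTable) -> float:
    """Standard reaction Gibbs energy, kJ mol^-1: sum of nu * dGf0."""
    total = 0.0
    for sid, c in rxn.stoich.items():
        total += float(c) * table[sid].delta_f_G0
    return total


def delta_r_G(
    rxn: Reaction,
    conc: Mapping[str, float],
    env: "Environment",
    table: ThermoTable,
    conc_floor: float | None = None,
) -> float:
    """In-situ reaction Gibbs energy: dG0 + RT ln Q, kJ mol^-1.

    Activities are molar concentrations for solutes (coefficient 1), unity
    for water; [O2] and [H+] come from the environment. ``conc_floor``
    (default from ``env``) is applied inside the logarithm so that
    near-depleted species keep dG evaluable.
    """
    if conc_floor is None:
        conc_floor = env.conc_floor
    rt = R_KJ * env.temperature
    ln_q = 0.0
    for sid, c in rxn.stoich.items():
        sp = table[sid]
        if sp.role == "water":
            continue
        if sp.role == "electron":
            raise ChemError(f"reaction {rxn.id!r}: electron in a full reaction")
        if sp.role == "oxygen":
            a = env.o2
        elif sp.role == "proton":
            a = env.h_conc
        else:
            a = conc.get(sid)
            if a is None:
                raise ChemError(f"reaction {rxn.id!r}: no concentration for {sid!r}")
        if a < 0:
            raise ChemError(f"reaction {rxn.id!r}: negative concentration for {sid!r}")
        ln_q += float(c) * math.log(max(a, conc_floor))
    return delta_r_G0(rxn, table) + rt * ln_q


@dataclass(frozen=True)
class Environment:
    """One fixed physico-chemical condition for the open-system model.

    [O2] and [H+] are held constant; the nitrogen species are dynamic.
    ``influx`` is the ammonia supply rate I (mol L^-1 per model time unit),
    ``efflux`` the first-order washout constant D (per time unit). Time
    units are arbitrary model units; at steady state only ratios matter.
    """

    o2: float
    ph: float
    temperature: float = 288.15
    influx: float = 1e-5
    efflux: float = 1e-3
    k_def: float = 1.0
    p: float = 0.3
    initial_conc: float = 1e-5
    conc_floor: float = 1e-30
    #: False switches the BEP weighting off entirely (k_i = k_def).
    bep_weighted: bool = True

    def __post_init__(self) -> None:
        if self.o2 <= 0:
            raise ChemError("o2 must be positive")
        if not (0.0 <= self.p <= 1.0):
            raise ChemError("thermodynamic weight p must lie in [0, 1]")
        if self.influx < 0 or self.efflux < 0 or self.k_def <= 0:
            raise ChemError("rates must be non-negative and k_def positive")
        if self.temperature <= 0:
            raise ChemError("temperature must be positive")

    @property
    def h_conc(self) -> float:
        """[H+] in mol L^-1, from pH."""
        return 10.0 ** (-self.ph)

    @property
    def rt(self) -> float:
        """R*T in kJ mol^-1."""
        return R_KJ * self.temperature


def equation_string(rxn: Reaction | HalfReaction) -> str:
    """Human-readable equation, e.g. ``2NO3- -> 2NO2- + O2``."""

    def side(items):
        parts = []
        for sid, c in sorted(items.items()):
            c = Fraction(c)
            coef = "" if c == 1 else (str(c) + " ")
            parts.append(f"{coef}{sid}")
        return " + ".join(parts) if parts else "0"

    reactants = {sid: -Fraction(c) for sid, c in rxn.stoich.items() if Fraction(c) < 0}
    products = {sid: Fraction(c) for sid, c in rxn.stoich.items() if Fraction(c) > 0}
    return f"{side(reactants)} -> {side(products)}"


def balance_couple(
    ox_id: str,
    red_id: str,
    table: ThermoTable,
    core_element: str = "N",
    half_id: str | None = None,
) -> HalfReaction:
    """Construct the reduction couple ``a Ox + h H+ + n e- -> b Red + w H2O``.

    ``a`` and ``b`` are fixed by conserving ``core_element`` at its least
    common multiple; water balances O, protons balance H and the electron
    count follows from charge balance. Raises if the pair is not actually
    a reduction (n_e <= 0) or cannot be balanced with H+/H2O alone.
    """
    ox, red = table[ox_id], table[red_id]
    proton, water, electron = (table.single(r) for r in ("proton", "water", "electron"))
    n_ox, n_red = ox.count(core_element), red.count(core_element)
    if n_ox == 0 or n_red == 0:
        raise ChemError(
            f"couple {ox_id}/{red_id}: both species must contain {core_element}"
        )
    lcm = math.lcm(n_ox, n_red)
    a, b = lcm // n_ox, lcm // n_red
    w = a * ox.count("O") - b * red.count("O")
    h = b * red.count("H") + 2 * w - a * ox.count("H")
    n_e = a * ox.charge + h - b * red.charge
    if n_e <= 0:
        raise ChemError(
            f"couple {ox_id}/{red_id}: not a reduction (n_e = {n_e})"
        )
    stoich: dict = {}
    for sid, c in (
        (ox.id, -a),
        (proton.id, -h),
        (electron.id, -n_e),
        (red.id, b),
        (water.id, w),
    ):
        if c != 0:
            stoich[sid] = stoich.get(sid, 0) + c
    half = HalfReaction(id=half_id or f"{ox_id}/{red_id}", stoich=stoich, n_e=n_e)
    bad = check_balance(half, table)
    if bad:
        raise ChemError(f"couple {ox_id}/{red_id}: " + "; ".join(bad))
    return half


# ---------------------------------------------------------------------------
# Delimited-text interfaces
# ---------------------------------------------------------------------------

def parse_stoich_field(text: str, *, where: str = "") -> dict:
    """Parse ``"NO3-:-1;NO2-:1;O2:1/2"`` into a stoichiometry dict."""
    stoich: dict = {}
    for j, item in enumerate(t for t in text.split(";") if t.strip()):
        if ":" not in item:
            raise ChemError(f"{where} pair {j + 1}: expected 'species:coef', got {item!r}")
        sid, _, coef_text = item.rpartition(":")
        sid = sid.strip()
        try:
            coef = Fraction(coef_text.strip())
        except (ValueError, ZeroDivisionError):
            raise ChemError(
                f"{where} pair {j + 1}: bad coefficient {coef_text!r} for {sid!r}"
            ) from None
        if not sid:
            raise ChemError(f"{where} pair {j + 1}: empty species id")
        if sid in stoich:
            raise ChemError(f"{where} pair {j + 1}: duplicate species {sid!r}")
        stoich[sid] = coef
    return stoich


def format_stoich_field(stoich: Mapping[str, Fraction | int]) -> str:
    return ";".join(f"{sid}:{Fraction(c)}" for sid, c in sorted(stoich.items()))


def _open_text(path_or_buf):
    if hasattr(path_or_buf, "read"):
        return path_or_buf, False
    return open(path_or_buf, "r", newline=""), True


def load_species_csv(path_or_buf, reference_temperature: float = 298.15) -> ThermoTable:
    """Read a species table (columns: id, name, N, H, O, charge,
    dGf0_kJ_mol, role, source) into a :class:`ThermoTable`."""
    fh, close = _open_text(path_or_buf)
    try:
        reader = csv.DictReader(fh)
        required = {"id", "name", "N", "H", "O", "charge", "dGf0_kJ_mol", "role"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            missing = required - set(reader.fieldnames or [])
            raise ChemError(f"species table: missing columns {sorted(missing)}")
        species = []
        for ln, row in enumerate(reader, start=2):
            try:
                species.append(
                    Species(
                        id=row["id"].strip(),
                        name=row["name"].strip(),
                        element_counts={e: int(row[e] or 0) for e in ELEMENTS},
                        charge=int(row["charge"]),
                        delta_f_G0=float(row["dGf0_kJ_mol"]),
                        role=row["role"].strip(),
                        source=(row.get("source") or "").strip(),
                    )
                )
            except (ValueError, ChemError) as exc:
                raise ChemError(f"species table line {ln}: {exc}") from None
    finally:
        if close:
            fh.close()
    return ThermoTable(species, reference_temperature)


def load_half_reactions_csv(path_or_buf, table: ThermoTable) -> list[HalfReaction]:
    """Read half-reactions (columns: id, n_e, stoich) with strict checking."""
    fh, close = _open_text(path_or_buf)
    halves = []
    try:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"id", "n_e", "stoich"}.issubset(reader.fieldnames):
            raise ChemError("half-reaction table: need columns id, n_e, stoich")
        for ln, row in enumerate(reader, start=2):
            where = f"half-reaction table line {ln}"
            stoich = parse_stoich_field(row["stoich"], where=where)
            for sid in stoich:
                if sid not in table:
                    raise ChemError(f"{where}: unknown species {sid!r}")
            try:
                n_e = int(row["n_e"])
            except ValueError:
                raise ChemError(f"{where}: bad n_e {row['n_e']!r}") from None
            half = HalfReaction(id=row["id"].strip(), stoich=stoich, n_e=n_e)
            bad = check_balance(half, table)
            if bad:
                raise ChemError(f"{where} ({half.id}): " + "; ".join(bad))
            halves.append(half)
    finally:
        if close:
            fh.close()
    ids = [h.id for h in halves]
    if len(set(ids)) != len(ids):
        raise ChemError("half-reaction table: duplicate ids")
    return halves


def load_reactions_csv(path_or_buf, table: ThermoTable, category: str = "other") -> list[Reaction]:
    """Read full reactions (columns: id, stoich[, category])."""
    fh, close = _open_text(path_or_buf)
    rxns = []
    try:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"id", "stoich"}.issubset(reader.fieldnames):
            raise ChemError("reaction table: need columns id, stoich")
        for ln, row in enumerate(reader, start=2):
            where = f"reaction table line {ln}"
            stoich = parse_stoich_field(row["stoich"], where=where)
            for sid in stoich:
                if sid not in table:
                    raise ChemError(f"{where}: unknown species {sid!r}")
                if table[sid].role == "electron":
                    raise ChemError(f"{where}: electron species in full reaction")
            rxn = Reaction(
                id=row["id"].strip(),
                stoich=stoich,
                provenance="extra",
                category=(row.get("category") or category).strip(),
            )
            if not rxn.reactants or not rxn.products:
                raise ChemError(f"{where}: need at least one reactant and one product")
            bad = check_balance(rxn, table)
            if bad:
                raise ChemError(f"{where} ({rxn.id}): " + "; ".join(bad))
            rxns.append(canonicalize(rxn))
    finally:
        if close:
            fh.close()
    return rxns


# ---------------------------------------------------------------------------
# Packaged nitrogen tables
# ---------------------------------------------------------------------------

def _data_text(name: str) -> io.StringIO:
    return io.StringIO(
        resources.files("nitronet.data").joinpath(name).read_text(encoding="utf-8")
    )


def nitrogen_thermo_table() -> ThermoTable:
    """The curated nitrogen species table shipped with the package."""
    table = load_species_csv(_data_text("species.csv"))
    table.validate_nitrogen()
    return table


def nitrogen_half_reactions(table: ThermoTable | None = None) -> list[HalfReaction]:
    """The curated reduction couples (37 nitrogen couples + the O2/H2O couple)."""
    table = table or nitrogen_thermo_table()
    return load_half_reactions_csv(_data_text("half_reactions.csv"), table)


def nitrogen_extra_reactions(table: ThermoTable | None = None) -> list[Reaction]:
    """Curated non-redox additions (acid-base equilibria, both directions)."""
    table = table or nitrogen_thermo_table()
    return load_reactions_csv(_data_text("extra_reactions.csv"), table, category="acid_base")
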