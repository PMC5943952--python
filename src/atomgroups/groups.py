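"""Breakdown of a molecule into atom-centered groups.

Every sufficiently connected heavy atom that is not a halogen is a *group
center*.  A center is classified by element, charge and unsaturation into
an atom type (``C sp3``, ``C aromatic``, ``N(+) sp2``, ``S4``, ...) and its
immediate neighborhood is encoded into a canonical neighbor string
(``H2CO``, ``C:N2``, ``CO=O2(-)``, ``HC(pi)``).  The (type, neighbors)
pair is the :class:`GroupSignature` that indexes a parameter-table row.

Grammar conventions (chosen to reproduce the printed table strings):

* hydrogens first (``H``/``H2``/``H3``);
* one token per heavy neighbor, ``[bond marker][element]`` with bond
  markers '' (single), ``=`` (double), ``#`` (triple), ``:`` (aromatic);
  identical tokens aggregate with a trailing count;
* tokens sorted element-major (B, C, N, O, P, S, Si, F, Cl, Br, J — iodine
  is written ``J``), within an element by bond marker ('' < ``=`` < ``#``
  < ``:``);
* the net formal charge of the neighbor shell, when nonzero, is appended
  as ``(+)``/``(-)`` (so the nitro nitrogen reads ``CO=O(-)`` and the
  sulfonate sulfur ``CO=O2(-)`` regardless of which oxygen carries the
  drawn charge);
* for the saturated divalent/trivalent center types ``N sp3``, ``O`` and
  ``S2`` a trailing ``(pi)``/``(2pi)`` counts the neighbors that are
  aromatic or are C/N atoms engaged in a multiple bond (phenol oxygen
  ``HC(pi)``, ester oxygen ``C2(pi)``, diphenyl ether ``C2(2pi)``).
  Hypervalent S=O / P=O neighbors do not count as pi.

Atoms with fewer than two connections (counting hydrogens) are *not*
centers: carbonyl/sulfonyl/phosphoryl oxygens, carboxylate and nitro
O(-), and nitrile nitrogens appear only inside their neighbor's string.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .molgraph import (
    AROMATIC,
    DOUBLE,
    HALOGENS,
    SINGLE,
    TRIPLE,
    MolecularGraph,
)

#: Element-major ordering of neighbor tokens.
ELEMENT_ORDER = ("B", "C", "N", "O", "P", "S", "Si", "F", "Cl", "Br", "J")
_BOND_MARKER = {SINGLE: "", DOUBLE: "=", TRIPLE: "#", AROMATIC: ":"}
_MARKER_ORDER = {"": 0, "=": 1, "#": 2, ":": 3}

#: Special (non atom-centered) group keys.
ALKANE_C = "alkane_C"
UNSAT_HC_C = "unsatHC_C"
H_ACCEPTOR = "h_acceptor"
SPECIAL_KEYS = (ALKANE_C, UNSAT_HC_C, H_ACCEPTOR)


class GroupSignature(NamedTuple):
    """Canonical (atom type, neighbor string) key of a parameter-table row."""

    atom_type: str
    neighbors: str

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.atom_type} {self.neighbors}".strip()


@dataclass
class GroupCountVector:
    """Per-molecule group counts: the A_i (and special-group B_j) terms."""

    counts: dict[GroupSignature, int] = field(default_factory=dict)
    special_counts: dict[str, int] = field(
        default_factory=lambda: {k: 0 for k in SPECIAL_KEYS}
    )

    @property
    def n_centers(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "GroupCountVector") -> "GroupCountVector":
        counts = dict(self.counts)
        for sig, c in other.counts.items():
            counts[sig] = counts.get(sig, 0) + c
        special = {
            k: self.special_counts.get(k, 0) + other.special_counts.get(k, 0)
            for k in SPECIAL_KEYS
        }
        return GroupCountVector(counts, special)


class PerceptionError(ValueError):
    """An atom's neighborhood cannot be expressed in the group grammar."""


def _element_token(element: str) -> str:
    return "J" if element == "I" else element


def _has_multiple_bond(mol: MolecularGraph, idx: int) -> bool:
    return any(order in (DOUBLE, TRIPLE) for order in mol.bond_orders(idx))


def _is_pi_neighbor(mol: MolecularGraph, idx: int) -> bool:
    if mol.is_aromatic_atom(idx):
        return True
    return mol.atoms[idx].element in ("C", "N") and _has_multiple_bond(mol, idx)


def is_group_center(mol: MolecularGraph, idx: int) -> bool:
    """Heavy non-halogen atom with at least two connections (H included)."""
    atom = mol.atoms[idx]
    if atom.element == "H" or atom.element in HALOGENS:
        return False
    return mol.connections(idx) >= 2


def _charge_marker(charge: int) -> str:
    if charge == 0:
        return ""
    sign = "+" if charge > 0 else "-"
    mag = abs(charge)
    return f"({sign})" if mag == 1 else f"({mag}{sign})"


def atom_type(mol: MolecularGraph, idx: int) -> str:
    """Atom-type label of a group center."""
    atom = mol.atoms[idx]
    el = atom.element
    if el == "H" or el in HALOGENS:
        raise PerceptionError(
            f"atom {idx} ({el}) is not a group center (hydrogens and "
            "halogens appear only in neighbor strings)"
        )
    marker = _charge_marker(atom.charge)
    orders = mol.bond_orders(idx)
    aromatic = AROMATIC in orders
    n_double = orders.count(DOUBLE)
    n_triple = orders.count(TRIPLE)
    if el == "C":
        if aromatic:
            hyb = "aromatic"
        elif n_triple or n_double >= 2:
            hyb = "sp"
        elif n_double:
            hyb = "sp2"
        else:
            hyb = "sp3"
        return f"C{marker} {hyb}"
    if el == "N":
        if atom.charge < 0:
            return f"N{marker}"
        if aromatic:
            hyb = "aromatic"
        elif n_triple or n_double >= 2:
            hyb = "sp"
        elif n_double:
            hyb = "sp2"
        else:
            hyb = "sp3"
        return f"N{marker} {hyb}"
    if el == "O":
        return f"O{marker}"
    if el == "S":
        return f"S2{marker}" if mol.connections(idx) <= 2 else f"S4{marker}"
    if el == "P":
        if atom.charge:
            return f"P{marker}"
        return f"P{mol.connections(idx)}"
    if el == "Si":
        return f"Si{marker}"
    if el == "B":
        return f"B{marker}"
    raise PerceptionError(f"atom {idx}: element {el} outside the supported set")


#: Center types whose neighbor strings carry the trailing pi count.
_PI_TYPES = frozenset({"N sp3", "O", "S2"})


def canonical_neighbor_string(mol: MolecularGraph, idx: int) -> str:
    """Canonical neighbor string of a group center (see module docstring)."""
    atom = mol.atoms[idx]
    parts: list[str] = []
    if atom.h_count == 1:
        parts.append("H")
    elif atom.h_count > 1:
        parts.append(f"H{atom.h_count}")

    tokens: dict[tuple[str, str], int] = {}
    net_charge = 0
    for j, order in mol.neighbors(idx):
        el = _element_token(mol.atoms[j].element)
        if el not in ELEMENT_ORDER and el != "H":
            raise PerceptionError(
                f"atom {idx}: neighbor element {mol.atoms[j].element} cannot "
                "be expressed in the group grammar"
            )
        marker = _BOND_MARKER[order]
        tokens[(marker, el)] = tokens.get((marker, el), 0) + 1
        net_charge += mol.atoms[j].charge

    def sort_key(item: tuple[tuple[str, str], int]):
        (marker, el), _ = item
        return (ELEMENT_ORDER.index(el), _MARKER_ORDER[marker])

    for (marker, el), count in sorted(tokens.items(), key=sort_key):
        parts.append(f"{marker}{el}" + (str(count) if count > 1 else ""))

    if net_charge:
        parts.append(_charge_marker(net_charge))

    if atom_type(mol, idx) in _PI_TYPES:
        n_pi = sum(1 for j, _ in mol.neighbors(idx) if _is_pi_neighbor(mol, j))
        if n_pi == 1:
            parts.append("(pi)")
        elif n_pi > 1:
            parts.append(f"({n_pi}pi)")

    return "".join(parts)


def signature(mol: MolecularGraph, idx: int) -> GroupSignature:
    return GroupSignature(atom_type(mol, idx), canonical_neighbor_string(mol, idx))


#: Regex accepting every string the grammar can emit (used to audit tables).
SIGNATURE_STRING_RE = re.compile(
    r"^(H\d?)?"
    r"((:|=|#)?(Si|Cl|Br|B|C|N|O|P|S|F|J)\d*)*"
    r"(\(\d*[+-]\))?"
    r"(\(\d*pi\))?$"
)


def detect_hydrocarbon_special(mol: MolecularGraph) -> tuple[int, int]:
    """Per-carbon special counts ``(alkane_C, unsatHC_C)``.

    Pure hydrocarbons contribute one extra term per carbon atom: through
    the alkane entry when fully saturated, through the unsaturated-HC
    entry when any double/triple/aromatic bond is present.  Molecules with
    heteroatoms get (0, 0).
    """
    elements = {a.element for a in mol.atoms}
    if not elements or elements - {"C", "H"}:
        return (0, 0)
    n_c = sum(1 for a in mol.atoms if a.element == "C")
    saturated = all(b.order == SINGLE for b in mol.bonds)
    return (n_c, 0) if saturated else (0, n_c)


def detect_h_acceptor(mol: MolecularGraph) -> int:
    """Count intramolecular hydrogen-bond donor/acceptor pairs.

    A donor is an N/O bearing at least one hydrogen; an acceptor any other
    N/O whose topological distance from the donor is 3-5 bonds, closing a
    5-7-membered hydrogen-bonded ring.  Pairs are formed greedily with
    each atom participating in at most one pair, so ethylene glycol counts
    a single internal hydrogen bond.  Off by default in perception: the
    packaged models fitted it on very few molecules.
    """
    candidates = [
        i for i, a in enumerate(mol.atoms) if a.element in ("N", "O")
    ]
    if len(candidates) < 2:
        return 0
    dist = _bond_distances(mol, candidates)
    used: set[int] = set()
    count = 0
    for d in candidates:
        if mol.atoms[d].h_count == 0 or d in used:
            continue
        for a in candidates:
            if a == d or a in used:
                continue
            if 3 <= dist[d].get(a, 10 ** 9) <= 5:
                used.add(d)
                used.add(a)
                count += 1
                break
    return count


def _bond_distances(mol: MolecularGraph, sources: Iterable[int]) -> dict[int, dict[int, int]]:
    from collections import deque

    out: dict[int, dict[int, int]] = {}
    for s in sources:
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v, _ in mol.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        out[s] = dist
    return out


def perceive(mol: MolecularGraph, *, h_acceptor: bool = False) -> GroupCountVector:
    """Break a molecule into its atom groups and special-group counts.

    Multi-fragment records (ionic liquids stored as one cation + anion
    record) are perceived jointly: the result is the sum over all
    fragments, matching the single experimental value such records carry.
    """
    counts: dict[GroupSignature, int] = {}
    for idx in range(len(mol.atoms)):
        if not is_group_center(mol, idx):
            continue
        sig = signature(mol, idx)
        counts[sig] = counts.get(sig, 0) + 1
    alkane, unsat = detect_hydrocarbon_special(mol)
    special = {
        ALKANE_C: alkane,
        UNSAT_HC_C: unsat,
        H_ACCEPTOR: detect_h_acceptor(mol) if h_acceptor else 0,
    }
    return GroupCountVector(counts, special)
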