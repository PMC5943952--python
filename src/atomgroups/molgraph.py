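"""Molecular data model, structure input and normalization.

The package works on a deliberately small graph representation: heavy atoms
with formal charges and materialized hydrogen *counts* (hydrogens are never
graph nodes), plus bonds of order single/double/triple/aromatic.  RDKit is
used only at the input boundary (SMILES and V2000 SDF parsing); everything
downstream — normalization, group perception, prediction — operates on
:class:`MolecularGraph`.

Aromaticity convention
----------------------
Structures read through RDKit are re-perceived with the MDL aromaticity
model: six-membered benzenoid rings (benzene, pyridine, pyridinium, fused
polycyclics) are aromatic, while five-membered heteroaromatics (pyrrole,
furan, thiophene, imidazole) are kept as KekulĂŠ single/double structures.
This is the convention the packaged parameter tables are written in: they
contain rows such as ``C sp2  H=CN`` (azole ring carbons) and
``N sp3  HC2(2pi)`` (pyrrole-type nitrogen) that only arise from KekulĂŠ
five-rings, next to genuinely aromatic rows such as ``C aromatic  H:C2``.

Amidinium convention
--------------------
N-C-N cations (imidazolium, amidinium, guanidinium) are stored with the
positive charge on the central carbon and aromatic carbon-nitrogen bonds,
reflecting the delocalized charge distribution of these ions rather than
the N(+) localization of common drawings.  :func:`normalize_amidinium`
rewrites incoming structures into this form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: Elements the parameter tables cover.
ELEMENT_WHITELIST = frozenset(
    {"H", "B", "C", "N", "O", "P", "S", "Si", "F", "Cl", "Br", "I"}
)

HALOGENS = frozenset({"F", "Cl", "Br", "I"})

SINGLE = "single"
DOUBLE = "double"
TRIPLE = "triple"
AROMATIC = "aromatic"

_RDKIT_ORDER = {
    Chem.BondType.SINGLE: SINGLE,
    Chem.BondType.DOUBLE: DOUBLE,
    Chem.BondType.TRIPLE: TRIPLE,
    Chem.BondType.AROMATIC: AROMATIC,
}
_MOLBLOCK_ORDER = {1: SINGLE, 2: DOUBLE, 3: TRIPLE, 4: AROMATIC}
_ORDER_MOLBLOCK = {v: k for k, v in _MOLBLOCK_ORDER.items()}


@dataclass(frozen=True)
class Atom:
    element: str
    charge: int = 0
    h_count: int = 0


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: str

    def other(self, idx: int) -> int:
        return self.j if idx == self.i else self.i


@dataclass
class MolecularGraph:
    """Heavy-atom graph with hydrogen counts.

    Attributes
    ----------
    atoms : list of Atom
    bonds : list of Bond
    name : record name (SDF title line or user supplied)
    id : compound identifier used in tables/reports; defaults to ``name``
    props : property fields carried along from an SDF record
    """

    atoms: list[Atom]
    bonds: list[Bond]
    name: str = ""
    id: str = ""
    props: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            self.id = self.name
        self._adjacency: list[list[tuple[int, str]]] | None = None

    # -- topology helpers -------------------------------------------------

    def neighbors(self, idx: int) -> list[tuple[int, str]]:
        """``(neighbor index, bond order)`` pairs of atom ``idx``."""
        if self._adjacency is None:
            adj: list[list[tuple[int, str]]] = [[] for _ in self.atoms]
            for b in self.bonds:
                adj[b.i].append((b.j, b.order))
                adj[b.j].append((b.i, b.order))
            self._adjacency = adj
        return self._adjacency[idx]

    def heavy_degree(self, idx: int) -> int:
        return len(self.neighbors(idx))

    def connections(self, idx: int) -> int:
        """Heavy neighbors plus hydrogens — the atom's connectivity."""
        return self.heavy_degree(idx) + self.atoms[idx].h_count

    def is_aromatic_atom(self, idx: int) -> bool:
        return any(order == AROMATIC for _, order in self.neighbors(idx))

    def bond_orders(self, idx: int) -> list[str]:
        return [order for _, order in self.neighbors(idx)]

    def net_charge(self) -> int:
        return sum(a.charge for a in self.atoms)

    def formula(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a in self.atoms:
            counts[a.element] = counts.get(a.element, 0) + 1
            if a.h_count:
                counts["H"] = counts.get("H", 0) + a.h_count
        return counts

    def _invalidate(self) -> None:
        self._adjacency = None


@dataclass(frozen=True)
class EligibilityVerdict:
    """Outcome of the element whitelist check."""

    offending_elements: tuple[str, ...]

    @property
    def eligible(self) -> bool:
        return not self.offending_elements

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.eligible


def validate_elements(mol: MolecularGraph) -> EligibilityVerdict:
    """Check the element whitelist (H, B, C, N, O, P, S, Si, halogens)."""
    offenders = sorted({a.element for a in mol.atoms} - ELEMENT_WHITELIST)
    return EligibilityVerdict(tuple(offenders))


# ---------------------------------------------------------------------------
# RDKit boundary
# ---------------------------------------------------------------------------


def _graph_from_rdkit(mol: Chem.Mol, name: str = "", id: str = "",
                      props: dict[str, str] | None = None) -> MolecularGraph:
    atoms = [
        Atom(a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs())
        for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        order = _RDKIT_ORDER.get(b.GetBondType())
        if order is None:
            raise ValueError(
                f"unsupported bond order {b.GetBondType()} between atoms "
                f"{b.GetBeginAtomIdx()} and {b.GetEndAtomIdx()}"
            )
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return MolecularGraph(atoms, bonds, name=name, id=id, props=props or {})


def _apply_mdl_aromaticity(mol: Chem.Mol) -> Chem.Mol:
    Chem.Kekulize(mol, clearAromaticFlags=True)
    Chem.SetAromaticity(mol, Chem.AROMATICITY_MDL)
    return mol


def read_smiles(smiles: str, name: str = "", *, normalize: bool = True) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Aromaticity is re-perceived with the MDL model (see module docstring)
    and, unless ``normalize=False``, amidinium/imidazolium/guanidinium
    cations are rewritten into the central-carbon charge convention.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"could not parse SMILES {smiles!r}")
    _apply_mdl_aromaticity(mol)
    graph = _graph_from_rdkit(mol, name=name or smiles, id=name or smiles)
    if normalize:
        graph = normalize_amidinium(graph)
    return graph


@dataclass(frozen=True)
class RecordError:
    index: int
    message: str


@dataclass
class SDFResult:
    """Molecules read from an SDF plus per-record errors."""

    molecules: list[MolecularGraph]
    errors: list[RecordError]

    def __iter__(self) -> Iterator[MolecularGraph]:
        return iter(self.molecules)

    def __len__(self) -> int:
        return len(self.molecules)


def _split_sdf(text: str) -> list[str]:
    records = []
    current: list[str] = []
    for line in text.splitlines():
        if line.strip() == "$$$$":
            records.append("\n".join(current) + "\n")
            current = []
        else:
            current.append(line)
    if any(l.strip() for l in current):
        records.append("\n".join(current) + "\n")
    return records


def _parse_molblock_literal(block: str) -> MolecularGraph:
    """Minimal V2000 reader that takes atoms/bonds/charges verbatim.

    Fallback for records RDKit cannot kekulize — in practice our own
    normalized amidinium output, whose aromatic N-C(+)-N bonds lie outside
    any perceivable aromatic ring.  Explicit hydrogens are collapsed into
    neighbor ``h_count``; no hydrogens are implied, so this path is only
    correct for files written with explicit hydrogens (as :func:`write_sdf`
    does).
    """
    lines = block.splitlines()
    if len(lines) < 4 or "V2000" not in lines[3]:
        raise ValueError("not a V2000 molblock")
    name = lines[0].strip()
    n_atoms = int(lines[3][0:3])
    n_bonds = int(lines[3][3:6])
    elements: list[str] = []
    for k in range(n_atoms):
        ln = lines[4 + k]
        elements.append(ln[31:34].strip())
    raw_bonds: list[tuple[int, int, str]] = []
    for k in range(n_bonds):
        ln = lines[4 + n_atoms + k]
        i = int(ln[0:3]) - 1
        j = int(ln[3:6]) - 1
        order = _MOLBLOCK_ORDER[int(ln[6:9])]
        raw_bonds.append((i, j, order))
    charges = {k: 0 for k in range(n_atoms)}
    props: dict[str, str] = {}
    for ln in lines[4 + n_atoms + n_bonds:]:
        if ln.startswith("M  CHG"):
            fields = ln.split()
            n = int(fields[2])
            for t in range(n):
                charges[int(fields[3 + 2 * t]) - 1] = int(fields[4 + 2 * t])
        elif ln.startswith("M  END"):
            break
    # property block
    key = None
    for ln in lines[4 + n_atoms + n_bonds:]:
        if ln.startswith("> "):
            key = ln.split("<", 1)[-1].rstrip(">").strip() if "<" in ln else ln[2:].strip()
        elif key is not None and ln.strip() and not ln.startswith("M  "):
            props[key] = ln.strip()
            key = None
    # collapse explicit hydrogens
    h_counts = [0] * n_atoms
    keep = [el != "H" for el in elements]
    for i, j, order in raw_bonds:
        if elements[i] == "H" and keep[j]:
            h_counts[j] += 1
        elif elements[j] == "H" and keep[i]:
            h_counts[i] += 1
    remap: dict[int, int] = {}
    atoms: list[Atom] = []
    for k in range(n_atoms):
        if keep[k]:
            remap[k] = len(atoms)
            atoms.append(Atom(elements[k], charges[k], h_counts[k]))
    bonds = [
        Bond(remap[i], remap[j], order)
        for i, j, order in raw_bonds
        if keep[i] and keep[j]
    ]
    return MolecularGraph(atoms, bonds, name=name, id=name)


def _block_has_aromatic_bonds(block: str) -> bool:
    lines = block.splitlines()
    if len(lines) < 4 or "V2000" not in lines[3]:
        return False
    try:
        n_atoms = int(lines[3][0:3])
        n_bonds = int(lines[3][3:6])
        return any(
            int(lines[4 + n_atoms + k][6:9]) == 4 for k in range(n_bonds)
        )
    except (ValueError, IndexError):
        return False


def _read_record(block: str, id_property: str | None) -> MolecularGraph:
    if _block_has_aromatic_bonds(block):
        # explicit aromatic (order 4) bonds: take the record verbatim.
        # V2000 interchange files are Kekulé; order-4 records are in practice
        # our own output (write_sdf), which always carries explicit hydrogens
        # and may contain amidinium bonds RDKit cannot kekulize.
        graph = _parse_molblock_literal(block)
        if id_property and id_property in graph.props:
            graph.id = graph.props[id_property]
        return graph
    mol = Chem.MolFromMolBlock(block, sanitize=True, removeHs=True)
    if mol is not None:
        _apply_mdl_aromaticity(mol)
        props = mol.GetPropsAsDict(includePrivate=False)
        props = {k: str(v) for k, v in props.items()}
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        graph = _graph_from_rdkit(mol, name=name, id=name, props=props)
    else:
        graph = _parse_molblock_literal(block)
    if id_property and id_property in graph.props:
        graph.id = graph.props[id_property]
    return graph


def read_sdf(path: str | Path, *, id_property: str | None = None,
             normalize: bool = True) -> SDFResult:
    """Read a V2000 SDF file.

    Unreadable records are reported in ``result.errors`` (1-based record
    index) while the remaining records are still returned.  Records with
    elements outside the whitelist are returned as graphs — eligibility is
    a separate check (:func:`validate_elements`) so that nothing is dropped
    silently.
    """
    text = Path(path).read_text()
    molecules: list[MolecularGraph] = []
    errors: list[RecordError] = []
    for idx, block in enumerate(_split_sdf(text), start=1):
        try:
            graph = _read_record(block, id_property)
        except Exception as exc:
            errors.append(RecordError(idx, f"record {idx}: {exc}"))
            continue
        if normalize:
            graph = normalize_amidinium(graph)
        molecules.append(graph)
    return SDFResult(molecules, errors)


def write_sdf(mols: MolecularGraph | Iterable[MolecularGraph],
              path: str | Path) -> None:
    """Write graphs as a V2000 SDF with explicit hydrogens.

    Hydrogens are written as explicit atoms so the file round-trips through
    :func:`read_sdf` without any valence model, including normalized
    amidinium structures whose aromatic bonds RDKit cannot kekulize.
    """
    if isinstance(mols, MolecularGraph):
        mols = [mols]
    blocks = []
    for mol in mols:
        blocks.append(_to_molblock(mol))
    Path(path).write_text("".join(blocks))


def _to_molblock(mol: MolecularGraph) -> str:
    atom_lines = []
    bond_lines = []
    charges = []
    n_heavy = len(mol.atoms)
    h_index = n_heavy
    for k, a in enumerate(mol.atoms):
        atom_lines.append(
            f"{0.0:10.4f}{0.0:10.4f}{0.0:10.4f} {a.element:<3} 0  0  0  0  0  0  0  0  0  0  0  0"
        )
        if a.charge:
            charges.append((k + 1, a.charge))
    for b in mol.bonds:
        bond_lines.append(f"{b.i + 1:>3}{b.j + 1:>3}{_ORDER_MOLBLOCK[b.order]:>3}  0")
    for k, a in enumerate(mol.atoms):
        for _ in range(a.h_count):
            atom_lines.append(
                f"{0.0:10.4f}{0.0:10.4f}{0.0:10.4f} {'H':<3} 0  0  0  0  0  0  0  0  0  0  0  0"
            )
            bond_lines.append(f"{k + 1:>3}{h_index + 1:>3}{1:>3}  0")
            h_index += 1
    lines = [mol.name, "  atomgroups", ""]
    lines.append(f"{len(atom_lines):>3}{len(bond_lines):>3}  0  0  0  0  0  0  0  0999 V2000")
    lines.extend(atom_lines)
    lines.extend(bond_lines)
    for start in range(0, len(charges), 8):
        chunk = charges[start:start + 8]
        line = f"M  CHG{len(chunk):>3}"
        for idx, chg in chunk:
            line += f"{idx:>4}{chg:>4}"
        lines.append(line)
    lines.append("M  END")
    for key, value in mol.props.items():
        lines.append(f">  <{key}>")
        lines.append(str(value))
        lines.append("")
    lines.append("$$$$")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Amidinium / guanidinium / imidazolium normalization
# ---------------------------------------------------------------------------


def normalize_amidinium(mol: MolecularGraph) -> MolecularGraph:
    """Rewrite N-C-N cations into the central-carbon charge convention.

    Any motif where a positively charged nitrogen is double- (or
    aromatically) bonded to a carbon that carries at least two nitrogen
    neighbors is rewritten: the charge moves to the carbon and *all* its
    C-N bonds become aromatic (three of them for guanidinium).  Structures
    already in this convention are returned unchanged; the function is
    idempotent and never changes the molecular formula or net charge.
    """
    atoms = list(mol.atoms)
    bonds = list(mol.bonds)

    def n_neighbors_of(c: int) -> list[int]:
        return [k for k, b in enumerate(bonds)
                if (b.i == c or b.j == c) and atoms[b.other(c)].element == "N"]

    changed = False
    for c, atom in enumerate(atoms):
        if atom.element != "C":
            continue
        nbond_idx = n_neighbors_of(c)
        if len(nbond_idx) < 2:
            continue
        if atom.charge == 1 and all(bonds[k].order == AROMATIC for k in nbond_idx):
            continue  # already normalized
        donor = None
        for k in nbond_idx:
            n_idx = bonds[k].other(c)
            if atoms[n_idx].charge == 1 and bonds[k].order in (DOUBLE, AROMATIC):
                donor = (k, n_idx)
                break
        if donor is None:
            continue
        if atom.charge != 0:
            warnings.warn(
                f"amidinium motif at carbon {c} cannot be rewritten "
                "consistently (central carbon already charged); left unchanged"
            )
            continue
        k, n_idx = donor
        atoms[n_idx] = replace(atoms[n_idx], charge=atoms[n_idx].charge - 1)
        atoms[c] = replace(atoms[c], charge=atom.charge + 1)
        for kb in nbond_idx:
            bonds[kb] = replace(bonds[kb], order=AROMATIC)
        changed = True

    if not changed:
        return mol
    return MolecularGraph(atoms, bonds, name=mol.name, id=mol.id,
                          props=dict(mol.props))
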