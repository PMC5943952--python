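"""Parameter tables: the packaged group-contribution data and its I/O.

Two tables ship with the package, transcribed at two-decimal precision:

* ``log_eta_293K`` — decimal-log liquid viscosity (cP) at 293.15 K;
  126 entries including a fitted constant C = -0.70, no special groups.
* ``log_gamma_inf_298K`` — decimal-log activity coefficient at infinite
  dilution in water at 298.15 K; 116 entries of which three are special
  groups (hydrogen acceptor, alkane and unsaturated-hydrocarbon per-carbon
  terms), constant fixed at 0.

A table entry is *valid* when at least three distinct molecules supported
it during fitting; only molecules composed entirely of valid groups are
predictable.  The packaged ``valid`` flags are derived from the printed
molecules column with that >= 3 rule; the printed "valid groups" headline
counts (76 and 75) are kept as metadata only, since they rest on an
additional independence notion the source does not spell out.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

from .groups import (
    ALKANE_C,
    H_ACCEPTOR,
    SIGNATURE_STRING_RE,
    SPECIAL_KEYS,
    UNSAT_HC_C,
    GroupCountVector,
    GroupSignature,
)

CONST = "CONST"

#: Descriptor identifiers.
LOG_ETA_293K = "log_eta_293K"
LOG_GAMMA_INF_298K = "log_gamma_inf_298K"

_PACKAGED = {
    LOG_ETA_293K: "viscosity_293K",
    LOG_GAMMA_INF_298K: "gamma_inf_298K",
}

#: Printed labels of the non atom-centered rows.
_SPECIAL_LABELS = {
    ("H", "H Acceptor"): H_ACCEPTOR,
    ("Alkane", "No of C atoms"): ALKANE_C,
    ("Unsaturated HC", "No of C atoms"): UNSAT_HC_C,
}
_SPECIAL_PRINT = {v: k for k, v in _SPECIAL_LABELS.items()}

EntryKey = Union[GroupSignature, str]  # signature, special key, or CONST

#: Minimum distinct supporting molecules for a group to be predictive.
MIN_MOLECULES_VALID = 3


@dataclass(frozen=True)
class TableEntry:
    entry: int
    key: EntryKey
    contribution: float
    occurrences: int = 0
    molecules: int = 0
    valid: bool = False

    @property
    def printed_fields(self) -> tuple[str, str]:
        if self.key == CONST:
            return ("Const", "")
        if isinstance(self.key, str):
            return _SPECIAL_PRINT[self.key]
        return (self.key.atom_type, self.key.neighbors)


class TableIntegrityError(RuntimeError):
    """Packaged data file does not match its recorded checksum."""


@dataclass
class ParameterTable:
    """Ordered group contributions plus the constant of one descriptor."""

    descriptor: str
    entries: list[TableEntry]
    constant: float = 0.0
    uses_constant: bool = False
    uses_special_groups: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index: dict[EntryKey, TableEntry] = {}
        for e in self.entries:
            if e.key == CONST:
                continue
            if e.key in self._index:
                raise ValueError(
                    f"duplicate signature {e.key} at entries "
                    f"{self._index[e.key].entry} and {e.entry}"
                )
            self._index[e.key] = e

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, key: EntryKey) -> TableEntry | None:
        return self._index.get(key)

    def __contains__(self, key: EntryKey) -> bool:
        return key in self._index

    @property
    def atom_group_entries(self) -> list[TableEntry]:
        return [e for e in self.entries if isinstance(e.key, GroupSignature)]

    @property
    def special_entries(self) -> list[TableEntry]:
        return [e for e in self.entries if isinstance(e.key, str) and e.key != CONST]

    def audit_signatures(self) -> list[TableEntry]:
        """Entries whose neighbor string the grammar could not emit."""
        bad = []
        for e in self.atom_group_entries:
            if not SIGNATURE_STRING_RE.match(e.key.neighbors):
                bad.append(e)
        return bad


def _entry_from_row(row: dict[str, str]) -> TableEntry:
    atom_type = row["atom_type"].strip()
    neighbors = row["neighbors"].strip()
    if atom_type == "Const":
        key: EntryKey = CONST
    elif (atom_type, neighbors) in _SPECIAL_LABELS:
        key = _SPECIAL_LABELS[(atom_type, neighbors)]
    else:
        key = GroupSignature(atom_type, neighbors)
    return TableEntry(
        entry=int(row["entry"]),
        key=key,
        contribution=float(row["contribution"]),
        occurrences=int(row["occurrences"]),
        molecules=int(row["molecules"]),
        valid=bool(int(row["valid"])),
    )


def _build(descriptor: str, entries: list[TableEntry], metadata: dict) -> ParameterTable:
    const_entries = [e for e in entries if e.key == CONST]
    uses_constant = bool(const_entries)
    constant = const_entries[0].contribution if const_entries else 0.0
    uses_special = any(
        isinstance(e.key, str) and e.key != CONST for e in entries
    )
    numbers = [e.entry for e in entries]
    if numbers != sorted(numbers) or len(set(numbers)) != len(numbers):
        raise ValueError("entry numbers must be unique and ascending")
    return ParameterTable(
        descriptor=descriptor,
        entries=entries,
        constant=constant,
        uses_constant=uses_constant,
        uses_special_groups=uses_special,
        metadata=metadata,
    )


def load_packaged(descriptor: str) -> ParameterTable:
    """Load one of the two packaged tables, verifying file checksums."""
    if descriptor not in _PACKAGED:
        raise KeyError(
            f"unknown descriptor {descriptor!r}; "
            f"expected one of {sorted(_PACKAGED)}"
        )
    stem = _PACKAGED[descriptor]
    data = resources.files("atomgroups") / "data"
    sums = json.loads((data / "checksums.json").read_text())
    entries_bytes = (data / f"{stem}.csv").read_bytes()
    meta_bytes = (data / f"{stem}.meta.json").read_bytes()
    for fname, blob in ((f"{stem}.csv", entries_bytes), (f"{stem}.meta.json", meta_bytes)):
        digest = hashlib.sha256(blob).hexdigest()
        if digest != sums[fname]:
            raise TableIntegrityError(
                f"packaged file {fname} checksum mismatch "
                f"(expected {sums[fname]}, got {digest})"
            )
    rows = list(csv.DictReader(entries_bytes.decode().splitlines()))
    entries = [_entry_from_row(r) for r in rows]
    metadata = json.loads(meta_bytes.decode())
    return _build(descriptor, entries, metadata)


_COLUMNS = ["entry", "atom_type", "neighbors", "contribution",
            "occurrences", "molecules", "valid"]


def write_table(table: ParameterTable, path: str | Path) -> None:
    """Write a table as CSV (lossless round trip with :func:`read_table`)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for e in table.entries:
            atom_type, neighbors = e.printed_fields
            writer.writerow(
                [e.entry, atom_type, neighbors, f"{e.contribution:.2f}",
                 e.occurrences, e.molecules, int(e.valid)]
            )


def read_table(path: str | Path, descriptor: str = "",
               metadata: dict | None = None) -> ParameterTable:
    """Read a table from the CSV dialect written by :func:`write_table`."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"table CSV missing columns: {sorted(missing)}")
        entries = [_entry_from_row(row) for row in reader]
    return _build(descriptor or str(path), entries, metadata or {})


def molecules_per_group(
    count_vectors: Iterable[GroupCountVector],
) -> dict[EntryKey, int]:
    """Number of distinct molecules containing each group (or special)."""
    support: dict[EntryKey, int] = {}
    for cv in count_vectors:
        for sig in cv.counts:
            support[sig] = support.get(sig, 0) + 1
        for key, c in cv.special_counts.items():
            if c:
                support[key] = support.get(key, 0) + 1
    return support


def recompute_validity(
    table: ParameterTable, count_vectors: Iterable[GroupCountVector]
) -> ParameterTable:
    """Re-derive valid flags from a dataset with the >= 3 molecules rule."""
    support = molecules_per_group(count_vectors)
    entries = []
    for e in table.entries:
        if e.key == CONST:
            entries.append(e)
            continue
        n = support.get(e.key, 0)
        entries.append(replace(e, molecules=n, valid=n >= MIN_MOLECULES_VALID))
    return _build(table.descriptor, entries, dict(table.metadata))
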