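"""Descriptor prediction: evaluate the additive model against a table.

The predicted value is ``Y = sum_i a_i A_i + sum_j b_j B_j + C`` where the
``A_i`` are atom-group counts, the ``B_j`` special-group counts (used only
by tables that carry special groups) and ``C`` the table constant.
Prediction is gated: every group of the molecule must be present in the
table *and* valid (supported by >= 3 training molecules); otherwise a
structured ineligible verdict is returned, never a numeric guess.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .groups import GroupCountVector, GroupSignature, perceive
from .molgraph import MolecularGraph, validate_elements
from .tables import CONST, EntryKey, ParameterTable


@dataclass
class Prediction:
    descriptor: str
    compound_id: str = ""
    value: float | None = None
    eligible: bool = False
    missing: list[EntryKey] = field(default_factory=list)
    invalid: list[EntryKey] = field(default_factory=list)
    breakdown: list[tuple[EntryKey, int, float, float]] = field(default_factory=list)

    @property
    def linear_value(self) -> float | None:
        """Back-transform from decimal log (e.g., eta in cP)."""
        return None if self.value is None else 10.0 ** self.value


def check_eligibility(
    counts: GroupCountVector, table: ParameterTable
) -> tuple[list[EntryKey], list[EntryKey]]:
    """Split a molecule's groups into (missing from table, present but invalid)."""
    missing: list[EntryKey] = []
    invalid: list[EntryKey] = []
    keys: list[EntryKey] = list(counts.counts)
    if table.uses_special_groups:
        keys += [k for k, c in counts.special_counts.items() if c]
    for key in keys:
        entry = table.get(key)
        if entry is None:
            missing.append(key)
        elif not entry.valid:
            invalid.append(key)
    return missing, invalid


def predict(
    mol_or_counts: MolecularGraph | GroupCountVector,
    table: ParameterTable,
    *,
    h_acceptor: bool = False,
) -> Prediction:
    """Predict the table's descriptor for a molecule or count vector.

    ``h_acceptor`` enables the intramolecular hydrogen-bond detector
    during perception (off by default).
    """
    compound_id = ""
    if isinstance(mol_or_counts, MolecularGraph):
        compound_id = mol_or_counts.id
        verdict = validate_elements(mol_or_counts)
        if not verdict.eligible:
            return Prediction(
                descriptor=table.descriptor,
                compound_id=compound_id,
                missing=[
                    GroupSignature(el, "element not supported")
                    for el in verdict.offending_elements
                ],
            )
        counts = perceive(mol_or_counts, h_acceptor=h_acceptor)
    else:
        counts = mol_or_counts

    missing, invalid = check_eligibility(counts, table)
    if missing or invalid:
        return Prediction(
            descriptor=table.descriptor,
            compound_id=compound_id,
            missing=missing,
            invalid=invalid,
        )

    breakdown: list[tuple[EntryKey, int, float, float]] = []
    total = 0.0
    for sig, count in counts.counts.items():
        contrib = table.get(sig).contribution
        breakdown.append((sig, count, contrib, count * contrib))
        total += count * contrib
    if table.uses_special_groups:
        for key, count in counts.special_counts.items():
            if not count:
                continue
            contrib = table.get(key).contribution
            breakdown.append((key, count, contrib, count * contrib))
            total += count * contrib
    if table.uses_constant:
        breakdown.append((CONST, 1, table.constant, table.constant))
        total += table.constant

    return Prediction(
        descriptor=table.descriptor,
        compound_id=compound_id,
        value=total,
        eligible=True,
        breakdown=breakdown,
    )
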