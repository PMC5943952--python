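"""Synthetic data and reference fixtures.

Two kinds of test substrate live here:

* :func:`make_design` generates sparse non-negative integer count
  matrices with known contribution vectors and homoscedastic Gaussian
  noise — the exact statistical structure the additive model assumes —
  so the fitting, cross-validation and outlier machinery can be checked
  against ground truth.
* :func:`fixture_molecules` returns a frozen set of small molecules and
  ions with hand-derived group decompositions.  These fixtures are the
  de facto specification of the grammar's edge cases (ionic-liquid
  moieties, pi counting, net-charge suffixes, special hydrocarbon
  groups) and guard the perception code against regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fit import TrainingCompound, TrainingSet
from .groups import ALKANE_C, H_ACCEPTOR, UNSAT_HC_C, GroupCountVector, GroupSignature
from .molgraph import MolecularGraph, read_smiles


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings for a synthetic group-count regression problem.

    Defaults mirror the scale of the packaged problems: a few hundred
    compounds over a few dozen groups, counts 0-4 with sparse occupancy,
    contributions of order one and measurement noise of 0.10 log units
    (the cross-validated standard error of the viscosity model).
    """

    n_compounds: int = 500
    n_groups: int = 40
    occupancy: float = 0.25
    max_count: int = 4
    contribution_low: float = -1.0
    contribution_high: float = 1.0
    constant: float = 0.0
    noise_sigma: float = 0.10
    seed: int = 20171221

    def __post_init__(self) -> None:
        if self.n_compounds <= 0 or self.n_groups <= 0:
            raise ValueError("sizes must be positive")
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError("occupancy must be in (0, 1]")
        if self.max_count < 1:
            raise ValueError("max_count must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def make_design(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate ``(X, a_true, y)`` with ``y = X a_true + C + N(0, sigma)``.

    Every column is guaranteed to be nonzero (empty groups are resampled),
    so each parameter has supporting data.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    X = np.zeros((spec.n_compounds, spec.n_groups), dtype=int)
    occupied = rng.random((spec.n_compounds, spec.n_groups)) < spec.occupancy
    X[occupied] = rng.integers(1, spec.max_count + 1, size=int(occupied.sum()))
    for i in range(spec.n_compounds):
        # a molecule always contains at least one group center
        if not X[i].any():
            X[i, rng.integers(spec.n_groups)] = rng.integers(1, spec.max_count + 1)
    for j in range(spec.n_groups):
        while not X[:, j].any():
            rows = rng.random(spec.n_compounds) < max(spec.occupancy, 1.0 / spec.n_compounds)
            if not rows.any():
                continue
            X[rows, j] = rng.integers(1, spec.max_count + 1, size=int(rows.sum()))
    a_true = rng.uniform(spec.contribution_low, spec.contribution_high, spec.n_groups)
    y = X @ a_true + spec.constant
    if spec.noise_sigma > 0:
        y = y + rng.normal(0.0, spec.noise_sigma, spec.n_compounds)
    return X, a_true, y


def training_set(spec: SyntheticSpec) -> tuple[TrainingSet, np.ndarray]:
    """Wrap :func:`make_design` output as a :class:`TrainingSet`.

    Synthetic groups get placeholder signatures ``("G<j>", "")``.
    """
    X, a_true, y = make_design(spec)
    sigs = [GroupSignature(f"G{j}", "") for j in range(spec.n_groups)]
    compounds = []
    for i in range(spec.n_compounds):
        counts = {sigs[j]: int(X[i, j]) for j in range(spec.n_groups) if X[i, j]}
        compounds.append(
            TrainingCompound(id=f"cmpd{i:04d}", counts=GroupCountVector(counts),
                             value=float(y[i]))
        )
    return TrainingSet(compounds), a_true


@dataclass(frozen=True)
class FixtureMolecule:
    name: str
    smiles: str
    expected: GroupCountVector
    molecule: MolecularGraph = field(compare=False, hash=False, default=None)


def _cv(groups: dict[tuple[str, str], int],
        alkane: int = 0, unsat: int = 0, h_acc: int = 0) -> GroupCountVector:
    return GroupCountVector(
        counts={GroupSignature(*k): v for k, v in groups.items()},
        special_counts={ALKANE_C: alkane, UNSAT_HC_C: unsat, H_ACCEPTOR: h_acc},
    )


#: Hand-derived reference decompositions.  The first nine are the
#: ionic-liquid moieties whose printed signatures anchor the grammar.
_FIXTURES: list[tuple[str, str, GroupCountVector]] = [
    ("tetrafluoroborate", "F[B-](F)(F)F",
     _cv({("B(-)", "F4"): 1})),
    ("pyridinium", "[nH+]1ccccc1",
     _cv({("N(+) aromatic", "H:C2"): 1,
          ("C aromatic", "H:C:N(+)"): 2,
          ("C aromatic", "H:C2"): 3})),
    ("2-methylimidazolium", "Cc1[nH+]cc[nH]1",
     _cv({("C sp3", "H3C(+)"): 1,
          ("C(+) aromatic", "C:N2"): 1,
          ("N aromatic", "HC:C(+)"): 2,
          ("C sp2", "H=CN"): 2})),
    ("1-methylimidazolium", "Cn1cc[nH+]c1",
     _cv({("C sp3", "H3N"): 1,
          ("N aromatic", "C2:C(+)"): 1,
          ("C(+) aromatic", "H:N2"): 1,
          ("N aromatic", "HC:C(+)"): 1,
          ("C sp2", "H=CN"): 2})),
    ("1-methylpyridinium", "C[n+]1ccccc1",
     _cv({("C sp3", "H3N(+)"): 1,
          ("N(+) aromatic", "C:C2"): 1,
          ("C aromatic", "H:C:N(+)"): 2,
          ("C aromatic", "H:C2"): 3})),
    ("bis(trifluoromethanesulfonyl)amide", "FC(F)(F)S(=O)(=O)[N-]S(=O)(=O)C(F)(F)F",
     _cv({("C sp3", "SF3"): 2,
          ("S4", "CN=O2(-)"): 2,
          ("N(-)", "S2"): 1})),
    ("tetramethylphosphonium", "C[P+](C)(C)C",
     _cv({("C sp3", "H3P(+)"): 4,
          ("P(+)", "C4"): 1})),
    ("hexafluorophosphate", "F[P-](F)(F)(F)(F)F",
     _cv({("P(-)", "F6"): 1})),
    ("methylsulfonate", "CS(=O)(=O)[O-]",
     _cv({("C sp3", "H3S"): 1,
          ("S4", "CO=O2(-)"): 1})),
    ("methanol", "CO",
     _cv({("C sp3", "H3O"): 1, ("O", "HC"): 1})),
    ("ethanol", "CCO",
     _cv({("C sp3", "H3C"): 1, ("C sp3", "H2CO"): 1, ("O", "HC"): 1})),
    ("n-hexane", "CCCCCC",
     _cv({("C sp3", "H3C"): 2, ("C sp3", "H2C2"): 4}, alkane=6)),
    ("benzene", "c1ccccc1",
     _cv({("C aromatic", "H:C2"): 6}, unsat=6)),
    ("toluene", "Cc1ccccc1",
     _cv({("C sp3", "H3C"): 1,
          ("C aromatic", "C:C2"): 1,
          ("C aromatic", "H:C2"): 5}, unsat=7)),
    ("acetic acid", "CC(=O)O",
     _cv({("C sp3", "H3C"): 1, ("C sp2", "CO=O"): 1, ("O", "HC(pi)"): 1})),
    ("phenol", "Oc1ccccc1",
     _cv({("O", "HC(pi)"): 1,
          ("C aromatic", ":C2O"): 1,
          ("C aromatic", "H:C2"): 5})),
    ("methyl acetate", "COC(C)=O",
     _cv({("C sp3", "H3O"): 1, ("O", "C2(pi)"): 1,
          ("C sp2", "CO=O"): 1, ("C sp3", "H3C"): 1})),
    ("nitromethane", "C[N+](=O)[O-]",
     _cv({("C sp3", "H3N(+)"): 1, ("N(+) sp2", "CO=O(-)"): 1})),
    ("diphenyl ether", "O(c1ccccc1)c1ccccc1",
     _cv({("O", "C2(2pi)"): 1,
          ("C aromatic", ":C2O"): 2,
          ("C aromatic", "H:C2"): 10})),
]


def fixture_molecules() -> list[FixtureMolecule]:
    """Molecules with frozen hand-derived group decompositions."""
    out = []
    for name, smiles, expected in _FIXTURES:
        mol = read_smiles(smiles, name)
        out.append(FixtureMolecule(name=name, smiles=smiles,
                                   expected=expected, molecule=mol))
    return out
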