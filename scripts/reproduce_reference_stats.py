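#!/usr/bin/env python
"""Recompute the full training/cross-validation statistics for one
descriptor from an experimental compound collection.

The packaged parameter tables were fitted on several hundred compounds
with experimental log(eta) at 293.15 K or log(gamma)inf at 298.15 K.
Those compound collections are not shipped with this package; when you
have them (an SDF of structures plus a CSV of ``id,value`` experimental
data), this script runs the complete pipeline — perception, Gauss-Seidel
fit with three-sigma outlier exclusion, and ten-fold cross-validation —
and prints N, R^2, Q^2 and the deviation statistics.

Usage:
    python scripts/reproduce_reference_stats.py \
        --sdf compounds.sdf --values values.csv --descriptor visc
"""

from __future__ import annotations

import argparse
import csv
import sys
from pathlib import Path

from atomgroups.crossval import cross_validate
from atomgroups.fit import TrainingCompound, TrainingSet, fit_with_outlier_removal
from atomgroups.groups import perceive
from atomgroups.molgraph import read_sdf, validate_elements
from atomgroups.tables import LOG_ETA_293K, LOG_GAMMA_INF_298K

DESCRIPTORS = {
    "visc": (LOG_ETA_293K, True, False),
    "gamma": (LOG_GAMMA_INF_298K, False, True),
}


def main(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    parser.add_argument("--sdf", required=True,
                        help="SDF with the experimental compound structures")
    parser.add_argument("--values", required=True,
                        help="CSV with columns id,value (experimental data)")
    parser.add_argument("--descriptor", required=True, choices=sorted(DESCRIPTORS))
    parser.add_argument("--k", type=int, default=10)
    parser.add_argument("--seed", type=int, default=20171221)
    parser.add_argument("--id-property", default=None,
                        help="SDF property holding the compound id "
                             "(default: title line)")
    args = parser.parse_args(argv)

    for path in (args.sdf, args.values):
        if not Path(path).exists():
            print(f"error: input file not found: {path}", file=sys.stderr)
            return 2

    descriptor, uses_constant, uses_special = DESCRIPTORS[args.descriptor]
    with open(args.values, newline="") as fh:
        values = {row["id"]: float(row["value"]) for row in csv.DictReader(fh)}

    result = read_sdf(args.sdf, id_property=args.id_property)
    for err in result.errors:
        print(f"warning: {err.message}", file=sys.stderr)

    compounds = []
    for mol in result:
        if mol.id not in values:
            continue
        verdict = validate_elements(mol)
        if not verdict.eligible:
            print(f"warning: {mol.id}: unsupported elements "
                  f"{verdict.offending_elements}", file=sys.stderr)
            continue
        compounds.append(
            TrainingCompound(mol.id, perceive(mol, h_acceptor=uses_special),
                             values[mol.id])
        )
    if not compounds:
        print("error: no compounds with both structure and value", file=sys.stderr)
        return 2

    training = TrainingSet(compounds)
    fit_result = fit_with_outlier_removal(
        training, descriptor=descriptor, uses_constant=uses_constant,
        uses_special=uses_special, k=args.k, seed=args.seed,
    )
    kept = training.drop(cid for cid, *_ in fit_result.outliers)
    cv = cross_validate(
        kept, k=args.k, seed=args.seed,
        uses_constant=uses_constant, uses_special=uses_special,
    )

    print(f"descriptor          : {descriptor}")
    print(f"compounds (input)   : {len(training)}")
    print(f"outliers excluded   : {len(fit_result.outliers)}")
    print(f"N (training fit)    : {fit_result.n_used}")
    print(f"R^2                 : {fit_result.statistics.r2:.4f}")
    print(f"avg deviation       : {fit_result.statistics.avg_dev:.2f}")
    print(f"std deviation       : {fit_result.statistics.std_dev:.2f}")
    print(f"N (cv predictable)  : {cv.n_predictable}")
    print(f"Q^2                 : {cv.q2:.4f}" if cv.q2 is not None else "Q^2: n/a")
    if cv.avg_dev is not None:
        print(f"cv avg deviation    : {cv.avg_dev:.2f}")
        print(f"cv std deviation    : {cv.std_dev:.2f}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
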