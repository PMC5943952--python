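# Methods

This note documents the modeling conventions behind `atomgroups`: what is
computed, which choices were genuinely open, and what the tests do and do
not demonstrate.

## The additive model

Both descriptors are linear in group counts:

    Y = Σᵢ aᵢ·Aᵢ + Σⱼ bⱼ·Bⱼ + C

with *Y* either log₁₀ of the liquid viscosity coefficient in cP at
293.15 K or log₁₀ of the activity coefficient at infinite dilution in
water at 298.15 K.  Both tables are single-temperature; no temperature
extrapolation is attempted.  The viscosity model uses a fitted constant
(C = −0.70) and no special groups; the activity-coefficient model fixes
C = 0 and adds three special groups (per-carbon alkane and
unsaturated-hydrocarbon terms for pure hydrocarbons, and an intramolecular
hydrogen-bond term).  Predicted values are log units; `Prediction.linear_value`
back-transforms with 10^Y.

## Group centers

Every heavy, non-halogen atom with at least two connections (hydrogens
count as connections) is a group center.  This excludes terminal
multiply-bonded atoms — carbonyl, sulfonyl, phosphoryl and nitro/
carboxylate oxygens and nitrile nitrogens — which appear only inside the
neighbor string of the atom they hang from.  The packaged tables force
this reading: they contain ketone (`C sp2 C2=O`), nitrile (`C sp C#N`)
and nitro (`N(+) sp2 CO=O(-)`) center rows but no corresponding rows for
a doubly-bonded oxygen or a triply-bonded nitrogen center, even though
molecules of those classes were fitted and are predictable.  Halogens and
hydrogens are never centers.

## Atom typing

Type = element + charge marker + unsaturation class, read from the bond
pattern, never from geometry: any aromatic bond → `aromatic`; a triple
bond or two doubles → `sp`; one double → `sp2`; otherwise `sp3`.
Divalent sulfur is `S2`, hypervalent (sulfoxide/sulfone/sulfonate) `S4`;
tetracoordinate neutral phosphorus is `P4`, charged phosphorus `P(+)`/
`P(-)`; oxygen is a single class `O` (its context lives in the neighbor
string); boron and silicon are `B`/`Si` with charge markers.  Negatively
charged nitrogen is written plain `N(-)` without a hybridization word,
matching the table vocabulary.

## Neighbor strings

Deterministic construction: hydrogens first (`H`, `H2`, `H3`), then one
token per heavy neighbor — bond marker ('' single, `=` double, `#`
triple, `:` aromatic) plus element symbol, iodine written `J` — with
identical tokens aggregated by a trailing count.  Tokens sort
element-major (B, C, N, O, P, S, Si, F, Cl, Br, J), then by bond marker
('' < `=` < `#` < `:`).  This ordering reproduces the printed strings
`C:C2`, `:C2N`, `:C2O`, `CN=O`, `CO=O`, `H:C:N(+)`; a marker-major order
would not.

**Charges.**  The net formal charge of the neighbor shell, when nonzero,
is appended once at the end (`(+)`/`(-)`).  This is deliberately a
*shell* property, not a per-token marker: a nitro nitrogen reads
`CO=O(-)` whichever oxygen carries the drawn charge, and the same rule
generates the sulfonate `CO=O2(-)`, the perfluoroalkylphosphate carbon
`CPF2(-)` and the `CN=O(+)` row without any exception list.  Every
signature string in both packaged tables is generatable by the grammar
(`ParameterTable.audit_signatures()` verifies this).

**Pi counts.**  For the saturated center types `N sp3`, `O` and `S2` the
per-neighbor annotation is replaced by a trailing `(pi)`/`(2pi)` counting
neighbors that are aromatic or are C/N atoms engaged in a multiple bond.
A carbonyl carbon therefore counts as pi (ester oxygen `C2(pi)`), while
hypervalent S=O or P=O neighbors do not (sulfonamide nitrogen `HCS(pi)`
carries one pi from its aryl carbon only, alkyl-phosphate oxygen is plain
`CP`).  The element restriction to C/N is the only reading consistent
with the sulfonamide and phosphate rows coexisting with the ester rows.

## Aromaticity

The MDL aromaticity model is applied after parsing: six-membered
benzenoid rings (benzene, pyridine, pyridinium, fused carbocycles) are
aromatic; five-membered heteroaromatics (pyrrole, furan, thiophene,
imidazole) are kept as Kekulé structures.  The table vocabulary demands
exactly this split — azole and furan/thiophene carbons appear as
`C sp2 H=CN` / `H=CO` / `H=CS` and the pyrrole nitrogen as
`N sp3 HC2(2pi)`, alongside genuinely aromatic `C aromatic` rows.  The
perceived flags are then frozen; the packaged fixture decompositions
define the reference behavior.

## Amidinium convention

N–C–N cations (imidazolium, amidinium, guanidinium) are stored with the
positive charge on the central carbon and *all* of that carbon's C–N
bonds aromatic, reflecting the delocalized charge distribution of these
ions; the rest of a five-membered ring keeps its Kekulé bonds.  This
makes, e.g., the N1 of 1-methylimidazolium read `N aromatic C2:C(+)`
(one aromatic bond to the charged C2, single bonds to methyl and C5).
Normalization runs automatically on input (disable with
`normalize=False`), is idempotent, and never changes formula or net
charge.  A charged nitrogen whose candidate central carbon is already
charged is left unchanged with a warning.

## Structure input

RDKit parses SMILES and V2000 SDF; the package then works on its own
heavy-atom graph with hydrogen counts (hydrogens are never graph nodes).
Multi-fragment records — ionic liquids stored as one cation + anion
record — are perceived jointly into a single count vector, since one
record carries one experimental value.  SDF records with explicit
aromatic (order 4) bonds are read verbatim by a minimal literal V2000
parser and must carry explicit hydrogens; this is the format `write_sdf`
emits, and it round-trips normalized amidinium structures whose aromatic
bonds fall outside any kekulizable ring.  Standard Kekulé SDF goes
through RDKit with MDL re-perception.  Unreadable records yield
per-record errors without losing the rest of the file; out-of-whitelist
elements flag the record ineligible rather than dropping it.

## Validity gating

A table entry is valid when at least three distinct molecules supported
it in fitting; prediction requires every group of a molecule to be
present *and* valid.  The packaged `valid` flags are recomputed from the
printed per-entry molecule counts with this ≥3 rule.  The tables'
headline "valid groups" counts (76 and 75) rest on an additional notion
of *independent* molecules that is not spelled out; they are stored as
metadata only and not re-derived.

## Fitting

Ordinary least squares on the sparse count matrix (column per fitted
group, plus the all-ones constant column when used).  The normal
equations X'X a = X'y are solved by Gauss–Seidel iteration: zero start,
full coordinate sweeps (implemented as the triangular solve
(D+L)·a⁺ = b − U·a), convergence when the largest coordinate change
relative to the largest coordinate magnitude falls below 1e-10, capped
at 1e5 sweeps.  X'X is symmetric positive definite for full-rank
designs, where Gauss–Seidel is guaranteed to converge; tests check
agreement with a direct dense solver to better than 1e-8 on random
well-conditioned systems.  Groups with fewer than three supporting
molecules are still fitted (and retained in the output table for future
use) but flagged invalid for prediction.

Statistics conventions: R² is the squared Pearson correlation of
experimental versus fitted values; "average deviation" is the mean
absolute residual and "standard deviation" the RMS residual.  These are
interpretations — the quantities are reported in the source tables
without formulas.  Degenerate cases: zero variance in y is an error
(R² undefined); constant predictions give R² = 0 by convention.

## Cross-validation and outliers

K-fold (default K = 10) with a seeded shuffle (default seed 20171221;
the fold construction is a free choice and fixing it makes every CV
number reproducible).  Inside each fold the model is refitted on the
complement and validity recomputed *on that complement*: a group whose
support drops below three once carriers move into the test fold renders
its test compounds unpredictable, with the reason recorded.  Q² is the
squared correlation over predictable out-of-fold pairs.  This per-fold
gating is the mechanism by which the number of CV predictions falls
below the number of training predictions on real data.

The outlier loop wraps both: fit → 10-fold CV → σ_cv → exclude
compounds whose training residual exceeds 3·σ_cv → refit, until a pass
excludes nothing (or a cap of 10 rounds, after which the result is
flagged not converged).  CV is rerun inside each pass because the
threshold is defined by the *cross-validated* standard error.  Outlier
exclusion is not rerun inside CV folds — the exclusion loop wraps CV,
not vice versa.

## Synthetic benchmarks

`SyntheticSpec` generates sparse integer count matrices
(y = X·a + C + N(0, σ)) matching the statistical structure the model
assumes: defaults of 500 compounds × 40 groups, counts 0–4 at 25%
occupancy (chosen to mimic the sparsity of real group-count matrices;
every row and column is guaranteed nonzero, as every molecule has at
least one group center), contributions uniform on (−1, 1), noise
σ = 0.10 log units — the cross-validated standard error of the viscosity
model.  These benchmarks validate the estimation machinery (recovery
RMSE < 0.04 at these settings; Q² = 1 on noise-free data); they do not
emulate collinearity between chemically co-occurring groups, heavy-tailed
experimental error, or the group-frequency skew of real compound sets, so
passing them says nothing about prediction accuracy on real chemistry
beyond what the packaged tables' own statistics state.

The molecule fixtures (19 structures with frozen hand-derived
decompositions, including the nine worked ionic-liquid moieties) are the
de facto specification of the grammar's edge cases and guard against
perception regressions.

## Known limitations

* Coverage is bounded by the tables: molecules containing any group that
  is absent or invalid are not predictable (by design).
* Single temperatures only; no mixtures, no concentration dependence.
* No 3D information: stereochemistry, conformation and tautomerism are
  outside the model.
* The hydrogen-bond special group uses a purely topological 5–7-membered
  ring criterion with greedy one-pair-per-atom matching; it was fitted on
  very few molecules and is off by default.
* The full training statistics of the packaged tables can only be
  recomputed with the original experimental compound collections (see
  `scripts/reproduce_reference_stats.py`), which are not distributed
  here.
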