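# Methods

This note records the modeling choices, parameter conventions and known
limitations of the package. Everything quantitative stated here is
computed by the test suite or the acceptance script.

## Activity scale and censoring

Activity is log₁₀ of the minimum effective dosage (MED), so that equal
steps correspond to equal free-energy changes; lower MED = more active.
The training tables are used exactly as published, in µmol/cm²; the
expansion table is in µg/cm² and is never converted (conversion would
need molar masses the source does not apply). Five carboxamides were
measured only at the 25 µmol/cm² assay ceiling: they are flagged
right-censored but retained at face value for the headline fit (the
published model included them); `log_activity` offers `exclude` and
`use-bound` policies for other analyses. Hit-expansion entries printed
as ">2.5" are censored with bound 2.5 and carry no numeric MED.

## Atomic fields

**Charges (Q).** An in-package PEOE (partial equalization of orbital
electronegativity) implementation: explicit hydrogens, electronegativity
χ(q) = a + bq + cq² with the classic element/hybridization parameters,
charge transferred between bonded atoms proportional to Δχ normalized by
the cation electronegativity of the donor, damped by (1/2)ᵏ in cycle k,
8 cycles. It matches RDKit's implementation to <0.02 e across the
training set (cross-checked in tests). Reported charges are the heavy
atom's own charge: folding hydrogen charges onto heavy atoms collapses
alkyl-carbon charges to ≈0 and destroys the sign/ordering structure of
the published per-position charge values, so folding is available but
off by default. The published calibration charges (e.g. terminal methyl
−0.0428) are ~0.65× the standard PEOE magnitudes; no damping value
reproduces all of them simultaneously (the original parameterization is
unpublished), so the package asserts their sign and ordering but not
their magnitude. This is a documented red in the acceptance suite.

**Radii (vdW).** Element lookup (Bondi-style), with environment
overrides so the published anchors hold exactly: any carbon 1.7 Å,
carbonyl oxygen 1.5 Å. Vacancy radius is 0.

**Lipophilicity (Lipo).** An editable environment-keyed table
(`data/field_tables.csv`) reproduces the published anchor values
bit-exactly (CH₃ −0.6327, CH₂ −0.3998, carbinol carbon −0.9463,
carbonyl O −0.173); every other environment falls back to the Crippen
atomic logP contribution. The published table prints the CH₂/CH₃ values
swapped at one position relative to the other three; we treat that as a
row swap. Note the two scales (anchors vs Crippen) have different
conventions, so mixed-occupancy columns are internally inconsistent —
a known limitation discussed under *Why Q² falls short* below.

**Hydrogen bonding (HBa/HBd).** Only four anchor values are published
(CH₂ acceptor −2.0, terminal-alkyne CH 0.3, CH₃ donor −2.0, hydroxyl O
donor 1.2). They are reproduced exactly; polar environments without
published values get small implementation-defined extensions flagged
`extension` in the table; everything else is 0.

**Electronegativity (EN).** Implemented as a Pauling element lookup but
excluded from the default field set, mirroring the published field
selection.

**Vacancies.** Unoccupied supergraph cells are filled with Q = 0,
vdW = 0, Lipo = −0.25, HBa = HBd = 0.

## Supergraph construction

Incremental superposition: molecules are folded one at a time into the
growing MSG by a McGregor-style connected
maximum-common-edge-subgraph backtracking search, exact on small graphs
and budget-capped (300k nodes, logged) with best-found fallback on
large ones. The objective is lexicographic: matched bonds, then matched
environment labels, then matched atoms, then the lowest vertex-id
sequence — fully deterministic. After the fold, every molecule is
re-embedded into the final MSG (fold-time mappings stay valid because
vertices/edges are only appended, so a failed re-embedding cannot break
the build).

Two defaults deviate from the obvious choices because measurement
proved them better:

- **Atom-type matching.** Element-only matching produced
  path-dependent, inconsistent alignments (near-identical molecules
  landing on disjoint vertex sets) and leave-10%-out Q² ≈ 0.31.
  Matching at the level of first-shell environment labels — with ring
  carbons pooled so cyclohexyl can still superimpose on phenyl — yields
  consistent congener placement, |MSG| = 184 for the 71 training
  structures, and Q² ≈ 0.53. Atom-type matching is listed by the
  original method as a construction setting; looser levels remain
  available (`MsgOptions.match_level`).
- **Insertion order.** Descending-size order gave Q² ≈ 0.49; a
  progressive similarity chain (largest molecule first, then repeatedly
  the molecule with highest Morgan-Tanimoto similarity to any inserted
  one) gave Q² ≈ 0.53 and visibly consistent placements, analogous to
  guide-tree ordering in multiple sequence alignment. `seed_order`
  accepts `"size"` and `"given"` as alternatives, and
  `order_sensitivity()` reports the MSG-size spread over shuffled
  orders rather than hiding it.

Bond-order matching is off by default (a single bond may superimpose on
an aromatic or double edge); cyclic↔acyclic mapping is on. Forced
superposition pairs are accepted in the options but unused by default.

## PLS and model selection

NIPALS PLS1 on autoscaled columns (zero-variance columns dropped,
logged); one deflation pass yields the whole nested family of
coefficient vectors, so factor dynamics and cross-validation reuse a
single fit per fold. At full rank PLS equals OLS (asserted against a
normal-equations oracle at 1e-8). Q²ₙ = 1 − PRESS/TSS with TSS around
the full-sample mean; each repeat partitions the data into disjoint
folds of round(n·fraction) so every compound is predicted out-of-fold
exactly once per repeat; defaults are 10% folds, 25 repeats, seed 7,
bit-reproducible. The selected factor count is the smallest k with Q²
within 0.01 of the maximum (the tolerance was fixed a priori; the
published dynamics peak at k = 6, ours plateaus and selects 8 — left
red in the acceptance suite rather than retuned).

Predictions embed a new molecule into the frozen MSG (no extension),
fill unoccupied positions with vacancies, and report the antilog MED
together with the out-of-MSG atom fraction; below a 50% matched-atom
floor the prediction is flagged outside the model domain but still
returned. Contribution maps report −(standardized coefficient),
normalized to unit total absolute impact, so positive = activity-
increasing, matching the published red/blue reading; an all-zero
coefficient vector yields an all-zero map.

## Why the cross-validated Q² falls short

The headline 6-factor fit reaches training R² = 0.959 (published:
0.964) but Q²₁₀% ≈ 0.53 (published: 0.801). We probed every legitimate
lever — match strictness, bond-order matching, cyclic↔acyclic mapping,
insertion order, field subsets, hydrogen folding, per-column vs pooled
field scaling, and Q² as out-of-fold r² instead of 1 − PRESS/TSS —
without exceeding ≈ 0.55. The residual gap is attributable to the
original software's unpublished internally consistent descriptor tables
(its lipophilicity and hydrogen-bond scales, and a charge scheme whose
magnitudes are ~0.65× standard PEOE) and its alignment objective; our
four published anchors plus Crippen/zero fallbacks simply carry less
transferable signal. The corresponding acceptance checks are left red
with this analysis; no tolerance was widened.

## Bioassay simulator

The simulator emulates the arm-in-cage MED protocol: ~500 (±10%)
host-seeking females, 1-minute exposures, ≥5 bites (~1% of the cage)
fail a patch. Defaults: p0 = 0.8 (per-mosquito bite probability on an
untreated patch within the exposure — chosen so an untreated control
reliably draws hundreds of bites, as a valid replicate requires),
ED50 = 0.01 dose units, Hill slope 1.5 (a shallow response typical of
behavioral endpoints), 5 subjects (the study's panel size), lognormal
σ = 0.1 between-subject spread of p0, and a 2-fold dose ladder (the
ladder spacing is not published; 2-fold is the conventional choice and
is exposed in the parameters). The "consecutive pass/fail" stopping
rule is read as: stop when a pass and a fail have occurred at adjacent
ladder doses; the MED is the lowest passing dose. All-fail runs censor
above the ladder; all-pass runs flag the lowest dose as an upper bound.
The closed-form 1%-bite dose ED50·(100·p0 − 1)^(1/hill) inverts the
dose-response exactly and anchors the calibration tests: the mean
staircase MED over 500 simulated subjects sits within one ladder step
of it, and the bias shrinks monotonically as the ladder refines
(2.0 → 1.5 → 1.25-fold).

What a green simulator test does and does not establish: the generator
reproduces the protocol's sampling structure (binomial bites, staircase
quantization, subject averaging, censoring) but not mosquito behavior —
no time-on-patch dynamics, no depletion or knockdown, no inter-day
colony variation. Recovery tests on the congeneric generator establish
that the pipeline can find a linear field signal *expressed in its own
descriptor space*; they cannot validate the descriptor tables against
nature.

## Congeneric series generator

N-ethyl amides `O=C(R1)N(R2)CC` with R1/R2 drawn from fixed substituent
pools (120 combinations). True log MED = intercept − or + declared
weights times the computed field values at the two attachment atoms,
plus Gaussian noise. Defaults: n = 60, noise σ = 0.1 log units
(comparable to inter-subject assay scatter), weights on (R1, Lipo),
(R2, Lipo) and (R2, Q) sized so the structural signal spans ≈ 1.5 log
units — matching the spread of the real congeneric series. Effect-sign
recovery aggregates the model's coefficients over the supergraph
vertices hosting each attachment atom, occupancy-weighted.

## Known limitations

- Expansion-set structures are not machine-readable in the source;
  those records carry no SMILES and cannot be predicted or embedded.
- The descriptor tables are anchored, not complete (see above); Q² of
  the headline model understates the original software's.
- The MCS search is budget-capped; on molecules far larger than the
  training set it may return a suboptimal embedding (logged).
- MED unit systems (µmol/cm² vs µg/cm²) are intentionally never
  interconverted.
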