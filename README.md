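# repelqsar

Topological 2D QSAR and bioassay simulation for mosquito-repellent
discovery, built around the minimum effective dosage (MED) of candidate
repellents against *Aedes aegypti*, the vector of yellow fever, dengue
and chikungunya.

The package is aimed at cheminformaticians and medicinal chemists who
want to (a) model repellency of congeneric series with an interpretable,
alignment-based 2D method, (b) relate docking scores against the
mosquito odorant binding protein OBP1 to measured activity, and (c)
simulate the arm-in-cage staircase bioassay that produces MED values in
the first place.

## The method

**Molecular field topology analysis (MFTA).** A 2D analogue of CoMFA:
instead of aligning conformers in a 3D grid, the hydrogen-suppressed
molecular graphs of a training series are superimposed into a *molecular
supergraph* (MSG) — a union graph into which every training structure
embeds injectively. Each MSG position carries local atomic descriptors
for the molecules that occupy it:

- *Q* — Gasteiger–Marsili (PEOE) partial charge,
- *vdW* — van der Waals radius,
- *Lipo* — atom-additive lipophilicity contribution,
- *HBa*, *HBd* — hydrogen-bond acceptor/donor scores.

Positions a molecule does not occupy are filled with fixed *vacancy*
values (charge 0, radius 0, lipophilicity −0.25). The resulting
compounds × (positions × fields) matrix **X** is autoscaled and related
to activity *y* = log₁₀ MED by PLS regression with *k* latent factors:

    y = ȳ + X' b,    b = W (PᵀW)⁻¹ q        (NIPALS PLS1)

Model quality is tracked as the training R² and the leave-many-out
cross-validation Q²ₙ = 1 − PRESS/TSS (fraction *n* of compounds left out
per round, repeated over random partitions); the selected *k* is the
smallest one whose Q² is within tolerance of the maximum. Interpretation
uses the *field contribution map*: per (position, field) the
standardized coefficient, sign-flipped to activity orientation
(positive = more repellent as the descriptor grows) and normalized to
unit total absolute impact.

**Superposition engine.** Each molecule is embedded into the growing MSG
by a connected maximum-common-edge-subgraph backtracking search with
deterministic tie-breaking (matched bonds, then matched atom-type
labels, then atom count, then lowest vertex-id sequence). Molecules are
inserted along a structural-similarity chain (largest first, then
nearest by Morgan-fingerprint Tanimoto), which keeps congeners on the
same vertices; matching strictness, bond-order matching and
cyclic↔acyclic mapping are configurable.

**Bioassay simulator.** One-minute exposures of a treated patch to
~500 (±10%) host-seeking females; ≥5 bites (~1%) fail a patch. Doses
walk a geometric ladder — down after a pass, up after a fail — until a
pass and a fail occur at adjacent doses; the MED is the lowest passing
dose, averaged over subjects (mean ± SE). Because the failure threshold
is 1% of the cage, the MED estimates the ED99. The per-mosquito bite
probability is log-logistic, `p(d) = p0 / (1 + (d/ED50)^h)`, with the
analytic 1%-bite dose `ED50·(100·p0 − 1)^(1/h)` available in closed
form for calibration checks. A companion generator produces congeneric
amide series with a *known* linear structure–activity signal for
end-to-end recovery tests of the QSAR pipeline.

## Data

The package ships curated fixtures of the published tables: 71 training
compounds (44 carboxamides incl. DEET + 27 assorted alcohols, ethers,
esters, ketones and halogenated compounds; MED in µmol/cm²), a 15-row
docking-score/MED table, and a 23-row hit-expansion evaluation table
(µg/cm²; entries not active at the 2.5 µg/cm² ceiling are censored).
Structures were curated as SMILES from the published IUPAC names; the
expansion compounds' structures were published only graphically and
ship without SMILES.

## Worked example

```sh
$ repelqsar fit --outdir results          # headline model on the packaged data
n=71 |MSG|=184 k=6 R2=0.959 Q2=0.532
```

Read: the 71 training structures superimpose into a 184-position
supergraph; the 6-factor PLS model explains 95.9% of the variance of
log MED in training and predicts 53.2% out-of-fold under repeated
leave-10%-out. (The study this reimplements reports R² = 0.964 and
Q²₁₀% = 0.801 for its 6-factor model; our training fit matches, while
the cross-validated predictivity is lower — see `docs/methods.md` for
why.) The run writes `model.json`, `msg.json`/`msg.graphml`,
`dynamics.csv`, `contributions.csv` and `fitted.csv`.

```sh
$ repelqsar corr
subset (n=7): r=0.922   full (n=15): r=-0.062
  id  score  med_obs  score_rank  activity_rank  concordant
YF24 -8.491    0.039           2              1        True
YF19 -8.363    0.065           4              2        True
...
```

Over the seven most active compounds, raw MED and docking score
correlate at r = 0.922 — the compound with the second-best score
(2-phenylcyclohexanol, YF24) is the most active — while over all 15
compounds the correlation vanishes (r = −0.06): strong OBP1 binding is
compatible with repellency but does not guarantee it.

```sh
$ repelqsar simulate
n=60 noise=0.1 R2=0.970 Q2=0.927 sign-agreement=100%
```

A synthetic 60-amide series with declared field effects and noise
σ = 0.1 log units is generated, refit from scratch, and recovered:
Q² = 0.93 and every declared (position, field) effect keeps its true
sign.

Predictions for new molecules (`repelqsar predict new.smi --model-dir
results`) return the MED on the dosage scale plus an out-of-supergraph
atom fraction as an applicability diagnostic.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
rebuilds the whole pipeline from the packaged tables — parse, fields,
supergraph, descriptor matrix, 6-factor PLS — and writes the training R²
of the headline model (with the sample size) as JSON. The build is
deterministic; the seed covers any stochastic stage.
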