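# Methods

## Model

The scoring model treats the DnaK substrate-binding cleft as five independent
sites (−2, −1, 0, +1, +2) contacting five consecutive substrate residues in
an extended, conserved backbone conformation.  A window's score is a linear
combination of per-site, per-residue interaction energies:

    E(five-mer) = w_cp · E_cp + E_reverse + Σ_s w_s Σ_t w_t · E[s, t, res(s)]

The basis set `E[s, t, res]` holds six terms per cell, in kcal/mol,
referenced to an all-glycine substrate: van der Waals, electrostatics,
backbone strain, desolvation of the substrate side chain, desolvation of the
binding site, and side-chain rotamer propensity.  This package does not run
the molecular simulations that produce such a basis set; it implements the
closed-form term formulas, the trajectory aggregation rules that turn
per-frame records into matrix cells, and everything downstream (combination,
scanning, training, evaluation).

Key modelling assumptions inherited with the linear form:

- sites contribute independently — no substrate-internal coupling;
- residues beyond the central five are disregarded;
- the same basis set describes both orientations: a reverse-bound window is
  scored by threading it C→N through the same sites, plus a single scalar
  `E_reverse` (0 in the default weight set);
- lower scores mean stronger binding; the score scale is anchored in
  kcal/mol by the physical terms but is only semi-quantitatively comparable
  to binding free energies.

## Energy-term formulas

- Desolvation: `E_desolv = −(ΔSASA_bind / SASA_total) · ΔG_chx→wat` — the
  burial fraction of the side-chain surface times its cyclohexane→water
  transfer free energy.  Positive ΔG (hydrophobic side chains) makes burial
  favorable.  The site-side desolvation term uses the same formula on the
  complementary surface change of the pocket; the backbone's transfer free
  energy is approximated by asparagine's.  Known artifact reproduced, not
  corrected: arginine and lysine are treated as whole side chains, so burial
  of their aliphatic stems is penalized with the full (very hydrophilic)
  head-group transfer free energy, which over-penalizes R in buried sites.
- Side-chain rotamer propensity: `E_r = −kT ln(P_r / P_0)` with kT fixed at
  0.6 kcal/mol; `P_r` is the bound (lowest-energy) rotamer's probability and
  `P_0` the highest rotamer probability in the β-strand backbone basin, so
  `E_r ≥ 0` and is 0 when the bound rotamer is the most probable one.
- Backbone coil propensity: `E_cp` = mean of (1 − helical propensity) over
  the window's five residues (dimensionless, in [0, 1]); it enters at
  scoring time scaled by `w_cp` and is not folded into the PSSM so a nonzero
  `w_cp` remains trainable.
- Trajectory aggregation: per-term means and SEMs are computed over the
  trailing `ceil((1 − d) · n)` frames with discard fraction d = 2/5 by
  default (the first 2/5 of each run treated as equilibration).  SEM is the
  sample standard deviation over retained frames divided by √n, with no
  autocorrelation correction.  Across replicate runs started from different
  rotamers, the run with the lowest trailing-mean total potential energy is
  selected (ties to the lowest index).  Backbone strain is the aggregated
  restraint energy minus the all-glycine reference mean.

## Configuration tables

The formulas need three residue tables, shipped as editable YAML under
`src/paladin/data/`:

- **Solvation scale** (`solvation_chx_water.yaml`): cyclohexane→water
  side-chain-analog transfer free energies of Radzicka & Wolfenden (1988),
  kcal/mol.  Proline has no measured analog there; it is set to +1.8
  (aliphatic content comparable to alanine/valine).  Swap in another scale by
  editing the file or loading your own through
  `paladin.iodata.read_solvation_scale`.
- **Helical propensity** (`propensity_scales.yaml`): the Pace & Scholtz
  (1998) helix-propensity free energies mapped to [0, 1] as
  `helical = max(0, 1 − ΔΔG / 1 kcal·mol⁻¹)`, which puts alanine at 1 and
  glycine/proline at 0.  Any map to [0, 1] works; only differences of means
  over windows enter the model, scaled by the trainable `w_cp`.
- **Rotamer probabilities**: coarse approximate `(P_r, P_0)` pairs in the
  spirit of backbone-dependent rotamer statistics; alanine and glycine have a
  single state (`P_r = P_0 = 1`, zero cost).  These are deliberately
  low-precision: the side-chain propensity weight is zero in the default
  model, so the table only feeds the generic formula and the synthetic
  generator.

## Default weights

`default_weights()` returns the published set: vdW 0.1, electrostatics 0.6,
desolvation of the substrate side chain 1.0, desolvation of the site 0.4,
strain and both propensity weights 0; site weights 0.5, 0.5, 1.0, 0.2, 0.1
for sites −2 … +2; reverse penalty 0 kcal/mol.  Site weights encode the
qualitative picture — the central pocket dominates, the N-terminal-side sites
matter more than the C-terminal-side ones — and are folded into the combined
PSSM (`combine_terms`), so scoring never re-applies them.  Loading a
pre-combined matrix is therefore equivalent to combining a raw basis set.

## Scanning rules

- Sequences are uppercased; `*` and whitespace are stripped.  Windows
  containing any non-standard letter are skipped with a logged warning and
  excluded from the per-orientation bests; the rest of the sequence is still
  scanned.  Sequences shorter than five residues are rejected.
- Register prediction returns the minimum-score window of an orientation;
  exact ties resolve to the smallest start offset, forward before reverse,
  and are logged.
- Orientation calls use Δ = min(forward) − min(reverse) and the fixed
  ambiguity threshold kT = 0.6 kcal/mol; |Δ| ≤ kT is reported "ambiguous".
  The threshold applies only to orientation calls, never to register calls.
- Peptide-array scoring of a 13-mer is the forward-only minimum over its
  nine windows (array data carry no orientation information).
- The reverse-candidate screen keeps sequences with
  min(reverse) − min(forward) < −3 kcal/mol by default, ranked by that gap.
- Predicted arrays can be min-max normalized to [0, 1] intensities with
  clamping thresholds −10 (→ 1) and −6 (→ 0) kcal/mol.

## Training

`PeptideArrayModel.fit()` maximizes
`Z = 4·z(sb,nb) + 2·z(bi,nb) + z(bi,sb) + ½·z(nu,nb)` where each
`z = (μ₁ − μ₂)/sqrt((σ₁² + σ₂²)/2)` over per-class 13-mer scores.  Because
better binders score lower, z-scores are computed on negated scores, making
"larger Z = better separation" well defined.  Degenerate zero-variance
components saturate at ±10 with a warning instead of propagating infinities.

The search is a Monte-Carlo walk: one uniformly chosen trainable weight is
perturbed by a uniform step in [−0.05, +0.05] and clipped to [0, 2] per
move; improvements are always accepted and worsening moves are accepted with
a probability threshold annealed linearly from 0.25 to 0 over the run.  The
best-ever weight set is returned together with the full Z trace.  Records
are split 80/20 (stratified by class, seeded) into a training set that
drives the objective and a validation set for reporting.  By default the six
term weights and `w_cp` are trainable while site weights and `E_reverse`
stay fixed — the site weights are an empirical choice the array data cannot
constrain well, and the reverse penalty cannot be trained on orientation-free
array data at all.  Scoring inside the search is vectorized over a
precomputed (records × windows × sites × terms) tensor, with the site
dimension collapsed and cached while site weights are fixed.

The published protocol used ~10⁷ steps split across parallel searches;
`TrainingConfig.steps` defaults to 10⁷ accordingly, but the packaged studies
and tests use 10³–10⁵ steps, which this objective's smooth, low-dimensional
landscape saturates comfortably (the acceptance run reaches ≥ 100% of the
generating weights' Z at 10⁵ steps).

## Synthetic study

The generator module supplies every input with planted ground truth:

- `gen_pssm` — a deterministic basis set built from the shipped residue
  tables and simple site profiles (burial fraction and van der Waals depth
  peaking at site 0, electrostatic preferences for basic residues at the
  outer C-terminal-side sites) plus seeded Gaussian cell noise (σ = 0.15
  kcal/mol).  By construction hydrophobic residues are favored at sites
  −2 … 0 and the site-0 score spread exceeds site +2's.
- `gen_peptide_array` — 13-mers tiled (step 3) from random proteins whose
  composition is biased toward the binding motif (clusters of 3–5 branched
  hydrophobics flanked by K/R), scored by the truth model, perturbed with
  additive Gaussian noise (σ = 1 kcal/mol by default), and classed by score
  rank to match the 7/23/21/48% proportions.  Defaults are the study
  conditions: 3477 13-mers from 37 proteins.
- `gen_benchmark` — peptides (7–11 residues) whose recorded core and
  orientation are the truth-model argmin; peptides whose orientation gap is
  below kT are rejected so the planted truth is unambiguous.  An optional
  corruption rate replaces the recorded answer with a random different
  window to exercise imperfect-accuracy reporting.
- `gen_traces` — i.i.d. Gaussian per-frame records with the generating
  means/sds kept in the metadata.

What the fixtures do **not** emulate: fluorescence chemistry and its
correlated noise, the composition of real client proteins, the true published
energy values, and any disagreement between the basis set and reality.
Passing tests on synthetic data therefore demonstrates the machinery —
scoring identities, search behavior, evaluation arithmetic — not predictive
accuracy on real chaperone substrates.

## Numerical choices

- Energies are kcal/mol throughout; kT = 0.6 kcal/mol wherever thermal
  energy is invoked.
- Tabular output is fixed at six decimal places; read/write round trips are
  exact to that precision.
- z-scores use sample variances (ddof = 1).
- ROC/PR curves are computed with scikit-learn; ROC AUC is the trapezoid of
  the curve and equals the pairwise concordance statistic (ties counted ½).
  PR AUC integrates precision over recall in threshold order (preserving
  tied-recall point order), matching an exhaustive threshold sweep.
- The glycine column of a combined PSSM is *not* assumed to be zero: terms
  are referenced to an all-glycine substrate, but glycine's backbone can
  still interact.

## Known limitations

- The package cannot reproduce the published benchmark counts or worked
  example scores out of the box: the published 5×20 matrix and structure
  table are spreadsheet supplements that must be transcribed into
  `src/paladin/data/published/` first (documented there).  All claims the
  test suite makes without them concern the machinery, on synthetic data.
- The R/K whole-side-chain desolvation artifact is reproduced by design.
- No autocorrelation correction in trace SEMs; frames are assumed roughly
  independent at the sampling interval.
- The model disregards flanking residues, substrate-internal interactions,
  and any backbone rearrangement beyond the strain term.
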