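# paladin

Physics-based prediction of substrate binding to the Hsp70 chaperone DnaK:
which five-residue window of a protein binds, in which register, and in which
backbone orientation.

## The problem

DnaK, the major *E. coli* Hsp70, patrols the proteome by binding short
hydrophobic segments of client proteins — typically clusters of three to five
branched hydrophobic residues flanked by basic residues.  Its substrate-binding
cleft consists of five largely independent pockets (sites −2, −1, 0, +1, +2)
that contact five consecutive substrate residues; site 0 is a deep central
hydrophobic pocket, most often occupied by a leucine.  Because the bound
backbone conformation is highly conserved and makes identical hydrogen bonds
in both threading directions, a peptide can bind N→C ("forward") or C→N
("reverse"), and the preferred orientation is decided by side-chain
energetics alone.

`paladin` reimplements the Paladin model: a position-specific scoring matrix
(PSSM) whose entries are weighted sums of physical interaction energies
(derived from restrained atomistic sampling of every residue in every site),
used to score all five-mer windows of a sequence in both orientations.  It is
aimed at chaperone biologists and structural bioinformaticians who want
site-resolved, orientation-aware binding predictions rather than a bare
binder/nonbinder call.

## The model

A five-mer bound across the five sites is scored (kcal/mol, lower = better):

    E(five-mer) = w_cp · E_cp + E_reverse + Σ_sites w_site Σ_terms w_term · E[site, term, res(site)]

- `E[site, term, res]` — the basis set: mean energies of six physical terms
  (van der Waals, electrostatics, backbone strain, desolvation of the
  substrate side chain, desolvation of the binding site, side-chain rotamer
  propensity) per site and residue, referenced to an all-glycine substrate.
- `w_term`, `w_site` — dimensionless weights.  The published values are
  vdW 0.1, electrostatics 0.6, desolvation (substrate) 1.0, desolvation
  (site) 0.4, strain/propensity terms 0; sites 0.5 / 0.5 / 1.0 / 0.2 / 0.1
  for −2 … +2.  `paladin.default_weights()` returns them.
- `E_cp` — mean coil propensity (1 − helical propensity) of the window, the
  entropic cost of fixing the extended bound backbone (weight 0 by default).
- `E_reverse` — a flat penalty on reverse-orientation scores (0 by default).

Site weights are folded into the working 5×20 PSSM, so scoring a window sums
one matrix cell per site.  In the forward orientation window positions 1–5
occupy sites −2 … +2; in reverse they occupy +2 … −2, which gives the exact
identity `score(w, reverse) = score(reverse(w), forward) + E_reverse`.

Predictions derived from the scan:

- **register** — the minimum-score window within an orientation;
- **orientation** — Δ = (min forward) − (min reverse), called forward/reverse
  only when |Δ| exceeds kT = 0.6 kcal/mol, otherwise ambiguous;
- **peptide-array score** — for a 13-mer, the forward-only minimum over its
  nine windows.

Weights are trained against classed peptide-array data (13-mers labelled
strong binder / binder / neutral / nonbinder) by Monte-Carlo maximization of
the separation objective

    Z = 4·z(sb,nb) + 2·z(bi,nb) + z(bi,sb) + ½·z(nu,nb),
    z = (μ₁ − μ₂) / sqrt((σ₁² + σ₂²)/2),

computed on negated scores so that better separation of binders below
nonbinders increases Z.  The search perturbs one trainable weight per step
and anneals the worsening-move acceptance threshold linearly from 0.25 to 0.

## Worked example

Score the β-galactosidase fragment `GKTLFIS` with a synthetic example matrix
(deterministic, seed 0):

```python
from paladin import FixtureSpec, default_weights, gen_pssm, predict_orientation, scan_sequence

pssm, terms = gen_pssm(FixtureSpec(seed=0))
weights = default_weights()

result = scan_sequence("GKTLFIS", pssm, weights, seq_id="demo")
for s in result.scores:
    print(f"{s.start}  {s.window}  {s.orientation:<8s} {s.total:7.2f}")
call = predict_orientation("GKTLFIS", pssm, weights)
print(f"best forward: {call.best_forward.window} ({call.best_forward.total:.2f} kcal/mol)")
print(f"best reverse: {call.best_reverse.window} ({call.best_reverse.total:.2f} kcal/mol)")
print(f"delta = {call.delta:.2f} kcal/mol -> {call.call}")
```

prints

```
0  GKTLF  forward     3.52
0  GKTLF  reverse     1.34
1  KTLFI  forward    -2.50
1  KTLFI  reverse    -4.98
2  TLFIS  forward    -3.23
2  TLFIS  reverse    -3.06
best forward: TLFIS (-3.23 kcal/mol)
best reverse: KTLFI (-4.98 kcal/mol)
delta = 1.75 kcal/mol -> reverse
```

Each line is one (window, orientation) score in kcal/mol.  `KTLFI` threaded
C→N wins by 1.75 kcal/mol — more than kT (0.6) — so the peptide is called a
reverse binder: that threading puts its three hydrophobic residues into the
inner sites −2, −1 and 0.

Fitting the weights to a classed synthetic array (statsmodels-style
Model/Results):

```python
from paladin import FixtureSpec, PeptideArrayModel, default_weights, gen_peptide_array, gen_pssm

spec = FixtureSpec(seed=0, n_peptides=1000, n_proteins=10)
pssm, terms = gen_pssm(spec)
records, _ = gen_peptide_array(spec, pssm, default_weights())
results = PeptideArrayModel(records, terms).fit(steps=20_000, seed=0)
print(results.summary())
print(f"validation ROC AUC (strong vs nonbinder): {results.roc_auc(positive=('strong',)):.3f}")
```

ends with

```
Objective (training set)
--------------------------------------------------------------
  Z = 16.3598   [z_sb-nb 3.082, z_bi-nb 2.236, z_bi-sb -1.244, z_nu-nb 1.606]
  validation Z = 16.3319

validation ROC AUC (strong vs nonbinder): 0.986
```

i.e. the fitted weights separate strong binders from nonbinders almost
perfectly on held-out records of this synthetic array.

## Command line

```bash
paladin synth --out fixtures/ --seed 0                 # synthetic study with planted truth
paladin train --array fixtures/array.tsv --terms fixtures/terms.tsv \
              --steps 100000 --seed 0 --out-weights weights.yaml
paladin score --fasta proteins.fasta --pssm fixtures/pssm.tsv --out scores.tsv
paladin bench --benchmark fixtures/benchmark.tsv --pssm fixtures/pssm.tsv \
              --mode register --out report
```

`score` writes a per-window table plus a per-sequence summary (best
forward/reverse windows, Δ, orientation call); `bench` reports
register/orientation accuracy or ROC/PR AUCs as TSV + JSON.

## Layout

- `paladin.core` — basis-set, weight-set and PSSM containers; `combine_terms`.
- `paladin.energetics` — desolvation/propensity formulas and trajectory
  aggregation rules.
- `paladin.scanner` — window scoring, register/orientation prediction,
  13-mer array scoring, reverse-candidate screen.
- `paladin.training` — class z-scores, the Z objective, the Monte-Carlo
  search, and the `PeptideArrayModel` / `PeptideArrayResults` fitting surface.
- `paladin.evaluation` — ROC/PR curves and structure benchmarks.
- `paladin.iodata` — TSV/CSV/YAML/FASTA readers and writers with strict
  validation and exclusion logging.
- `paladin.synthetic` — seeded generators for every input, with planted truth.
- `docs/methods.md` — modelling assumptions, parameter choices, limitations.
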