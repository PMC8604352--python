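# Backbone and side-chain conformational propensity tables.
#
# helical: helix propensity mapped to [0, 1] as max(0, 1 - ddG) from the
# helix-propensity free energies of Pace & Scholtz, Biophys J 75:422-427
# (1998) (A = 0.00 kcal/mol ... P = 3.16 kcal/mol).  Coil propensity used by
# the model is 1 - helical.
#
# rotamer: (P_r, P_0) per residue -- the probability of the bound
# (lowest-energy) rotamer in the beta-strand backbone basin and the highest
# rotamer probability.  These are APPROXIMATE coarse values in the spirit of
# backbone-dependent rotamer statistics (Shapovalov & Dunbrack 2011), shipped
# as replaceable configuration; the side-chain propensity weight is zero in
# the published model, so they affect only the generic formula and the
# synthetic generator.  A and G have a single state: P_r = P_0 = 1.
helical:
  A: 1.00
  C: 0.32
  D: 0.31
  E: 0.60
  F: 0.46
  G: 0.00
  H: 0.39
  I: 0.59
  K: 0.74
  L: 0.79
  M: 0.76
  N: 0.35
  P: 0.00
  Q: 0.61
  R: 0.79
  S: 0.50
  T: 0.34
  V: 0.39
  W: 0.51
  Y: 0.47
rotamer:
  A: [1.00, 1.00]
  C: [0.35, 0.55]
  D: [0.30, 0.45]
  E: [0.25, 0.40]
  F: [0.40, 0.60]
  G: [1.00, 1.00]
  H: [0.30, 0.50]
  I: [0.45, 0.65]
  K: [0.20, 0.35]
  L: [0.45, 0.70]
  M: [0.25, 0.40]
  N: [0.30, 0.45]
  P: [0.45, 0.55]
  Q: [0.20, 0.35]
  R: [0.15, 0.30]
  S: [0.40, 0.50]
  T: [0.45, 0.60]
  V: [0.55, 0.75]
  W: [0.35, 0.55]
  Y: [0.40, 0.60]
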