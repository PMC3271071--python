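# tangle

Real-value prediction of protein backbone torsion angles (φ, ψ) from
amino-acid sequences, using a two-level support vector regression
cascade over sequence-derived profiles.

Backbone conformation is essentially fixed by two dihedrals per
residue: φ = C(i−1)–N–Cα–C about the N–Cα bond and ψ = N–Cα–C–N(i+1)
about the Cα–C bond (ω stays near 180° and is not predicted).  Accurate
real-valued (φ, ψ) predictions are useful as restraints in structure
prediction and fold recognition.  This package is for structural
bioinformaticians who want a transparent, fully tested implementation
of the cascade approach: every stage — dihedral geometry, profile
parsing, sliding-window encoding, the two SVR levels, circular error
metrics, the amino-acid-specific random null model — is an ordinary
library function, and a synthetic-data generator lets the whole
pipeline run end-to-end with no external tools or downloads.

## Model

Per residue, profile tracks are encoded over a sliding window of
L = 2l + 1 residues (default L = 9): PB (20 PSSM log-odds columns / 10),
PP (3 secondary-structure probabilities), SC (2 accessibility
indicators), DISO (2 disorder probabilities), giving scheme widths
20L / 23L / 25L / 25L / 27L, with an ALL variant appending global
features (composition, scaled length and weight).  Angles are
regressed on a normalized scale v = 0.5 + (θ − μ)/(6σ).  Two ε-SVRs in
cascade (RBF kernel, ε = 0.01, γ = 0.01, C = 5.0) first map features to
an initial normalized angle, then refine each residue from the window
of neighbouring first-level predictions, exploiting the local coupling
of torsion angles.  Errors are reported as Pearson CC, MAE and RMSE;
MAE/RMSE use the wrap-aware circular difference by default.  The null
model assigns each residue a random training-set angle of the same
amino-acid type, averaged over 10,000 repeats; its exact expectation is
also computed in closed form.  See `docs/methods.md` for details and
design choices.

## Worked example

```sh
tangle simulate --n 8 --seed 7   --out data/       # training fixtures
tangle simulate --n 4 --seed 1007 --out test_data/ # held-out fixtures
tangle train   --data data/ --out model.joblib --seed 7
tangle predict --model model.joblib --data test_data/ --out pred/
tangle -v evaluate --pred pred/predictions.tsv --out report/
tangle -v baseline --data data/ --test-data test_data/ --seed 7 \
       --repeats 2000 --out baseline.json
```

The evaluate and baseline steps log:

```
INFO tangle: phi: MAE (circular) 27.81 deg, CC 0.402 over 308 residues
INFO tangle: psi: MAE (circular) 49.37 deg, CC 0.481 over 308 residues
INFO tangle: phi baseline MAE 36.13 deg (exact 36.15)
INFO tangle: psi baseline MAE 75.04 deg (exact 75.13)
```

i.e. on held-out synthetic chains the cascade's circular MAE beats the
amino-acid-specific random baseline for both angles, ψ being harder
than φ (its distribution is bimodal) exactly as expected.  The
stratified report (`report/report.phi.tsv`) shows the characteristic
difficulty ordering — helix residues easiest, coil hardest:

```
phi  ss  C  0.1770  42.9442  57.7023   79
phi  ss  E  0.2262  29.0388  40.4928   51
phi  ss  H  0.0747  20.7472  26.0178  178
```

Per-chain predictions (`pred/<chain>.pred.tsv`) are 4-column tables —
1-based position, residue, predicted φ, predicted ψ — with `NA` for the
first residue's φ and the last residue's ψ, which are geometrically
undefined:

```
1  F  NA       3.95
2  V  -132.24  -11.74
3  S  -65.18   -51.43
```

Observed angles for real structures come from `tangle angles --pdb
file.pdb --out-prefix out`, which writes per-residue angle tables in
the same 8-column dialect the training readers accept.

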