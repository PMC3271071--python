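# Methods

## The prediction problem

The backbone conformation of a protein is essentially determined by two
dihedral angles per residue: φ (about the N–Cα bond, atoms
C(i−1)–N–Cα–C) and ψ (about the Cα–C bond, atoms N–Cα–C–N(i+1)); the
peptide-bond dihedral ω is effectively fixed near 180° and is not
modelled.  This package predicts real-valued (φ, ψ) for every residue of
a query sequence from four per-residue profile tracks — a PSI-BLAST-style
position-specific scoring matrix (PB), three-state secondary-structure
probabilities (PP), two-state solvent accessibility (SC) and disorder
probabilities (DISO) — optionally augmented with global sequence features
(amino-acid composition, scaled length and molecular weight).

## Angle computation and normalization

Observed angles are computed from backbone coordinates with the IUPAC
right-handed atan2 cross-product dihedral (cross-checked in the tests
against Bio.PDB and MDAnalysis) and reported on (−180°, 180°].  A
residue's φ is undefined when the preceding C is unavailable, ψ when the
following N is; a configurable `extra_trim` (default 0) can additionally
drop residues from each chain end, since some benchmark protocols discard
a few terminal residues beyond the geometrically undefined ones.

Regression targets are normalized as

    v = 0.5 + (θ − μ) / (c · σ)

with μ, σ the training-set mean and **sample** standard deviation
(ddof = 1) of the angle type and span multiplier c = 6 by default, so
that μ ± 3σ maps onto [0, 1].  Only mean/SD-based scaling into ≈[0, 1]
is pinned down by precedent; this particular affine form is the
package's choice because it is exactly invertible.  Denormalized
predictions are wrapped back onto (−180°, 180°] rather than clamped, so
predictions always stay on the legal circle.

## Feature encoding

Each residue is encoded by a sliding window of L = 2l + 1 consecutive
residues (default L = 9) whose per-position track blocks are
concatenated position-major in the fixed order PB (20 columns, raw
log-odds / 10, unclamped), PP (3), SC (2), DISO (2).  Window positions
outside the chain contribute exact zeros — zero padding is simple and
detectable, unlike edge repetition.  The per-residue widths are
therefore 20L, 23L, 25L, 25L and 27L for the PB, PB+PP, PB+PP+SC,
PB+PP+DISO and PB+PP+SC+DISO schemes.  The ALL scheme appends a global
block once per vector; its default width is 22 (20 composition
fractions over the standard alphabet, with X excluded from the
fractions but counted in the denominator; length / 1000 capped at 1;
summed average residue mass / 1e5).  The published ALL dimension implies
34 extra columns whose composition is never decomposed; this package
does not guess it — the global width is configurable and the default of
22 is reported honestly.  The track concatenation order within the
window is likewise unspecified upstream; any deterministic order is
equally learnable, so the order above is simply fixed and documented.

## The two-level SVR cascade

Both levels are ε-support-vector regressions with an RBF kernel at
ε = 0.01, γ = 0.01, C = 5.0 (scikit-learn's libsvm binding).  Level 1
maps the windowed profile features of a residue to its normalized
angle.  Level 2 takes, for each residue, the window of L₂ neighbouring
level-1 predictions (default L₂ = L, zero-padded at chain ends) and
outputs the refined normalized angle — torsion angles of neighbouring
residues are strongly coupled through local structure, which is what
the second level exploits.  Level-2 inputs are a pure window of level-1
outputs; re-concatenating the raw features alongside them is supported
as a design point deliberately left off by default.  Level-1
predictions used to train level 2 are in-sample by default; a
chain-level K-fold out-of-fold mode (`oof_folds`) is available to
reduce leakage.  Separate, independent cascades are trained per angle;
the default operating points are scheme PB+PP for φ and PB+PP+SC for ψ,
both at L = 9 — the best-performing combinations per angle in the
original benchmark.

Kernel SVR training is quadratic in the number of rows, so training
subsamples to `cap_rows` (default 20,000) rows per level with a seeded
generator; raising the cap reproduces full-scale runs.  Training is
deterministic under a fixed seed and fixed input order.

## Evaluation

Residue-level metrics: Pearson CC on raw angle values (deliberately
without wrap correction, matching the benchmark definition; a
Jammalamadaka–SenGupta circular correlation is provided separately and
clearly labelled as the non-benchmark variant), MAE in degrees, and
RMSE on both the raw (degrees) and normalized scales.  The MAE/RMSE
difference is **circular** by default (shortest arc, in [0, 180°]),
because angles are periodic; a `linear` mode (plain |a−b|) is exposed
for strict literalism, since published torsion-angle MAEs do not state
their convention and large errors near ±180° in the benchmark's
angle-binned error profile suggest the linear reading.  Reports name
the mode used.  Undefined observed or predicted values are excluded
pairwise.

Reports stratify by the 20 amino acids, three-state secondary
structure, two-state accessibility, 18 twenty-degree observed-angle
bins covering [−180°, 180°), and per chain.  The chain-level summary
includes the mean/median of per-chain CC and MAE and the fraction of
chains with CC ≥ 0.5 and ≥ 0.6; chain-level RMSE is emitted both as
the mean of per-chain RMSEs and as the pooled-residue value, labelled,
since either aggregation is defensible.  A two-sided Wilcoxon
signed-rank test on paired per-chain MAEs (exact null up to n = 25,
normal approximation beyond) supports method comparisons.

The null model is the amino-acid-specific random predictor: each test
residue receives an angle drawn uniformly from the training pool of its
amino-acid type (falling back to the global pool, with a warning, for
types absent from training), and the MAE is averaged over R repeats
(default 10,000).  `expected_random_mae` computes the exact expectation
of this procedure in closed form — the mean over test residues of the
mean pool-vs-observation difference — and the Monte-Carlo sampler is
tested to agree with it within three standard errors at R = 50,000.

## Synthetic data

The generator emulates the statistical structure that makes torsion
angles learnable from profiles, in exactly the file dialects the
readers accept.  Secondary structure is laid down in segments
(Poisson-distributed lengths, means H 9 / E 5 / C 4, no immediate
repeats); amino acids are drawn with state-biased propensities; angles
come from state- and residue-conditioned Gaussian basins: helix
φ ~ N(−63°, 8°), ψ ~ N(−42°, 10°); strand φ ~ N(−120°, 20°),
ψ ~ N(135°, 20°); coil a broad three-component mixture spanning the
PPII/β, α and left-handed-α basins.  Proline's φ is locked near
−75° ± 10° regardless of state; glycine's φ is widened 1.5× and
mirrored with probability 0.4, giving it the sign-symmetric spread that
makes it the hardest residue.  These basin parameters are design
defaults mimicking the familiar Ramachandran picture (single φ mode,
bimodal ψ), not measured values.

Profile tracks are noisy renditions of the truth: integer PSSM rows
with the true residue at N(7, 2) log-odds and others at N(−2, 2); SS
probabilities as a (1−r)·one-hot + r·noise smear with r = 0.15 and an
r/2-probability state flip; accessibility from hydrophobicity
(hydrophobics buried with p = 0.75) with a 0.10 label-flip rate;
disorder elevated for coil near the termini with σ = 0.05 noise.  All
floats are rounded to four decimals at generation so that writing and
re-reading the text fixtures is exactly lossless.

What the generator does **not** emulate: real covalent geometry or
tertiary packing, correlated errors of actual upstream predictors,
database-dependent PSSM statistics, or homology structure between
chains.  Passing end-to-end tests therefore demonstrates that the
pipeline recovers sequence-conditioned angle structure when it exists —
not that real-data accuracies are reproduced.

## Problem sizes and numerical choices

The end-to-end benchmark conditions used by the tests and the
acceptance script are 30 training chains and 10 held-out chains of
50–120 residues (~2,400 training rows per angle), the package's chosen
desk-scale configuration; the cascade there reaches a circular MAE well
below the exact random-baseline expectation for both angles, with the
helix < strand < coil error ordering.  Degenerate inputs are handled
explicitly: collinear/coincident dihedral geometry raises an
undefined-angle error; zero-variance angle sets refuse normalizer
fitting; zero-variance vectors make CC NaN with a warning; chains with
fewer than two defined pairs are skipped from chain-level statistics;
secondary-structure probability ties resolve to coil.  Model archives
embed a format version and refuse to load mismatched versions.

## Known limitations

Real accuracies depend on real PSSM/SS/accessibility/disorder inputs,
which must be produced by external tools; only their output formats are
consumed here.  The ALL scheme's global block differs in width from the
original's undocumented 34 columns.  CC on raw angles penalizes
wrap-around errors inconsistently near ±180°; the circular-correlation
variant is provided but is not the benchmark definition.  In-sample
level-2 training can leak level-1 fit; use `oof_folds` when that
matters.
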