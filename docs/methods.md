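# Methods

## Thermodynamics and affinity ranges

Binding free energy and dissociation constant are related by
`ΔG = RT ln K_d` with `R = 1.987 × 10⁻³ kcal K⁻¹ mol⁻¹` and `T = 298 K`
by default (temperature is a parameter). K_d is carried in nM — the unit
experimental Wnt–CRD affinities are reported in — and converted to molar
inside the formula, so `RT ≈ 0.5921 kcal/mol` and 1 M maps to ΔG = 0.
Conversions are exact inverses of each other and unrounded internally;
reported values are rounded to 2 dp (ΔG) and 1 dp (K_d, nM), the
precision of the experimental comparison table.

Affinity ranges are ordinal K_d bins: `++++` < 10 nM, `+++` 10–40 nM,
`++` 40–100 nM, `+` 100–400 nM, `−` > 400 nM. The "<10 nM" bound is
strict and the interior bins are read as closed at both printed ends, so
an exact boundary value takes the higher-affinity side's bin (10 nM →
`+++`, 40 nM → `+++`, 100 nM → `++`, 400 nM → `+`). No measured K_d in
the packaged table falls on a boundary, so any consistent convention
reproduces its range column; this one was fixed once and is tested.

## Linear affinity models

A model is `ΔG = β₀ + Σ βᵢ xᵢ` over named descriptors, each labelled
`protein-protein` or `lipid-protein`. Class labels are part of the model
definition (JSON: `{name, intercept, terms:[{descriptor, coefficient,
class}]}`), not of the descriptor data file, because class is determined
by a descriptor's provenance (interface scoring function vs MM-GB/SA
term), which the data file does not encode. Descriptor names are opaque
exact-match strings, normalised only for surrounding whitespace — the
column headers of the originating scoring pipeline are the vocabulary,
and fuzzy matching risks silently reading the wrong column. The four
published models are built in with their printed coefficients stored
bit-identically; descriptor values are assumed to be on their raw scales
(no normalisation before regression), consistent with the heterogeneous
magnitudes of the published coefficients.

## Constrained model search

The model-building procedure enumerates every descriptor subset of size
`k` (default 4) containing exactly `n_lipid` lipid-class descriptors
(default 1 — every published model has exactly one MM-GB/SA term among
four descriptors), fits ordinary least squares of experimental ΔG on the
training complexes, and rejects any candidate whose lipid–protein
contribution is unfavourable. "Favourable" is enforced **per training
sample** by default: `Σ_lipid βᵢ xᵢ ≤ 0` for every training complex.
Since the desolvation-type lipid descriptor is almost invariably
positive, this is the strictest reading of the requirement that the term
lower the predicted binding energy; a mean-based relaxation (`≤ 0` on
the training average) is selectable. Models with no lipid-class term
(reachable with `n_lipid = 0`) skip the check.

Surviving candidates are evaluated on the fixed training/test split
taken verbatim from the measurement table (never re-randomised) and
ranked by the mean of training and test RMSE, with ties broken by test
RMSE and then lexicographic descriptor names; the ranking key is
configurable (`rmse_train`, `rmse_test`) because the original
publication reports both RMSEs without stating an explicit tie-break.
Enumeration order is lexicographic throughout, so results are bitwise
reproducible without seeds.

Numerical choices: OLS is solved by `numpy.linalg.lstsq`; subsets whose
design matrix (including the intercept column) has a condition number
above 10⁸ are skipped and tallied in the diagnostics rather than fitted
— silent near-collinear fits would poison the ranking with unstable
coefficients. Residual orthogonality to the design is verified in tests
to 10⁻⁸, and the fit is cross-checked against statsmodels OLS.

The within-experimental-error count (InExp) takes each measurement's
K_d ± error band, maps it through the (monotone) ΔG conversion, and
counts predictions inside the interval. If `K_d − err ≤ 0` the lower ΔG
bound is −∞; measurements without an error range cannot contain any
prediction and count as not-within. The error ranges of the original
interferometry measurements are not published, so InExp against the
published counts is not reproducible; the statistic is exercised on
synthetic error ranges (a fixed fraction of each K_d) instead.

## Evaluation

`evaluation_table` derives ΔG_exp unrounded from the measured K_d,
compares it with each prediction, and flags complexes whose experimental
and predicted K_d occur in different affinity ranges. Computing ΔG_exp
this way (rather than from the 2-dp printed values) reproduces both
published RMSEs of model 1 — 0.33 train and 0.36 test — whereas the
rounded printed energies give 0.32 on the test set. Two printed |diff|
cells of the packaged table (mWnt4–mFzd5, mWnt5–mFzd1) are 0.10 smaller
than the printed energies imply; the fixture ships the printed cells
verbatim and the tests pin these two anomalies explicitly.

The two-model comparison statistic partitions complexes by the ordinal
distance between the two predicted ranges: same (0), adjacent (exactly
1), farther (>1). The three fractions sum to 1 and are symmetric in the
two prediction sets.

## Synthetic data

Real descriptor matrices from interface-scoring pipelines are not
redistributable, so the generator reproduces their statistical shape:

- **protein-protein columns**: Normal(0, σ) with σ drawn log-uniformly
  from [1, 10³] per column, mimicking the three-orders-of-magnitude
  scale heterogeneity implied by the published coefficient magnitudes
  (per-residue potentials vs summed contact energies);
- **lipid-protein columns**: log-normal with mean 20 and CV 0.25 —
  strictly positive, like a binding-site desolvation energy;
- **binding energies**: a planted 4-descriptor model (published-magnitude
  coefficients, one negative-coefficient lipid term, intercept −6.2941)
  plus Gaussian noise, default sd 0.3 kcal/mol ≈ the RMSE of the
  published models, giving ΔG mostly in the observed −12…−9 kcal/mol
  band. Columns named by the planted model get σ = 1/|β| so each planted
  term contributes ~1 kcal/mol of spread; OLS subset selection is
  scale-invariant, so this convention does not make recovery easier, it
  only keeps the planted signal physically sized.

Measurements invert the noisy ΔG to K_d, attach an error range of 20% of
K_d by default, and label the first 15 rows training and the next 8 test,
mirroring the experimental split. Everything is driven by one integer
seed (matrix and noise use decoupled streams derived from it);
identical spec + seed gives bit-identical output.

What the generator does **not** emulate: correlations between real
scoring functions (descriptors are independent by default; a duplicated
column is used in tests to exercise the collinearity guard), systematic
errors of structure-based scoring, or the actual numeric output of any
named scoring function. Passing recovery tests therefore show the search
machinery is correct, not that four-descriptor models are identifiable
from 15 real training complexes.

## Problem sizes

The recovery experiments (tests and the acceptance script) use a
12 protein + 2 lipid descriptor pool with the 15/8 split — 440 candidate
subsets per search — for the noiseless exact-recovery check and the
50-replicate rank-first rate at noise sd 0.1 kcal/mol. The generator's
defaults keep the full ~23 × 104 geometry of the emulated study; the
brute-force oracle equivalence checks run at ≤ 10 descriptors with
k ≤ 3, where independent naive enumeration is cheap.

## Known limitations

- Descriptor values are ingested, never computed: no structures, no
  scoring functions.
- Exhaustive enumeration is O(C(m, k)); the intended regime is m ≈ 100,
  k ≤ 5. Larger sweeps need a smarter strategy than this package offers.
- The published InExp counts and the full prediction matrices for
  putative CRD interactions depend on unpublished inputs (experimental
  error bars, per-complex descriptor values) and are out of reach; the
  corresponding machinery is validated on synthetic inputs only.
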