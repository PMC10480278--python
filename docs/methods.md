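# Methods

`phspec` analyses the reaction specificity of a thermophilic
4-α-glucanotransferase (GTase) and its loop variants: how mutations in the
domain-B lid loop shift the balance between transglycosylation (glycosyl
transfer to maltose) and hydrolysis (transfer to water), and how that
balance connects to the protonation behaviour of the catalytic residues.
This note records the models, the parameter choices and their rationale,
the synthetic-data conditions used for validation, and known limitations.

## Polyprotic activity–pH model

The core model treats the enzyme as a linear chain of `n` stepwise
(macroscopic) deprotonations with dissociation constants
`Ka_i = 10^(−pKa_i)`, populating `n + 1` species. Species `j` (with `j`
protons removed) has unnormalised population

    P_j ∝ 10^( Σ_{i≤j} (pH − pKa_i) )

and the observed activity is the population-weighted mean of per-species
activity weights `w_j` (arbitrary % units; they may exceed 100 and are
never renormalised, because the assay's "100%" is itself an arbitrary
reference). The familiar bell-shaped profile
`1/(1 + 10^(pKa1−pH) + 10^(pH−pKa2))` is the middle-species fraction of
the two-site chain; the four-pKa/three-active-species and
three-pKa/two-active-species formulas are likewise special cases, which
the tests verify against literal transcriptions to 1e−10.

Numerics: populations are computed in log10 space with the maximum
exponent subtracted before exponentiation, so pKa spreads of ten units
and pH values far outside [0, 14] cannot overflow. The model is
invariant to re-referencing the partition function.

One published formula is internally inconsistent: the
three-pKa equation's prose assigns weight `x` to the singly deprotonated
species, but its numerator `x + y[H+]/Ka2` pairs `x` with the doubly
deprotonated ("1") species. We implement the formula literally; in
general-scheme terms its weights are `(0, y, x, 0)`.

## Profile fitting

`fit_profile` minimises `Σ((obs − model)/sd)²` (unit sd when none is
given). Ordering and positivity constraints are removed by
reparameterization — `pKa_i = pKa_{i−1} + exp(δ_i)`, `w = u²` — and the
optimiser is Levenberg–Marquardt with ftol 1e−10 and at most 2000
function evaluations per start. The 7-parameter four-pKa surface is
multimodal, so starts form a deterministic grid: all ordered subsets of
an evenly spaced pKa grid spanning the data's pH range (15 starts for
four sites), optionally extended with seeded jitter. Because the model
is *linear* in the weights given the pKas, each start seeds its weights
by nonnegative least squares, which makes the multi-start both fast and
reliable (noiseless curves are recovered to 1e−3 in the pKas).

Standard errors are Gauss–Newton: a central-difference Jacobian in the
natural parameters at the optimum, covariance `SSE/(n−p)·(JᵀJ)⁻¹`. If
the Jacobian condition number exceeds 1e8 the parameters are flagged
unidentifiable and SEs reported as NaN rather than as inflated numbers.
A residual-resampling bootstrap (percentile intervals, seeded,
refitting from the point estimate) is provided as an alternative error
measure, since published ± values rarely state their method.

Lack of fit is diagnosed with a Wald–Wolfowitz runs test on residual
signs (zeros dropped): exact enumeration of the runs distribution for
n ≤ 20, normal approximation beyond. The reported p is the
*directional* tail — `P(R ≤ r)` when runs are fewer than expected
(clustered residuals, the signature of a too-simple model), `P(R ≥ r)`
for excess alternation. Model ranking (`compare_models`) combines AICc
(`n·ln(SSE/n) + 2k + 2k(k+1)/(n−k−1)`, `k` counting the residual
variance) with the runs filter: preferred is the lowest-AICc model whose
runs p exceeds 0.05, falling back to lowest AICc overall, ties to fewer
parameters. On synthetic data (33 points, pH 3–11, Gaussian noise
sd 3 %) this selects the generating model in ≳ 90 of 100 realisations in
both directions — the same residual-structure argument that motivates a
four-pKa description of the wild-type profile.

## Kinetics and H/T specificity

Transglycosylation is followed as starch consumption via the
starch–triiodide complex: one unit is the enzyme amount changing one
A620 unit per minute, so the reduction is `(A620(0) − A620(t))/(t·mg)`
averaged over time points (negative drops clipped to zero with a
warning). Hydrolysis is read by DNS colorimetry: a ≥ 3-point glucose
standard line `A540 = a·[glc] + b` is inverted after blank subtraction
and the glucose equivalents divided by incubation time and enzyme mass.
Activities of partially degraded samples are divided by the full-length
protein fraction (e.g. 0.83 for a 17 % degradation band), which the
module takes as an explicit input.

Acceptor kinetics `v = Vmax·S/(Km+S)` are fitted by nonlinear least
squares started from the Hanes–Woolf linearisation. When replicates are
present each is fitted separately and parameters averaged (so Vmax/Km is
the mean of per-replicate ratios, not the ratio of means); a single
pooled fit is used otherwise.

Specificity quantities: `H/T = H / Vmax_T` is kept in the assays' mixed
units, as conventionally reported; the increment is the ratio of
unrounded H/T means versus the reference variant; and the
transition-state energy difference is `ΔΔG‡ = R·T·ln(Vmax_ref/Vmax_var)`
with `R = 1.987e−3 kcal/(mol·K)` and `T = 343.15 K` — the 70 °C assay
temperature — positive when the reference is faster. A ten-fold Vmax
loss thus corresponds to ≈ 1.5 kcal/mol.

## Ensemble analytics

These are desk-scale implementations of standard trajectory analyses;
they consume coordinate ensembles from multi-model PDB files (frame
spacing supplied separately, default 100 ps) rather than running any MD.

- **Superposition** is Kabsch via SVD of the 3×3 cross-covariance, with
  the determinant correction guaranteeing a proper rotation; collinear
  or < 3-atom inputs are rejected. Tests check it against a brute-force
  rotation-grid-plus-simplex oracle.
- **RMSD series** superpose each frame's selection onto a reference
  frame (default: first).
- **Windowed RMSF** partitions frames into non-overlapping windows
  (default 100 ps; trailing partial window dropped), superposes frames
  onto the window-mean structure (seeded by the window's first frame,
  one re-superposition iteration — the reference choice is configurable
  because conventions differ) and reports
  `RMSF_i = sqrt(mean_t |r_i − ⟨r_i⟩|²)`. For isotropic Gaussian jitter
  of sd σ per coordinate this converges to σ√3, less the 6/3N
  degrees-of-freedom absorbed by the superposition.
- **Clustering** is the greedy neighbour-count (GROMOS/Daura) algorithm
  on the pairwise superposed-RMSD matrix at a 2 Å default cutoff, ties
  broken toward the lowest frame index for determinism. Pairwise RMSDs
  use the singular-value identity with batched 3×3 SVDs.
- **Distance counters**: hydrogen bonds are N/O–N/O heavy-atom pairs
  within 3.4 Å with *no* angle criterion (the donor/acceptor set is all
  N and O atoms, since no further chemistry is imposed by the
  definition); loop–protein contacts are carbon–carbon pairs within
  6 Å, with the overall minimum C–C distance reported even beyond the
  cutoff. Both are tested against O(n²) double-loop oracles.
- **pKa populations**: per-frame pKa series (e.g. PROPKA values at
  100 ps intervals) are decomposed into Gaussian mixtures fitted by EM
  (20 restarts, seeded) for 1–3 components, the count chosen by BIC —
  conservative for small populations, which is the right bias when
  asking whether a minority "catalytically compatible" low-pKa state
  exists. The decomposition method is this package's choice; the
  reported fraction of frames in the lowest-mean component is the
  catalytically compatible fraction. A constant series short-circuits
  to one zero-variance component flagged degenerate.

## Synthetic data: what it emulates and what it does not

The generators define the validation conditions and are deterministic
given (parameters, seed):

- **Profiles**: model curve on pH 3–11 in 0.25 steps (33 points) plus
  Gaussian noise, floored at zero. Noise sd 3 (% activity) is used
  throughout validation — the order of the published error bars.
- **Kinetics**: Michaelis–Menten velocities at the assay's acceptor
  range (1.2–20.5 mM maltose), Gaussian noise as a fraction of Vmax.
- **Two-state ensembles**: a self-avoiding 3.8 Å-step coil (60 atoms by
  default) whose "lid" subset is rigidly displaced 5 Å in the open
  state; frames follow a two-state Markov chain with stationary weights
  (0.8, 0.2) and mild stickiness (0.25), plus 0.3 Å isotropic jitter.
  The default lid is half the chain: optimal superposition absorbs much
  of a displacement carried by a small subset, and the lid must carry
  enough atoms for the two conformations to remain > 2 Å apart in RMSD
  — the regime the clustering analysis is meant to resolve.
- **pKa series**: Markov-switching Gaussian emissions, default two
  states near pKa 3 and 10 with 0.3/0.7 occupancy, emulating a
  nucleophile alternating between buried-protonated and
  solvent-stabilised environments.

These synthetics validate the *analytics*, not the biology: they have no
force field, no correlated backbone motion, no pH-dependent sampling,
and their noise is homoscedastic Gaussian. Passing recovery tests shows
the estimators are correct and calibrated under the stated conditions;
it does not certify behaviour on real trajectories or assays with
structured error.

## Problem sizes

Validation uses 33-point profiles, 100 noise realisations for recovery
and model-selection rates, 500-frame ensembles for clustering,
4000-frame pKa series, and ≤ 200-atom frames for the exact-counter
oracles — sizes at which every stated tolerance is met while the whole
suite runs in minutes on one core.

## Limitations

- pKas are macroscopic and the scheme linear; microscopic branching and
  coupled-site electrostatics are out of scope.
- Model selection assumes independent homoscedastic residuals; the runs
  filter catches gross structure only.
- The mixture decomposition assumes Gaussian components; strongly skewed
  pKa populations would bias means.
- The kinetics module fits the acceptor dimension only; ping-pong
  bi-bi global fits, product inhibition and thermal inactivation during
  long hydrolysis assays are not modelled.
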