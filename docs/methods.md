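# Methods

This note documents the models and numerical choices behind `saxsbench`:
how independent SAXS measurements are merged into a consensus profile, how
theoretical profiles are computed from coordinates, how models are fitted
to data, and what the synthetic-data generators do and do not emulate.

## Maximum-likelihood consensus

Independent solution-scattering measurements of the same particle differ by
a multiplicative scale *a* (concentration, intensity calibration) and an
additive constant *b* (imperfect solvent subtraction). The consensus
procedure iterates four steps:

1. **Alignment.** The current reference curve is linearly interpolated onto
   each dataset's q grid over their shared range and fitted as
   *a*·I_ref + *b* by weighted least squares with weights 1/σ², using only
   the dataset's own errors. The goodness of alignment is the reduced χ²
   with M − 2 degrees of freedom. Each dataset is re-expressed on the
   reference scale: I → (I − b)/a, σ → σ/a. Fitted a ≤ 0 is treated as a
   pathological input and raised as an error (σ/|a| with a < 0 would invert
   the curve).
2. **Combination.** A target q array (linear or geometric, user-set bin
   count) is built over the union of the input ranges. Each aligned point
   is assigned to a half-open bin [e_j, e_j+1) (the last edge inclusive)
   and bins are merged by inverse-variance maximum likelihood: with
   w = σ⁻², I_j = Σ wI / Σ w, σ_j = (Σ w)^(−1/2), and q_j = Σ wq / Σ w.
   Empty bins are dropped, so the requested bin count is an upper bound on
   the output length. Because q_j is a weighted mean, the output grid is
   generally not equispaced.
3. **Normalization.** The curve is divided by the mean of its first five
   points (alternatively by the Guinier I(0)) so that I(0) ≈ 1, then
   shifted so its minimum equals a configurable floor (default 0.001).
   Errors scale with the division and ignore the shift.
4. **Iteration.** The combined curve becomes the new reference and steps
   1–3 repeat until the per-dataset alignment χ² values change by less
   than a relative tolerance of 1e−6 (maximum over datasets; ceiling of
   200 iterations, non-convergence flagged rather than raised). Iterating
   makes the result independent of the initial reference: permuting the
   input order changes the converged consensus by less than 1e−6 relative
   in our replica tests.

Two numerical details matter for a clean fixed point. First, overlap
membership against the combined reference uses the *outer edges of the
occupied bins* (recorded in the profile metadata) rather than the
outermost weighted-mean q values: bin edges depend only on the fixed input
grids, whereas the end-bin q_j moves slightly every iteration, which
otherwise flips edge points in and out of the overlap and creates a limit
cycle at the 10⁻³ level. Interpolation is clamped (constant) over that
sub-bin margin and never extrapolates beyond it. Second, the
normalization's fixed point has first-five mean exactly 1 and minimum
exactly at the floor; a singly-normalized curve differs from this by the
(small) shift, which tests must account for.

Per-input diagnostics against the final consensus (χ², error-weighted
residual series for 3σ screening) use the experimental errors only — the
combined curve's errors are not folded in. No automatic outlier filter is
applied; exclusion and per-dataset q_min truncation are explicit inputs.

**Error-calibration diagnostic.** For K ≥ 3 datasets on a common grid, the
sample standard deviation across datasets at each q is divided by
√K·σ_combined. Well-calibrated errors give a mean ratio near 1 (slightly
below, by the sample-SD bias factor c₄(K)); errors understated by a factor
f give a ratio near f.

## Debye predictor with implicit hydration layer

Structures are reduced to heavy atoms; waters, hetero ligands and
hydrogens are stripped and alternate locations resolved to the
highest-occupancy conformer (ties keep 'A'). Each heavy atom becomes a
united-atom group (CH, CH₂, CH₃, NH, NH₂, NH₃, OH, SH, bare C/N/O/S/P)
carrying a displaced-solvent volume from the classic Fraser–MacRae–Suzuki
table and the implied sphere radius. Unknown residue or atom names fall
back to the bare-element group with a logged warning. This taxonomy is a
documented default of this package, not a reproduction of any particular
program's internal table.

The effective form factor of group *i* is

    f_i(q) = f_i^v(q) − G(q, c₁)·f_i^s(q) + c₂·s_i·f_w(q)

* **f_i^v** — in-vacuo factor: 4-Gaussian Cromer–Mann coefficients
  (International Tables Vol. C) for the heavy element plus h·f_H(q) for
  the implicit hydrogens, with amplitudes renormalized by a constant so
  f(0) equals the electron count exactly. The 4-Gaussian table was chosen
  over 5-Gaussian fits because it is equally standard and its q ≤ 1 Å⁻¹
  behaviour is indistinguishable at the precision relevant here; the full
  q-dependent hydrogen factor (rather than a constant electron count)
  keeps f(0) exact without special-casing.
* **f_i^s** — dummy-atom (displaced solvent) factor of a Gaussian sphere:
  ρ_bulk·V_i·exp(−q²·V_i^{2/3}/4π), with ρ_bulk = 0.334 e Å⁻³ by default
  (0.335 for the benchmark buffers).
* **G(q, c₁)** — excluded-volume adjustment
  c₁³·exp(−(4π/3)^{3/2}·q²·r_m²·(c₁²−1)/(16π)) with r_m = 1.62 Å, so the
  total excluded volume scales exactly as c₁³ and G ≡ 1 at c₁ = 1. The
  exact envelope form is a documented convention: only the q→0 behaviour
  and qualitative fit trends are relied upon, not bit-for-bit agreement
  with any existing program.
* **f_w** — hydration water factor f_O + 2f_H (10 e at q = 0), weighted by
  the atom's solvent-accessible surface fraction s_i and the hydration
  weight c₂ ∈ [−2, 4] (grid step 0.1). c₂ maps linearly onto the shell
  contrast, δρ = 0.0135·c₂ e Å⁻³, fixed by the printed end-point shell
  densities (0.388 e Å⁻³ at c₂ = 4, 0.307 at c₂ = −2 against bulk 0.334);
  the true relation is not simple, and this linear map is a documented
  convention of this artifact.

s_i is computed by a deterministic Shrake–Rupley method: 960 golden-spiral
points per expanded sphere (group radius + 1.4 Å probe), a point being
accessible if outside every neighbouring expanded sphere. No RNG is
involved; the two-sphere analytic cap fraction and an independent
implementation (biotite) agree within the point-set resolution (±0.02).

Intensities are the orientationally averaged Debye double sum
I(q) = ΣΣ f_i f_j sin(qd_ij)/(qd_ij). Two modes:

* `exact` — the O(N²) double sum per q value;
* `binned` — pair-distance histograms at 0.1 Å width, accumulated per pair
  of united-atom classes with weights {1, s_i, s_j, s_i·s_j}. This factors
  the intensity into six (c₁, c₂)-independent partial sums
  (A_vv, A_vd, A_dd, A_vw, A_dw, A_ww), so a full (c₁, c₂) grid scan costs
  one histogram pass plus trivial assembly per node. Binned agrees with
  exact to well under 0.5% for q ≤ 1 Å⁻¹ on a 500-atom model; self terms
  are added exactly, not histogrammed.

## Fitting and Guinier analysis

Model-to-data fits solve scale and additive constant in closed form by
weighted least squares, with reduced χ² over M − 2 degrees of freedom.
The error weighting is σ_expt alone, or √(σ_w² + σ_expt²) for model
profiles that carry their own statistical errors (frame-averaged
predictions). The (c₁, c₂) optimization is an exhaustive grid search
(c₁ ∈ [0.95, 1.05] step 0.01, c₂ ∈ [−2, 4] step 0.1 by default; an option
restricts c₂ ≥ 0 to emulate the no-negative-contrast policy); exact χ²
ties prefer the least-adjusted model (smallest |c₂|, then |c₁ − 1|).
Because the grid contains the unadjusted node (1.0, 0.0), the optimum is
never worse than a plain scale-plus-constant fit.

Guinier analysis fits ln I vs q² by unweighted linear regression with
R_g = √(−3·slope) and the regression standard error propagated to R_g.
The `fixed_limit` policy iterates the upper limit to self-consistency with
q·R_g ≤ 1.3; the `auto` policy additionally scans lower limits, requiring
at least 10 points and q_min·R_g < 1.0, and rejects windows whose
upper-half refit disagrees with the full-window R_g beyond the combined
regression errors plus 0.3% relative slack — a stand-in linearity screen
for low-q artifacts (the reference auto-range algorithm's internals are
not published). A caveat established against the closed-form sphere
factor: the Guinier approximation itself biases a uniform sphere's fitted
R_g by +1.85% when the window extends to qR_g = 1.3 (+0.44% at 0.65), so
sphere-identity checks (R_g = √(3/5)·R) use a window limit of 0.6; for a
Gaussian (exact Guinier-law) profile any window is exact. Similarly, the
identity between profile R_g and f-weighted coordinate R_g holds for
q-independent form factors; the near-cancellation in v(q) − d(q) otherwise
adds a real form-factor contribution to the apparent R_g.

Residual reports flag a run of ≥ 5 consecutive points beyond ±3σ as a
systematic deviation; isolated spikes are not flagged.

## Synthetic data

* **Replicas** emulate independent measurements: a_k·I_truth + b_k on
  optionally jittered or truncated grids, with Gaussian noise of
  σ = f·(|a_k·I| + 0.02·|a_k·I(0)|) — proportional to the signal *before*
  the background offset, with a floor so σ never vanishes (a σ ∝ |I + b|
  model degenerates to infinite weights where the offset crosses zero).
  Defaults: f = 1%, K as requested.
* **Mixtures** follow the pseudo-experimental protocol: predicted
  component profiles receive an experimental-style error template and
  Gaussian noise once, then are proportionately scaled and mass-fraction
  averaged with quadrature error propagation. "Proportionate scaling" is
  read as equal mass concentration — a j-mer contributes per-mass forward
  scattering ∝ j, so per-particle profiles are divided by j; a
  number-fraction alternative is available (orders of 1). The
  contamination ramp defaults to {0, 1, 2, 2.5, 3, 4, 5, 10}% contaminant.
* **Error template**: σ(q) = σ₀·(ε + (1−ε)e^(−q/λ)), decreasing from a
  low-q maximum (σ₀ = 1% of I(0), ε = 0.1, λ = 0.15 Å⁻¹), mimicking the
  shape of frame-averaged model errors and typical experimental error
  profiles. The round-robin error profile itself is not printed anywhere,
  so the template is synthetic by construction; χ² magnitudes at non-zero
  contamination depend on this noise scale and are treated as trends only,
  whereas the pure self-fit χ² ≈ 1 is scale-free.
* **Oracle structures**: cubic-lattice bead spheres (for the closed-form
  sphere factor) and compact pseudo-protein globules — uniform sphere
  placement with a 1.5 Å minimum-distance rejection rule and united-atom
  groups drawn from typical protein heavy-atom frequencies, deterministic
  under a seed.

What the generators do **not** emulate: beamline-specific error profiles,
correlated (smearing) noise, SEC frame-level effects, interparticle
interference, radiation damage. Passing the replica-recovery and
contamination tests therefore demonstrates the estimator's correctness
under ideal independent-Gaussian conditions, not robustness to those
real-data pathologies.

## Problem sizes and determinism

Test and benchmark runs use 200–500-atom globules, 4×10³-bead spheres,
K = 10 replicas on 400-point grids and 201-point fit grids — sizes chosen
so every oracle comparison is cheap while keeping the statistics
informative (e.g. the mean per-input χ² band 1 ± 3√(2/M) is ±0.21 at
M = 400). All randomness flows through explicit integer seeds;
repeated runs with the same configuration and seed are numerically
identical.

## Known limitations

* The united-atom volume/radius table and the c₁ envelope are documented
  conventions; fitted c₁/c₂ values are therefore not directly comparable
  with those printed by other programs, only their trends are.
* The consensus assumes Gaussian, independent, correctly scaled errors;
  the error-calibration diagnostic detects global mis-scaling but not
  q-dependent correlation.
* No indirect Fourier transform p(r), d_max estimation, or error
  rescaling by Bayesian inference; those belong to external tools.
* mmCIF input, hydrogen placement and loop building are out of scope;
  structures must be complete heavy-atom PDB files.
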