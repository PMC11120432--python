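# Methods

This note documents the models, numerical conventions, and design
choices behind `mixqmri`, and what its synthetic experiments can and
cannot say about real acquisitions.

## Signal model

Each sequence interleaves one or more TSE blocks within a shared
repetition time TR. A block may carry a T2-preparation module (echo
time TE_prep), a spin-lock module (spin-lock time TSL at a fixed
spin-lock frequency), and/or a spectral fat-saturation prepulse. The
voxel signal is a two-compartment steady-state model:

    S = (1 − f)·S_w + f·κ·S_f,
    S_c = PD · (1 − e^{−TR/T1_c}) · e^{−TE_equiv/T2_c} · P_c,

with preparation factor `P_c = 1` (no prep), `e^{−TE_prep/T2_c}`
(T2-prep), or `e^{−TSL/T1ρ_c}` (spin-lock), fat fraction `f`, and
fat-saturation residual `κ` (default 0.05; 1 when the block applies no
fat saturation). The water compartment uses the voxel's ground-truth
T2/T1ρ, so depth-dependent cartilage modulation propagates into the
images; the fat compartment uses the tissue-table values.

Assumptions and deliberate simplifications:

* **Full-TR saturation recovery.** Longitudinal recovery is
  `1 − e^{−TR/T1}` per block rather than an echo-train-resolved
  calculation. Variable-flip-angle refocusing trains are summarized by
  a single equivalent echo time TE_equiv (the 2D TSE references use
  their plain TE). Because all blocks of a sequence share TR and
  readout, these shared factors cancel exactly in prepared/unprepared
  signal ratios — the property the map reconstruction exploits — so the
  echo-train detail does not affect the quantities studied here. A
  consequence worth noting: residual T1-contrast effects that real
  short-TR 3D TSE acquisitions can show in short-T1 tissues (e.g.,
  artifactual meniscal hyperintensities) cannot arise in this
  ratio-cancelling model; representing them would require an
  echo-train-resolved (EPG-style) simulation, which is out of scope.
* **Fat saturation as a scalar residual.** SPAIR/SPIR pulses are
  modeled as a single multiplicative factor on the fat compartment; no
  spectral or inversion-timing physics. Only the downstream contrast
  and map-validity behavior matter for the analyses here.
* **Rician noise, spatially white, block-independent.** Magnitude
  images are `|(v + n_re) + i·n_im|` with independent zero-mean
  Gaussians of SD σ per channel. No coil profiles or parallel-imaging
  noise amplification: the ROI-level metrics under study compare
  sequences under a common, controlled noise floor. Per-block noise
  substreams are spawned from one master seed (`SeedSequence.spawn`),
  making every stack reproducible.

## Phantom

The phantom is a stylized sagittal slab (default 160×160×7 voxels at
0.875×0.875×3 mm): a curved femoral condyle band over a femoral
cartilage plate, a fluid-filled joint space with wedge-shaped marginal
menisci, a flat tibial plateau, an anterior infrapatellar fat pad, and
posterior muscle. Geometry is parametric in the grid size (minimum
32×32×3) and fully deterministic. Anatomic fidelity is intentionally
minimal — the phantom's job is to carry known parameters, not to look
like a knee; consequently, nothing here tests segmentation robustness,
partial-volume behavior at curved interfaces, or motion.

Default tissue parameters are plausible 3 T values (synovial fluid
T1 3600/T2 800 ms; fat and marrow T1 380/T2 130 ms with fat fraction
0.9; meniscus T2 12 ms; muscle T1 1400/T2 32 ms; cartilage T1
1200 ms). Cartilage truth maps follow a linear zonal profile from the
articular surface (depth 0) to the osteochondral interface (depth 1):
femoral T2 63→33 ms, tibial T2 51→21 ms, femoral T1ρ 60→30 ms, tibial
T1ρ 53→23 ms. With the uniform depth sampling of a constant-thickness
plate these average to 48/36 ms (T2) and 45/38 ms (T1ρ), representative
segmented plate means for morphologically intact cartilage. All values
are configuration, not constants; recovery tests assert against
whatever the config states.

ROIs are placed from the label map only: `round(area / voxel_area)`
voxels (minimum 1) nearest the in-slice tissue centroid, ties broken by
index order. The paired-contrast ROIs use 2.11 mm² and the CV ROI
3.76 mm². The in-plane ROI shape and placement convention (centroid
disc) is ours; only "circular, of stated area, inside the named tissue"
is externally fixed.

## Map reconstruction

Mono-exponential fits in the log domain:

* **Two points** (prep times 0 and τ): `t = τ / ln(s1/s2)`, defined
  when `s1 > s2 > floor`. R² is 1.0 by convention.
* **Three or more points:** ordinary least squares of `ln s` on prep
  time; `t = −1/slope`. Log-linear rather than nonlinear least squares:
  it is deterministic, agrees exactly with the two-point closed form,
  and is adequate at 2–3 samples; the difference from magnitude-domain
  NLLS is far below the noise level at the SNRs studied.

Fitted times are clamped above at 2000 ms (keeps long-T2 fluid finite
under noise). A voxel is **valid** only if all its block signals exceed
a floor (default 3σ), the fitted time is positive (decaying signal),
and — for ≥3-point fits — the log-domain R² is at least 0.95.

The R² criterion is what flags fat in the T1ρ variant: its unprepared
block is *not* fat-saturated while the prepared blocks *are*, so a
fat-dominated voxel shows a huge spurious initial drop followed by slow
decay — grossly non-mono-exponential (R² ≈ 0.87 even noiseless, given
fat fraction 0.9 and residual 0.05). In the T2 variant the saturation
asymmetry runs the other way and fat fails the decay condition
outright. A simple 3σ floor alone does **not** catch the T1ρ-variant
fat voxels (their water fraction and saturation residual keep them
above any reasonable floor), which is why the diagnostics include the
R² gate. Alternatively, a known fat mask (fat fraction > 0.5 from the
phantom) can be imposed; diagnostics mode is the default because a real
scanner has no ground-truth fat map.

## Image-quality metrics

Weber contrast `(SI_t − SI_r)/SI_r`, signed CNR
`(SI_a − SI_b)/√(σ_a² + σ_b²)`, and CV `σ/μ`, computed on the
morphologic (unprepared) block of each sequence. PD-w FS sequences pair
femoral cartilage with synovial fluid and measure CV in fluid; T1-w
sequences pair cartilage with the fat pad. ROI SDs are population
(n-denominator) SDs — a convention that must be fixed for exact tests;
CNR is reported signed, not absolute. In the degenerate noiseless case
where both paired ROIs are perfectly homogeneous, CNR is reported as
NaN (the standalone `cnr` function treats it as an error).

## Reader statistics

**Sample size.** `n = ceil(((z_{1−α/2} + z_{power})·sd/|δ|)²)` — a
paired, two-sided normal approximation. Two-sided is adopted because it
reproduces the reference design value (δ 0.5, sd 0.4, power 0.8,
α 0.01 → n = 8; the one-sided variant gives 7).

**Latent model.** Scores follow a cumulative-logit (proportional-odds)
model, `P(score ≤ s) = logistic(θ_s − η)` with
`η = β_sequence + u_structure + u_reader + u_specimen`, the `u`s
independent Gaussian random intercepts. The simulator draws from
exactly this model; it emulates ordinal score clustering by specimen,
reader, and structure, but not reader drift, score-category collapse,
or non-proportional odds — so recovery tests validate the estimator
under its own assumptions, not CLMM robustness to misspecification.

**Fitting.** Marginal likelihood via the Laplace approximation:

* inner loop — damped Newton maximization over the stacked
  random-effect vector `u` (the cumulative-logit log-pmf is log-concave
  in η, so the penalized Hessian `ZᵀWZ + D⁻¹` is positive definite);
  convergence 1e−8, warm-started across outer iterations;
* outer loop — L-BFGS-B over (θ₁, log threshold increments, β, log
  random-effect SDs), with log-SDs bounded in [−6, 3] so boundary
  (zero-variance) fits remain finite; convergence ~1e−8 relative.

The log-increment threshold parametrization enforces strictly
increasing cutpoints. With no random terms the objective reduces to the
exact proportional-odds likelihood, optimized with an analytic
gradient; tests verify agreement with an independent ML implementation
(statsmodels `OrderedModel`) to 1e−6 in log-likelihood. Fixed-effect
covariance comes from the numerically differentiated Hessian of the
(Laplace) objective, mapped to the natural (θ, β) scale by the delta
method. Reference-level coding uses the first sequence level (the 2D
TSE clinical standard in the presets).

**EMMs and contrasts.** Latent-scale EMMs are identified only up to
threshold location; we center by the mean threshold:
`EMM(level) = β_level − mean(θ)`. Pairwise contrasts are Wald z tests;
the Tukey family adjustment is the equicoordinate multivariate-normal
probability `P(max_c |Z_c| ≥ |z_obs|)` over the full contrast set,
evaluated by seeded Monte Carlo (200 000 draws; the contrast
correlation matrix is rank-deficient by construction, handled through
an eigenvalue square root). Adjusted p-values are floored at the raw
p-value. The classical studentized-range distribution is used only in
the repeated-measures ANOVA, matching common practice in each setting.

**Repeated-measures ANOVA.** One-way within-subject decomposition
(specimen block + sequence effect); Tukey–Kramer uses
`q = |m_i − m_j| / sqrt(MS_err·(1/n + 1/n)/2)` against the
studentized-range distribution with (k−1)(n−1) error df.

## Problem sizes and calibration checks

The test suite exercises, among others: noiseless round-trips on the
full default phantom (exact to ≤1e−9 relative); Monte-Carlo recovery at
SNR 50 with 10⁴ repetitions (mean bias < 3%, the residual being the
expected small Rician bias at the decayed point's SNR); 100-instance
agreement between the log-linear fit and an independent grid+refine SSE
minimizer (≤1e−6 relative); 200 replicates of the full CLMM on the
study-shaped design (10 specimens × 3 readers × 22 structures × 3
sequence levels, random-effect SDs 0.5/0.3/0.5) for 99% Wald coverage;
and 2000 null simulations of the RM-ANOVA for type-I control at
α = 0.01. These sizes keep the whole suite to a few minutes while
leaving Monte-Carlo error comfortably inside each tolerance.

## Known limitations

* No k-space, parallel-imaging, B0/B1, or echo-train physics; scan
  times and refocusing patterns are metadata only.
* Single-component relaxometry; no magnitude-bias correction in the
  fits (the floor mask keeps the bias small at the SNRs studied).
* The phantom's regular geometry makes ROI statistics cleaner than in
  vivo; absolute CNR/CV values are not comparable to scanner data,
  only their between-sequence ordering under matched conditions.
* The ordinal simulator and fitter share the same model family;
  conclusions about real reader behavior require real scores.
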