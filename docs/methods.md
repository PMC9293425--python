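# Methods

## Rate computation from headspace incubations

A respiration rate is derived from one sealed-vial incubation as

    rate = Δn(CO2) · 10⁶ / (m_dry · t)        [µmol CO2 g⁻¹ min⁻¹]

where Δn = Δppm·10⁻⁶ · P·V/(R·T) converts the headspace CO2 increase
to moles by the ideal gas law at the measured incubation temperature
(P = 101325 Pa by default; configurable).  The vial gas volume V is
either supplied per record or modelled as vial volume minus soil
volume, V = 12 mL − m_dry/ρ with ρ = 0.9 g cm⁻³ (a loose pumice soil);
both behaviours are supported because field protocols rarely state
which was used.  Headspace accumulation is treated as linear over the
incubation; no instrument drift or non-linear accumulation correction
is applied.

Soil mass follows the incubation-temperature rule (4 g below 20 °C,
3 g for 20–30 °C, 2 g for 30–38 °C, 1 g at 38 °C and above), with
half-open intervals closed on the left so the boundary temperatures
20/30/38 °C are assigned to the lighter mass.

A sample's (temperature, rate) series becomes one response curve.
Negative rates (headspace CO2 drawdown) are retained in the rates
table but excluded point-wise from log-scale fitting; a curve enters
fitting only with ≥5 positive rates — one more than the largest
parameter count plus residual variance, so AICc is always defined.
Duplicate (sample, temperature) pairs are averaged with a warning.

## Curve fitting

Both models are linear in their parameters on the log-rate scale, so
both fits are exact ordinary least squares with covariance
σ²(XᵀX)⁻¹, σ² = RSS/(n − p):

* MMRT: y = ln(rate) − ln(k_B·T/h) on the basis
  [−1/(RT), −(T−T₀)/(RT) + ln(T/T₀)/R, 1/R] → (ΔH‡_T0, ΔC‡ₚ, ΔS‡_T0).
* Lloyd & Taylor: ln(rate) on [1, 1/56.02 − 1/(T−227.13)] →
  (ln R₁₀, E₀).  The constants 227.13 K and 56.02 K are chosen so
  R₁₀ is exactly the rate at 10 °C; both are configurable.

Fitting both models on the same scale with the same residual
convention makes their AICc values directly comparable:
AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1), where k counts the
regression parameters plus the residual variance (k = 4 for MMRT, 3
for Lloyd & Taylor).  No weights are used — errors are assumed
homoscedastic on the log scale, consistent with multiplicative
lognormal measurement noise.

Trait standard errors use the delta method with analytic gradients.
T_opt depends only on (ΔH‡_T0, ΔC‡ₚ) and R₂₅ only on (ΔH‡_T0, ΔS‡_T0),
so each trait's SE is invariant to the parameter it excludes; the
delta SEs agree with parametric-bootstrap SEs to within ~15% at
moderate noise (verified in the test suite).  When the fitted
ΔC‡ₚ ≥ −R the rate has no interior maximum; the fit is returned with
traits undefined rather than failing, and such samples drop out of
trait-level analyses.  Fits whose T_opt exceeds the warmest measured
temperature are flagged `extrapolated_optimum`: such estimates are
systematically uncertain and can be arbitrarily large when ΔC‡ₚ is
estimated near −R (see "Known limitations").

Q10 is reported in the printed MMRT approximation
exp{10·[ΔH‡(T) − 5ΔC‡ₚ]/(R·T²)}; the exact forward ratio
R(T+10)/R(T) is provided alongside (`q10_exact`), and the two agree to
within ~15% over 10–40 °C for field-like parameters.  Treatment-level
Q10 envelopes evaluate Q10 per replicate fit on a 5–45 °C grid (1 °C
step) and report mean ± SE across replicates (n = 6 when the two
depths are pooled within biome × distance).

## The synthetic study generator

The generator emulates the geothermal-gradient field design so the
whole pipeline can be exercised with known truth:

* **Design** — 3 transects × 3 distances (2, 10, 30 m) × 2 biomes ×
  2 depths = 36 points; 22 incubation temperatures, 4–46 °C in 2 °C
  steps (the field protocol's "approximately 4–48 °C with 2 °C
  increments" admits several 22-value grids; 4–46 is the default and
  is overridable).
* **Environment** — MET anchored on the published treatment-cell
  means (16.9–48.3 °C), with a shared N(0, 2 °C) offset per
  transect × biome × depth plus N(0, 0.5 °C) within-cell noise, so MET
  always decreases with distance from the heat source within a series.
  pH = biome intercept − 0.03·MET + N(0, 0.15): the slope reproduces
  the strong negative pH–MET association of geothermal soils.  Carbon
  is lognormal with biome × depth medians (10.5/4.3 % grassland
  topsoil/subsoil, 15/4.5 % shrubland) and σ_log = 0.35; C:N is
  normal per biome (13.7 ± 1.0 grassland, 21.8 ± 2.5 shrubland) and
  N = C/(C:N).  Volumetric water content is independent uniform
  0.20–0.42.  All covariates are clipped to the envelope of the
  published cell means, so simulated marginals stay inside the
  field-observed range.
* **Traits** — each point's true MMRT parameters are built by
  inverting a trait triple: T_opt(°C) = 51 + 1.3·C + 0·MET + N(0, 8)
  (the carbon slope is the published substrate effect; the zero MET
  slope encodes the null thermal-history result; intercept and spread
  chosen to reproduce the published T_opt level ≈ 65 °C at mean
  carbon and its between-replicate spread), ΔC‡ₚ uniform on
  [−3.4, −1.1] kJ mol⁻¹ K⁻¹ (the published range), and
  ln R₂₅ = 1.4 + 0.08·C + N(0, 0.3) (a log-linear interpolation of the
  published R₂₅ extremes against carbon).
* **Incubations** — measured temperature = target + N(0, 0.25 °C)
  (±0.5 °C box control); rate = exp(MMRT log rate) × exp(N(0, σ_log))
  with σ_log = 0.15 by default; initial headspace CO2 ~ N(410, 10)
  ppm; the final reading is the *exact inverse* of the rate
  computation, so with all noise at zero the pipeline recovers the
  true parameters to machine precision (≈1e-14 relative, asserted at
  1e-8).  The duration targets a fixed headspace increase and is
  clipped to the protocol window of 52–169 min.  With rates on the
  published µmol g⁻¹ min⁻¹ scale the target increase is reached in
  under a minute, so durations sit at the 52-min bound and simulated
  ppm values are large; nothing downstream depends on ppm
  plausibility because generation and rate computation are exact
  inverses.
* **Dead sample** — optionally (default on) one shrubland sample is
  silenced (final ppm = initial ppm everywhere), reproducing the
  36 → 35 fitted-curve count of the field study via the discard rule.

One global seed feeds a hierarchical stream (environment → traits →
incubations → dead-sample choice); runs are byte-for-byte
reproducible.

What the generator does *not* emulate: instrument drift, non-linear
headspace accumulation, spatial autocorrelation beyond the transect
intercept, seasonal MET dynamics, or community composition.  Passing
tests therefore validate the estimation machinery under the stated
noise model, not the field measurement process itself.

## Treatment statistics

* **Summaries** — cell means ± SE (sd/√n); marginal means are
  unweighted means of cell means, which matches pooled means exactly
  on the balanced design and weights cells equally under the mild
  unbalance introduced by the dead sample.
* **Three-way ANOVA** — full factorial biome × depth × distance with
  sequential (Type I) sums of squares in that fixed order; order
  matters only through the one-sample unbalance, and is therefore
  fixed and stated.  F-tests are against the residual mean square.
* **Backwards stepwise regression** — starts from the full three-way
  interaction of MET, water content and carbon (pH, N and C:N are
  excluded by default because they are collinear with MET and C).
  At each step the droppable terms (not nested in a retained
  higher-order term) are tested by the extra-sum-of-squares F test;
  the least significant with p > α = 0.05 is dropped, preferring
  higher-order terms on ties; elimination stops when every droppable
  term is significant.  The full trace is returned so alternative
  stopping conventions can be audited.  Note that an intercept-only
  outcome under a null response requires all seven candidate terms to
  survive their own exit tests, so its probability is ≈0.95⁷ ≈ 0.70,
  not 0.95 — multiplicity is intrinsic to stepwise selection.
  When a final model retains interactions, the single-number slope of
  a covariate is reported as its average marginal effect over the
  observed data (equal to the raw coefficient in additive models).
* **Random intercept** — a Gaussian transect-intercept model fitted by
  maximum likelihood via a one-dimensional profile over the
  between/within variance ratio λ (closed-form GLS and determinant per
  group; λ = 0 admitted at the boundary).  ML rather than REML so AICc
  is comparable across fixed-effect structures; the AICc parameter
  count is the number of fixed effects plus two variances.  On
  balanced one-way data the ML components match the closed-form
  estimators (σ̂²_e = MSE, σ̂²_b = (SSB/a − MSE)/n) to 1e-6.

## Numerical choices

* T₀ = 298.15 K (exact 25 °C), all constants injectable.
* Temperatures cross the API in °C and are converted once to Kelvin;
  parameters are SI internally and reported in kJ mol⁻¹ / °C.
* CSV interchange uses %.17g formatting and round-trip float parsing,
  so staged runs equal the in-memory driver exactly.
* Singular fit designs (all temperatures equal) and too-few-points
  curves raise; empty ANOVA cells are dropped with a warning.

## Known limitations

* When the true optimum lies well above the warmest incubation
  temperature, T_opt and ΔC‡ₚ are extrapolations: with 15% rate noise
  the per-fit ΔC‡ₚ SE on the 22-point grid is ≈0.32 kJ mol⁻¹ K⁻¹, and
  flat-response samples (ΔC‡ₚ near −1.1 kJ mol⁻¹ K⁻¹) occasionally
  yield fitted ΔC‡ₚ within ~2 SE of −R and explosive fitted T_opt.
  The resulting trait-regression errors are right-skewed and grow with
  carbon, which inflates residual variance and makes interaction
  F-tests anti-conservative in a minority of simulated studies.  The
  recovered carbon slope averaged over replicate studies is unbiased
  (≈1.33 vs the configured 1.3), but term selection is less stable
  than a Gaussian-error analysis would suggest; consult the stepwise
  trace and the `extrapolated_optimum` flags before interpreting a
  single study.
* AICc comparability across the two models presumes both are fitted to
  the same points on the same (log) scale; the comparison refuses
  mismatched point sets.
* The MMRT-vs-Lloyd & Taylor AICc preference is decisive only when the
  optimum is inside the measured range; for strongly extrapolated
  optima the two models describe the data almost equally well and the
  preference can go either way.
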