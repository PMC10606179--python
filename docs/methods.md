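# Methods

## Scope and model

`drykin` analyses thin-layer hot-air drying of a slab of wet plant
material (the reference system is tomato peel spread as a ~10 mm bed) and
the thermal degradation of carotenoids in the dried product.

### Moisture scales

Wet-basis moisture M_WB (% wt.) converts to dry basis as
M = M_WB/(100 − M_WB) (kg water per kg dry solid). From weighed masses,
M(t) = (m(t) − m_s)/m_s with the dry-solid mass m_s either given or
derived as m(0)·(1 − M_WB(0)/100). The moisture ratio is
MR = (M − M_e)/(M_0 − M_e); the equilibrium moisture M_e defaults to 0
(it is small against M_0 for hot-air drying), so MR = M/M_0 and MR(0) = 1
exactly by construction. Masses up to 2 % of m_s below the dry-solid mass
are treated as balance noise and clipped to M = 0 with a warning; larger
violations are errors.

Times are stored in seconds; CSV I/O accepts hours (samples are weighed
hourly), and thin-layer rate constants are reported per hour — over 6–11 h
runs the fitted constants (≈ 0.2–2.5) are only meaningful on that scale.

### Slab diffusion

In the falling-rate period moisture transport obeys Fick's second law in
MR on 0 ≤ z ≤ L/2 with uniform initial moisture, zero flux at the
mid-plane, and the equilibrium value at the surface. The
thickness-averaged solution is the Fourier series with leading
coefficient 8/π² and decay rates (2j+1)²π²D_eff/(4(L/2)²). For Fourier
number Fo = D_eff·t/(L/2)² ≥ 0.2 the one-term truncation is accurate to
better than 0.5 % relative, which justifies estimating D_eff from the
slope of ln MR on t. The intercept is fixed at ln(8/π²) by default — the
analytic value of the one-term solution — with a free-intercept mode for
diagnostics. Usable points are those with t > 0 and MR > 0; fully dry
points (MR ≤ 0, undefined log) are dropped with a warning. The default
slab thickness is L = 0.01 m.

Across temperatures, D_eff = D_0·exp(−E_a/(R·T)) with T in kelvin
(conversion 273.15) and R = 8.3145 J/(mol·K). E_a = −slope·R of the
ln D_eff vs 1/T regression. On the packaged reference diffusivities this
yields E_a = 16.27 kJ/mol with R² = 0.9706. Note the published
per-temperature slope→D_eff pairs for this system are mutually
inconsistent by up to ~4 % (e.g. at 50 °C the printed slope
−9.5680 × 10⁻⁵ s⁻¹ with L/2 = 0.005 m implies 0.969 × 10⁻⁹ m²/s against
the printed 1.0074 × 10⁻⁹); the package trusts the formula
D_eff = −slope·4(L/2)²/π² and records the printed D_eff values as data.

### Finite-difference check

`fd_solve` integrates the same boundary-value problem with an implicit
θ-scheme (Crank–Nicolson by default, backward Euler optionally) on a
uniform grid, a four-step backward-Euler start-up to damp the initial
surface discontinuity, and a geometrically ramping time step capped at
diffusion number D_eff·Δt/Δz² ≤ 10. With 201 nodes it agrees with the
50-term series to better than 10⁻⁴ absolute over Fo ∈ [0.01, 2],
providing an oracle for the series implementation that shares no code
with it.

### Thin-layer models and fitting

The ten registered forms and their parameter counts: one-term Fick (1),
Newton (1), Page (2), Modified Page (2), Henderson–Pabis (2), Two-term
exponential (2), Logarithmic (3), Midili (4), Two-term (4), Modified
Henderson–Pabis (6). Default bounds bracket published tomato-peel values
with wide margins: rates in [10⁻⁴, 50] h⁻¹, coefficients a, b, c in
[−2, 2], exponents n in [0.1, 5]. Initializers: a single-exponential rate
guess k = −ln MR(t_mid)/t_mid; Page/Midili start at n = 1;
multi-exponential forms split the single-exponential guess (k/2, 2k).
Fitting is bounded trust-region least squares on the MR residuals with
tolerances 10⁻¹⁰, from the initializer plus a deterministic 8-start grid
(fixed rate-scaling factors and coefficient offsets). Exact
parameterization equivalences hold by construction: Page and Modified
Page reach the same SSE with k′ = k^(1/n).

Statistics: RMSE = √(SSE/N); reduced χ² = SSE/(N − n); R² = 1 − SSE/SST
with SST centered on the mean of the experimental values. An
`as_printed` R² variant centers on the mean of the predictions instead,
for comparability with reports using that convention; it changes only R².

Ranking is RMSE ascending, then χ², then R², then fewer parameters, then
name. RMSE and χ² are quantized at 10⁻⁸ for ranking so that nested models
reproducing noise-free data exactly (SSE at numerical zero for several
forms) count as ties and the parameter-count tie-break decides — this is
what makes model selection on noise-free synthetic data deterministic and
sensible (Newton beats Page with n̂ = 1; Two-term beats the 6-parameter
Modified Henderson–Pabis that nests it). On noisy data no quantization is
active in practice and raw RMSE decides, so the most flexible form may
rank first — the model-selection self-consistency check therefore runs on
noise-free studies.

Hartley's Fmax (max/min sample variance across equal-sized replicate
groups) uses a Monte-Carlo critical value: n_sim draws of normal groups
under the homogeneous null, 95th percentile, fixed seed. Classical table
lookups are avoided; two independent simulations of 10⁵ draws agree to
within 2 %.

### Specific drying energy

E = A·w·ρ·Cp·ΔT·t/m (kWh/kg, with Cp in kJ/kg/°C and t in h). A literal
variant dividing by t instead of multiplying appears in parts of the
drying literature; it is dimensionally inconsistent with kWh/kg and
inverts the temperature-time trend, so the dimensional form is the
default and the literal one sits behind `formula_variant="as_printed"`.
Dryer parameters not fixed by data (tray area, air velocity, air
properties, ambient temperature — defaults 0.09 m², 1.0 m/s,
1.06 kg/m³, 1.007 kJ/kg/°C, 25 °C) are clearly non-measured defaults and
are logged as such by the pipeline. With the study's drying times (11,
10, 9, 8, 7, 6 h at 50–75 °C) the energy-temperature curve has its
minimum at 50 °C and decreases above 65 °C for any ambient in [20, 26] °C;
that qualitative trend, not an absolute kWh/kg value, is what the package
checks, since the dryer's geometry and air speed are unknown.

### Carotenoid degradation

Concentrations C(T) (mg/100 g dried material) are normalized to retention
y = C/C_ref with the baseline C_ref fitted jointly with the shape
parameters (initialized at the lowest-temperature concentration, which is
also the baseline used for reported degradation percentages
100·(C_ref − C)/C_ref). Registered forms: logistic
y = 1/(1 + exp(s(T − T_m))) (default — reproduces the slow-then-fast loss
pattern) and exponential y = exp(−b·max(T − T_0, 0)^p). The form behind
the original study's degradation curves is not published, so its
extrapolated values (94 %/83 % degradation at 110 °C) and fit statistics
are qualitative references only; both registered forms fit the reference
concentration series with R² > 0.95 on the retention scale and agree on
the monotone-degradation structure. Extrapolation beyond the fitted
temperature range is permitted with a warning. Fitting is
scale-invariant: rescaling all concentrations rescales C_ref and leaves
the shape parameters and retention-scale statistics unchanged.

One published percentage (21 % lycopene degradation at 60 °C) computes as
23.2 % under every printed baseline; it is not reproduced and is treated
as unexplained.

## Synthetic data

Generators emulate the study design: 30 g samples at 82.63 % wt. initial
moisture, a 10 mm slab, hourly weighing, run durations 11/10/9/8/7/6 h at
50/55/60/65/70/75 °C. A truth model (any registered form, or the Fick
series) produces MR(t); additive Gaussian noise on the MR scale
(approximating a constant balance error over the dry mass; a
multiplicative option exists) perturbs all t > 0 points, truncated to
[0, 1.05]; masses follow m(t) = m_s(1 + MR·M_0). The t = 0 point is
pinned at MR = 1 — the sample starts fully wet — so truth parameter sets
are taken with analytic intercept 1 (e.g. Two-term with a + b = 1); the
one-term Fick form, whose intercept is 8/π², describes only the t > 0
decay, exactly as in the linearized D_eff regression. Multi-temperature
studies link D_eff to temperature through an Arrhenius law so that the
whole estimation chain (per-temperature regression → Arrhenius fit) is a
noise-free round trip.

What the generators do not emulate: shrinkage of the bed during drying
(neglected throughout, as in the underlying slab model),
moisture-dependent diffusivity, temperature transients at the start of a
run, and correlated balance drift. Passing tests therefore demonstrate
correctness of the estimation chain under the stated model, not the
adequacy of that model for any particular material.

## Numerical choices and problem sizes

* Optimizer tolerances 10⁻¹⁰ (xtol/ftol/gtol), 8 deterministic starts.
* Ranking tie quantum 10⁻⁸ on RMSE and χ².
* Finite-difference check: 201 nodes, Fo ∈ [0.01, 2], agreement bound 10⁻³.
* Monte-Carlo sizes: 200 seeds for noisy-recovery checks, 10⁵ draws for
  Fmax critical values — sizes at which the checked bounds (median rate
  error < 5 %, mean rate bias < 2 %, critical-value stability 2 %) are
  comfortably resolved.
* MR values a few ulp below 0 (round-off in the normalization) are
  clipped to 0; values above 1.02 are rejected as data errors.

## Known limitations

* One-dimensional slab geometry only; no coupled heat transfer.
* The reduced-χ² denominator for the fixed-intercept D_eff regression
  uses the fitted-coefficient count (1), so its χ² is not comparable to
  the free-intercept variant's.
* Modified Henderson–Pabis parameters are recoverable only up to
  permutation of its three (coefficient, rate) pairs, and its fitted
  values on real (noisy) data are poorly identified — standard for
  six-parameter exponential sums.
* Absolute specific-energy values depend on dryer parameters that must be
  supplied; only the temperature trend is meaningful with defaults.
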