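# Methods

## Model and procedure

The package analyses osmotic-dehydration mass transfer in thin plant-tissue
slices immersed in a hypertonic sucrose solution, optionally inside an
ultrasonic bath (UAOD). Water leaves the tissue down the osmotic-pressure
gradient while solutes counter-diffuse in; ultrasound accelerates both by
cavitation and microstreaming. Three measured series per slice — total mass
A(t), solids mass S(t), water mass W(t) = A(t) − S(t) — support three layers
of analysis.

**Indices.** MRe, SG and WL are percentages of the *initial* mass A0 of the
same replicate, never of a pooled mean, so the identity WL = MRe + SG holds
exactly for every internally consistent record (it is asserted to 1e−9 in
`trajectory_metrics`). Negative SG or WL values are possible with replicate
scatter; they are returned unclipped with a warning, because clamping would
bias replicate means toward zero. Whether reported indices should be
per-replicate or pooled was an open design choice; the package computes per
replicate and summarises as mean ± sd.

**Thin-layer fits.** The moisture ratio MR(t) = W(t)/W(0) is fitted with six
empirical forms (Page, Newton, Midilli, Logarithmic, Verma, Two-term). Time
is minutes everywhere: rate constants like k = 0.013 are only physically
sensible per minute over an 80-min treatment, and every report header keeps
that unit. The Two-term form is implemented with an exponent n on its first
term, exactly as specified in the source table layout this package mirrors,
although the conventional two-term model has none; the consequence is that
Two-term nests Page (a=1, b=0), which matters for selection (below).

Fitting is bounded nonlinear least squares (scipy `least_squares`, TRF) with
soft bounds k, k0, k1, g ∈ [0, 10] min⁻¹, n ∈ (0, 3], a, b, c ∈ [−2, 2].
Starts are a deterministic grid — k from {0.001, 0.01, 0.1}, n from
{0.5, 1}, a = 1, b = c = 0, g = k/2 — and every model with three or more
parameters gets at least five starts (Logarithmic and Verma, which have no
n, sweep a second value of c and of the g/k ratio instead). The best start
by SSE wins; there is no RNG anywhere in fitting, so repeated calls are
bit-identical. Non-finite model evaluations inside the optimiser are
penalised with a large residual instead of aborting the start; if every
start fails the result carries `converged=False` and infinite SSE rather
than raising, so a single pathological condition cannot kill a batch run.

The t = 0 point (MR = 1 by definition) is included in fits by default
(`--no-include-t0` drops it): dehydration curves are anchored at 1 even when
sampling starts at 10 min. Replicate MR curves are averaged point-wise
before fitting, giving one parameter set per condition as in the standard
report layout; per-replicate fitting is available as an option.

**Goodness of fit and selection.** SSE = Σ(obs−pred)², RMSE = √(SSE/N) and
R² = 1 − SSE/Σ(obs−mean)². RMSE deliberately divides by N, not N − p: with
8–9 points per curve the plain definition is the one consistent with the
reference fit statistics (e.g. √(0.0003/8) ≈ 0.0061 against a printed
0.0065), and it keeps RMSE monotone in SSE across models of different size.
The winner has the highest R²; ties within 1e−6 fall through to lower RMSE,
RMSE ties within the same tolerance to fewer parameters, then to registry
order. The RMSE tolerance matters: on noiseless data every nested model
reaches SSE ≈ 0 at machine level, and without it the tie-break would be
decided by optimiser jitter instead of parsimony. A consequence of raw-R²
selection worth knowing: on *noisy* data the most flexible nested form
(Two-term, 5 parameters) generically edges out Page by a hair of R², since
the rule has no complexity penalty — that is the rule as specified, not a
defect; information criteria are deliberately out of scope.

**Diffusivity.** The first term of the Fickian series for a slab of
half-thickness L dried from both faces gives ln MR ≈ const − (π²D/4L²)t, so
D_eff = |slope|·4L²/π² with the slope in per-second units. Slopes are
regressed in per-minute units (OLS, scipy `linregress`, all points with
MR > 0 including t = 0) and converted by 1/60 internally: the per-minute
reading is forced by consistency, since a printed slope of 0.0033 with
L = 2.5 mm reproduces the printed 1.39×10⁻¹⁰ m²/s only under that
convention (a per-second reading is off by 60×). ln MR slopes are negative
during drying but the report convention is positive; the API stores the
magnitude and rejects negative inputs with guidance rather than silently
flipping signs. L defaults to 2.5 mm (half of the 5 mm slice) and is
configurable. Only the first series term is used — no multi-term
refinement — matching the log-linearisation the slope method implies.

The stored reference diffusivity table has one quirk worth documenting: its
slopes were rounded to two significant figures *after* D_eff was computed,
so recomputing D_eff from a printed slope can differ from the printed D_eff
by up to ~3 % (0.0022 → 9.29×10⁻¹¹ against a printed 9.05×10⁻¹¹); the
0.0033 rows agree exactly at 3 significant figures. Tests use a 3 % relative
tolerance for those recomputations and printed-precision (half-ulp)
tolerance for the group means — the 0 W mean is exactly 1.465×10⁻¹⁰, which
was published rounded up to 1.47.

## Synthetic-data generator

The generator emulates the study conditions, not tissue physics: moisture
kinetics follow the Page form with the nine reference (k, n) pairs verbatim,
because the acceptance surface is the analysis pipeline and the Page form is
what that pipeline should recover. Solids gain follows a saturating
first-order curve SG(t) = SG∞(1 − e^(−βt)) with β = 0.03 min⁻¹ (≈91 %
saturation by 80 min, consistent with uptake that is fast early and
flattening by the end of treatment); SG∞ is back-computed per cell from the
80-min uptake, using the four measured anchors (3.28, 6.76, 9.11, 13.53 %)
and values filled monotonically in power and concentration for the five
unreported cells. Slices start at A0 = 10 g and 84 % w.b. moisture; W, S and
A are reconstructed so W + S = A exactly, which makes the conservation
identity structural in generated data.

Noise is additive Gaussian, independent per (condition, replicate, time):
sd 0.005 on MR (clipped to (0, 1.05]) and 0.25 % absolute on SG (clipped at
0). No replicate-level dispersion was ever reported, so both are calibration
choices, made once: 0.005 puts synthetic Page-fit R² in the high 0.99s on
the per-condition replicate means and brackets the printed 0.975–0.996 range
across the wider random (k, n) sweeps used in testing. The t = 0 record is
noise-free by construction — it *defines* the initial masses every index is
computed against. Randomness comes from one `numpy` generator seeded
hierarchically by (seed, power, 10×concentration, replicate), so adding a
condition never perturbs the others.

What the generator does **not** emulate: shrinkage, temperature drift,
non-Gaussian or time-correlated measurement error, within-slice moisture
gradients, and any real departure of tissue kinetics from the Page form.
Passing tests therefore demonstrate that the pipeline is arithmetically
correct and recovers known kinetics under realistic noise — not that real
kiwifruit obeys the Page model; that conclusion belongs to the underlying
experiments.

## Problem sizes and numerics

The default study is 3×3 conditions × 3 replicates × 9 times; recovery
statistics use 200 simulated datasets of 9 points, chosen as the smallest
sweep that stabilises a median relative error. Optimiser tolerances are
xtol = ftol = gtol = 1e−14 (noiseless recovery lands near machine precision,
comfortably inside the 1e−6 relative contract). Degenerate inputs are
handled explicitly: constant observations make R² undefined (error), MR ≤ 0
points are dropped from the log regression with a warning (≥3 usable points
required), a constant-MR series returns slope 0 with r reported as 0, and
trajectory CSVs are validated for schema, duplicates and the W + S = A
balance (1e−6 g absolute) on read.

## Known limitations

- The six-model registry is closed; no Henderson–Pabis, Wang–Singh, AIC/BIC
  or weighted least squares.
- No temperature dependence (the design holds 50 °C) and no cylindrical or
  spherical diffusion geometries.
- The reference study's other five models' constants were never published,
  so only the Page surface of the fit report can be compared against
  measured values.
- Reported R² can exceed the printed range when fitting replicate-averaged
  synthetic curves, because averaging three replicates shrinks the effective
  noise below a single slice's scatter.
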