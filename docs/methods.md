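# Methods

This note documents the models behind each stage of `foldstate`, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical choices that matter.

## Sequence profiling

Composition statistics partition the 20-letter alphabet into
order-promoting {I, C, L, V, W, Y, F} and disorder-promoting
{A, G, R, D, H, Q, T, K, N, M, S, E, P} sets, so the two fractions sum to
one by construction. Molecular mass uses average (not monoisotopic) residue
masses plus one water, the convention of standard protein-parameter
calculators; the Biopython `ProtParam` table supplies the masses.

The charge–hydropathy classification follows the original recipe: the mean
net charge ⟨R⟩ at pH 7 is |#(K,R) − #(D,E)|/N, ignoring histidine and the
termini; mean hydropathy ⟨H⟩ is the Kyte–Doolittle scale rescaled to [0, 1]
by (v + 4.5)/9, averaged over all sliding windows of width 5 and then over
windows. The boundary ⟨R⟩_b = 2.785·⟨H⟩ − 1.151 separates natively folded
(below) from natively unfolded sequences; a point exactly on the line is
assigned to the native side so the classification is total. At pH ≠ 7 a
Henderson–Hasselbalch per-residue model is used instead, with an
EMBOSS-style pKa table (D 3.9, E 4.1, C 8.5, Y 10.1, H 6.5, K 10.8, R 12.5,
N-terminus 8.6, C-terminus 3.6) including both termini; the pH-7 counting
convention and the full model agree on the sign of the charge but not
exactly on its magnitude, which is why the convention is pinned at pH 7.
Default pH is 7.0 ("physiological" is ambiguous between 7.0 and 7.4; both
are accepted).

## Hydrodynamics

**SEC.** K_av = (V_e − V_0)/(V_t − V_0). Calibration fits ordinary least
squares of K_av against log₁₀ R_h and log₁₀ M independently; two standards
suffice (the line is then exact), and a relation whose standards are
degenerate is skipped with a warning rather than failing the other.
Inversion at an analyte's K_av gives R_h and an *apparent* mass — apparent
because the mass line assumes globular calibrants, which is exactly the
assumption a disordered analyte violates; values outside the calibrated
K_av span carry an extrapolation warning. No robust fitting is used
anywhere: the data volumes are tiny and outlier handling would be
unverifiable.

**Sedimentation.** Zone sedimentation in a sucrose gradient is linear in s
over the relevant range, whether the position is a fraction index or
% sucrose; a least-squares position→s line over the standards is evaluated
at the sample position. Non-monotone standards are an error; positions
outside the standards' span warn.

**Siegel–Monte.** M = s·N₀·(6πη·R_h)/(1 − ν̄₂ρ) with s in seconds
(1 S = 10⁻¹³ s), R_h in metres, η in Pa·s. Defaults η = 0.001 Pa·s and
ν̄₂ρ = 0.73 (ν̄₂ = 0.73 cm³/g, ρ = 1 g/cm³) describe a standard protein in
water. The relation is exactly linear in s and in R_h, which the tests
assert. With s = 4.2 S and R_h = 3.4 nm it gives 60.04 kDa.

**Scaling laws.** Expected R_h per conformational state follows
log₁₀ R_h[Å] = a·log₁₀ M[Da] + b with the adopted empirical set

| state | a | b |
|---|---|---|
| native | 0.369 | −0.254 |
| molten globule | 0.334 | −0.053 |
| pre-molten globule | 0.403 | −0.239 |
| urea-unfolded | 0.521 | −0.649 |
| GdmCl-unfolded | 0.543 | −0.709 |

stored in the config (more than one set exists in the literature; this one
reproduces the expected ≈3 nm for a 55.1 kDa native dimer and 3.39 nm for
the molten-globule law at the same mass). More expanded states have larger
exponents, so R_h(2M)/R_h(M) = 2^a grows with disorder.

**Q-factor.** Q = R_g/R_h with quadrature error propagation. Reference
values: uniform sphere √(3/5) ≈ 0.7746 (analytic); ideal Gaussian coil from
the Kirkwood double sum 1/R_h = N⁻²·Σ_{i≠j}√(6/π)/(b√|i−j|) with
R_g = b√(N/6), evaluated by exact summation (the double sum reduces to
Σ_k 2(N−k)/√k). At N = 10⁵ beads Q = 1.4993; the infinite-chain limit is
8/(3√π) = 1.5045. N = 10⁵ is used rather than 10⁴ because the finite-N
correction at 10⁴ (Q = 1.488) is still ~1% from the asymptote; the sum
costs milliseconds either way. Band defaults: sphere 0.775 ± 0.01, globular
0.76–0.86, molten globule 0.70–0.93, pre-molten globule 0.93–1.15, coil
≥ 1.35. The bands overlap deliberately; `q_classify` returns every band
containing Q plus "adjacent" bands whose edge is within 0.10, because a
single ratio cannot separate a molten globule from a pre-molten globule —
that is the Kratky plot's job.

## SAXS

**Guinier.** ln I = ln I₀ − q²R_g²/3, fitted by (optionally 1/σ²-weighted)
linear least squares on q². The fit window is defined in qR_g, which needs
R_g itself: starting from the lowest measured q-decade, the fit is iterated
— fit, recompute the window membership from the current R_g, refit — until
the selected point set is a fixed point (or 50 iterations; an oscillating
selection keeps the smaller window). The default window 0.759–1.294 qR_g
matches the window a PRIMUS-style analysis reports for a protein of this
size; the conventional qR_g ≤ 1.3 ceiling is in the config.

A caveat the tests document explicitly: the Guinier approximation is exact
only as q → 0. For an exact sphere form-factor curve, fitting over
0.759–1.294 qR_g overestimates R_g by a systematic 2.8% (the fourth-order
term of the sphere expansion, 3u⁴/175, differs from the Guinier
exponential's u⁴/50); for a Debye coil the same window *under*estimates R_g
by ~11%, since a coil's Guinier regime ends near qR_g ≈ 1. Sub-percent
recovery therefore requires a lower window (e.g. 0.15–0.65 for a sphere),
and the noisy-recovery property (median |ΔR_g| < 2% at 2% intensity noise
over 100 curves) is demonstrated on a 0.2–1.0 window where noise and
window-truncation bias balance. On synthetic Guinier-limit data
(I = I₀e^{−q²R_g²/3}) recovery is exact to numerical precision, which
isolates the window bias from the fitting machinery.

**Kratky.** x = qR_g, y = x²·I/I₀. The peak is the global interior maximum
after Savitzky–Golay smoothing (window 11, order 3 — exact for locally
cubic noiseless data), with prominence above 0.05·max(y), refined by
parabolic interpolation; for the Guinier-limit curve the peak is analytic,
x = √3, y = 3/e. The tail level is the mean of y over x ∈ [2.5, 4.0].
Classification: an interior peak with tail < 0.5·peak → `globular_compact`;
peak with tail ≥ 0.5·peak → `compact_plus_flexible`; no qualifying peak →
`extended`. The 0.5 threshold was set from the analytic anchors — a pure
sphere has tail/peak ≈ 0.15 and a 60/40 sphere+coil mixture ≈ 0.68, so 0.5
splits the two regimes with margin on both sides (a 0.8 threshold would
misclassify the mixture as globular). A profile not covering the tail band
is inconclusive and refuses to classify. Classification is invariant to
intensity rescaling (everything is normalized by I₀) and to q-grid
refinement.

q is nm⁻¹ internally; Å⁻¹ input is converted only on an explicit flag.
No pair-distance (P(r)) inversion is provided.

## Titrations

**Stern–Volmer.** F₀/F = 1 + K_SV[Q] with the intercept fixed at 1 (model
definition; the zero-quencher ratio is 1 identically). Linearity — the
single-accessibility-population verdict — requires both R² ≥ 0.99 and a
Wald–Wolfowitz runs test on residual signs with p ≥ 0.05, so smooth
curvature (two populations of different K_SV) fails even when R² is high.
F₀/F below 1 beyond the noise floor warns (static quenching or data error).

**Unfolding.** The two-state chemical model uses the linear-extrapolation
form ΔG = ΔG₀ − m[D] at 298.15 K with linear native and denatured
baselines, six parameters total; the thermal variant uses a van 't Hoff
two-state form (ΔH, T_m, baselines). The competing model is a plain line.
The verdict is `cooperative` only when the two-state model beats the line
by ΔAICc > 4 (a conventional "considerably less support" margin) *and* the
fitted midpoint lies inside the sampled range *and* m (or ΔH) is positive;
anything else — including non-convergence — is
`weakly_cooperative_or_linear`. A line that already fits to numerical
precision short-circuits the comparison: with both residuals at rounding
level the AICc difference is meaningless, and the richer model must not win
on noise (this is what makes the zero-noise linear case deterministic,
100/100). Fits use `scipy.optimize.curve_fit` with the midpoint initialized
where the signal crosses halfway between its endpoints.

**λ_max.** Per-spectrum maximum located by parabolic interpolation around
the grid maximum (±0.1 nm on a 1-nm grid for a Gaussian band); an edge
maximum is flagged rather than interpolated. The resulting series feeds
`fit_unfolding` like any other signal.

## State classifier

Linear additive voting. Each evidence channel carries a weight (default 1,
config-overridable) split evenly among the states it supports: CH native
side → {native, MG}; CH unfolded side → {pre-MG, coil}; each Q band maps to
its state (sphere/globular → native); the minimal-deviation scaling law →
its state; Kratky globular → native, compact-plus-flexible → MG, extended →
{pre-MG, coil}; cooperative unfolding → native, non-cooperative →
{MG, pre-MG, coil}; high ANS affinity → MG; λ_max in (330, 350) nm → MG.
Scores are normalized to sum to one; the primary state is the argmax with
ties broken by channel priority (Kratky > R_h-deviation > Q > unfolding >
CH > ANS/λ_max, reflecting the decisive role of the Kratky shape in
separating MG from pre-MG). Confidence: strong if top ≥ 0.5 and margin
≥ 0.15; weak if margin < 0.1 or fewer than two channels; else moderate.
A probabilistic model was deliberately not used: the underlying reasoning
is qualitative rule accumulation, and the additive scheme keeps every vote
auditable in the rationale. The equal default weighting is this package's
choice; sensitivity can be probed by overriding the weights.

Worked anchor: the molten-globule-like bundle (CH native side, Q = 1.03,
R_h deviation minimal at MG, compact-plus-flexible Kratky, non-cooperative
unfolding, ANS-positive, λ_max 344 nm) scores MG at 29/42 ≈ 0.69 with the
next state at 0.19 — a strong verdict; the arithmetic is frozen in the
tests. A deliberately contradictory bundle (globular Kratky + coil-band Q +
non-cooperative unfolding) yields 4/9 vs 3/9 for coil vs native — a
moderate verdict sitting just outside the weak margin, with both states
reported.

## Synthetic data

Generators emulate: sphere form factor I/I₀ = [3(sin u − u cos u)/u³]²,
Debye coil I/I₀ = 2(e^{−u²} + u² − 1)/u⁴ (u = qR_g), and intensity mixtures
of the two; SEC elution generated from a known K_av line; linear
Stern–Volmer and two-population (curved) quenching; two-state and linear
unfolding; Gaussian emission bands with drifting centres; gradient
migration linear in s; and random sequences hitting target composition
fractions within 1/length. Default q grid: 0.05–4.0 nm⁻¹, 400 points, a
beamline-style range. Both form factors switch to their series expansions
below u ≈ 10⁻² where the closed forms lose all significant digits to
cancellation.

Noise is additive Gaussian, either relative (σ as a fraction of each value)
or absolute; every generator draws from its own stream derived from
(seed, CRC32 of the generator name) through NumPy's `SeedSequence`, so
fixtures are mutually independent and byte-reproducible, and σ = 0 output
equals the analytic model exactly. What the generators do *not* emulate:
instrument smearing and beam geometry, buffer-subtraction artefacts,
inter-particle structure factors, aggregation tails, non-Gaussian counting
noise, baseline drifts, or photobleaching — so passing round-trip tests
demonstrates correctness of the analysis chain under its own assumptions,
not robustness to every pathology of real measurements.

Default study-scale parameters used by the tests and examples: sphere
radius 4.52 nm (R_g = 3.50 nm), coil R_g 3.5 nm, mixture weight 0.6;
unfolding ΔG₀ = 5 kcal/mol, m = 2 kcal/mol/M (C_m = 2.5 M), 2% relative
noise, 20-point 0–5 M urea grids, 100 seeds for recovery statistics;
K_SV = 5 M⁻¹. These sizes keep the full suite under a few seconds while
leaving the statistical assertions (median errors, 100/100 verdict counts)
well resolved.

## Known limitations

- The apparent-mass route through SEC is only as good as the globular
  calibrants; for disordered analytes it is reported as *apparent* and
  should be read against the Siegel–Monte mass.
- The reference-sequence checks (CNAG_03291, conalbumin) require FASTA
  files under `foldstate/data/reference_sequences/`, which must be fetched
  once from the public archives; they ship empty here.
- DLS-based R_h→mass conversion is not implemented (no published relation
  to reproduce); P(r) inversion and spectral deconvolution are out of
  scope.
- The classifier's weights are a design choice, not fitted to any corpus;
  its output is a structured summary of evidence, not a posterior
  probability.
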