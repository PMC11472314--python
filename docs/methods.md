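# Methods

This note records the models implemented in `membranescatter`, the defaults
and numerical choices behind them, and what the synthetic-data tests do and
do not demonstrate.

## Peptide sequence attributes

Net charge is the sum of formal side-chain charges at neutral pH
(R, K = +1; D, E = −1; His neutral). Mean hydrophobicity H is the arithmetic
mean of per-residue values over the whole sequence, and the helical
hydrophobic moment is

μH = (1/N) · | Σ_k h_k (sin kδ, cos kδ) |,  δ = 100°/residue,

computed over the full sequence (the peptides of interest are ≤ 18 residues,
so no window scanning). The magnitude is invariant under a global rotation of
the wheel, so the indexing origin is immaterial; a property test asserts
this. The default hydrophobicity scale is Fauchère–Pliska (octanol/water),
the scale used by the HeliQuest server. **Norvaline (`U`) and Tic (`X`) have
no published value on this scale**; they are mandatory arguments
(`fauchere_pliska_scale(h_nva=..., h_tic=...)`) and sequence scoring fails
loudly without them. Reported tables round H and μH to 3 decimals and μH/H to
2, with decimal (half-up) rounding to match conventional table formatting.

## CD deconvolution

Instrument ellipticity ε (mdeg) is converted to mean residue ellipticity by
MRE = ε·10⁴/N (deg·cm²/dmol), the convention appropriate for the fixed
10 μM / 1 mm measurement conditions for which the pipeline is intended; the
conversion is linear and N ≥ 1 is enforced.

A spectrum is decomposed as a convex combination of four reference spectra
(α-helix, β-sheet, β-turn, random coil). The constrained weighted
least-squares problem is solved by the squared-variable simplex
parameterization f_j = x_j²/Σx², minimized with a trust-region
least-squares solver; the underlying problem is convex in f, so the
parameterization introduces no spurious interior optima, and a test verifies
exact agreement with the KKT (equality-constrained least squares) solution on
noiseless interior mixtures. An optional fixed α:β ratio is honored exactly
by collapsing the two motifs into one component with the prescribed split;
the ratio has no default. Weights are per-wavelength; `"long-wavelength"`
down-weights λ < 215 nm by 4× (UV absorption by lipid suspensions corrupts
the short-wavelength end). Adjusted R² uses 3 free parameters (2 with a
fixed ratio).

The shipped default basis is a *parametric rendering* of the classic
poly-peptide reference band shapes (helix double minimum 208/222 nm, sheet
minimum ~217 nm, coil minimum ~198 nm) as small Gaussian sums on 200–240 nm.
It is adequate for exploration and for synthetic tests — which always treat
the basis as part of the generator, so no result depends on its provenance —
but quantitative work on measured spectra should supply a basis measured
under matching conditions.

## Diffuse-scattering elasticity (K_C, B)

### Model

The stack free energy is the discrete smectic functional: per-bilayer bending
K_C (units of k_B·T_ref, T_ref = 310.15 K) and nearest-neighbour harmonic
compression B (k_B·T_ref/Å⁴), free boundaries in the stacking direction.
Layer modes are the open-chain cosine modes with eigenvalues
B_μ = 4B sin²(μπ/2N); the in-plane continuum is restricted to
2π/L_r ≤ q ≤ π/Λ_c (Λ_c = 5 Å chain-level cutoff) and represented by a fixed
composite Gauss–Legendre node set. The node set *is* the model's in-plane
spectrum: generator, fit, analytic correlation table, Monte-Carlo sampling
oracle and brute-force pair-sum oracle all share it, which is what makes
equivalence checks at 1e-6 well-posed. Correlations scale exactly linearly
with temperature (equipartition); moduli convert to joules via k_B·T_ref.

The structure factor is the pair sum over bilayers of zeroth-order cylindrical
transforms of exp(−q_z²⟨Δu²⟩/2) over the finite domain [0, L_r]. Two
practical choices:

* **Offset averaging.** Free boundaries make ⟨Δu²⟩ depend on the pair (n, m),
  not just |n−m|; the default path averages the correlation table over pairs
  at fixed offset (the exact per-pair double sum is available via
  `per_pair=True` and is used by the tiny-instance oracle test; at N ≥ 40 the
  two agree to ~1%, and generator and fit always share one convention).
* **Quasi-specular split.** exp(−q_z²Δ/2) tends to a constant at the domain
  edge; transforming that constant over a finite disc gives an Airy-ringing
  quasi-specular sheet concentrated near q_r = 0. The constant part
  (evaluated at r = L_r) is split off analytically and excluded by default —
  experimentally it is hidden inside the beam/resolution exclusion window —
  leaving a ring-free, nonnegative diffuse term. `include_specular=True`
  restores it (used e.g. by the frozen-stack Bragg-sheet test).

Numerics: the r-quadrature uses 4-point Gauss–Legendre panels with width
≤ 10 Å (resolving the tens-of-Å correlation structure), at least 16 nodes per
J0 cycle at the largest q_r, and a geometrically graded first panel (the
correlations behave like r² log r near the origin). Bessel kernels and phase
factors are precomputed per geometry and reused across moduli, so one
structure-factor evaluation on an 80×80 map costs ~0.1 s.

### Fitting

I(q_r, q_z) ∝ S·|F(q_z)|²/q_z with a single global scale, which is profiled
out analytically. (K_C, B) are optimized in log space by bounded
least squares with seeded multi-start (default 3; ties broken by residual,
then lower K_C). Pixels with q_r below three beam-resolution widths
(default 3×10⁻³ Å⁻¹) are excluded. By default residuals are weighted by
counting statistics, σ = √max(I, 1) — the near-maximum-likelihood estimator
for count maps; unweighted fitting roughly triples the K_C dispersion at the
default noise level. Confidence intervals come from the log-space Jacobian;
B is flagged as weakly determined when its interval spans more than a decade.

### Study conditions

The synthetic condition is K_C = 20 k_BT, B = 5×10⁻⁶ k_BT/Å⁴, N = 100
bilayers, D = 64 Å, L_r = 2500 Å, T = 310.15 K, an 80×80 (q_r ≤ 0.15,
0.10 ≤ q_z ≤ 0.45 Å⁻¹) map, and Poisson-like noise calibrated so the
brightest pixel carries 1/noise² counts (5% relative at the peak by default).
B ~ 5×10⁻⁶ k_BT/Å⁴ is the fully hydrated regime in which diffuse lobes
actually exist; much stiffer coupling (B ≳ 10⁻³) locks the stack and leaves
almost no diffuse signal to fit. N = 100 stands in for the ~1800-bilayer
samples of real experiments; a convergence test shows the per-bilayer
structure factor changes by < 1% between N = 100 and N = 200 over the lobe
region (q_r ≥ 0.02 Å⁻¹); only the quasi-central spike below that still
depends on N. Recovery performance at these conditions: exact (≪1%) without
noise; median |ΔK_C| ≈ 4% over 20 seeds at 5% peak noise, with occasional
~15% excursions — the 20-seed study is therefore summarized by its median.

## WAXS chain order (S_xray)

Tilt density f(β) ∝ exp(m cos²β) sinβ on [0, π/2]; normalization and moments
are computed with adaptive quadrature on u = cosβ with the integrand scaled
by e^(−m) so arbitrarily large m stays finite.
S_xray = ⟨P₂(cosβ)⟩ is strictly increasing in m, 0 at m = 0 and → 1 as
m → ∞.

For infinitely thin rods the azimuthally averaged projection onto the
detector angle φ is I(φ) ∝ ∫_φ^{π/2} f(β) dβ/√(sin²β − sin²φ), which
evaluates in closed form to e^a I₀(a), a = m cos²φ/2 (implemented with the
exponentially scaled Bessel i0e; verified against a brute-force quadrature
oracle to 1e-6). Arc smearing and finite rod length are not modelled.

The fit profiles the linear scale and additive baseline out exactly (the
scale is constrained nonnegative — alignment brightens the equator) and
minimizes over m alone by bounded scalar search plus parabolic polishing,
so noiseless recovery reaches the machine-precision RMSE floor. A profile
whose angular falloff does not improve on a constant by an F-test-like
margin (relative RSS improvement < 4/n for the two extra parameters) is
reported as isotropic (m = 0, S = 0): a flat profile cannot determine m, and
returning the boundary value is the only stable answer.

## SDP form-factor modelling

Symmetric bilayer, origin at the midplane. Phos (phosphate + outer
headgroup), CG (carbonyl/glycerol) and CH₃ are mirrored Gaussian pairs whose
amplitudes are fixed by their molecular volumes; the hydrocarbon region is a
unit plateau with erf edges whose half-width D_C is solved (fixed point) from
CH₂ volume conservation; a peptide is a mirrored Gaussian envelope scaled by
the lipid:peptide molar ratio, and peptide density inside the core displaces
CH₂. Water fills the remainder, so occupancies sum to one identically and
each group's occupancy integrates (×A_L) to its volume (both leaflets) — the
two invariants every constructed *and fitted* model must satisfy. Models that
would exceed unit occupancy raise by default (naming the offending z); inside
a fit they instead contribute a smooth penalty on the integrated overfill,
and the result records feasibility.

Electron density is ρ(z) = Σ (e_i/V_i)P_i(z); |F| is the cosine transform of
the contrast against water, evaluated with cached Simpson-weighted transform
matrices on a 0.025 Å half-grid to ±45 Å (agrees with the closed-form
Gaussian transform to better than 1e-8). D_HH is twice the parabolic-refined
outer maximum of the Phos+CG electron density; 2D_C is the FWHM of the
CH₂+CH₃ occupancy; A_L is a model parameter.

### Fitting and identifiability

Experimental |F| carry an arbitrary per-sample scale, profiled out
analytically; χ² uses supplied uncertainties (unit weights otherwise) and is
reported per degree of freedom. On a relative scale, |F| alone does **not**
determine all profile parameters: without further constraints the area per
lipid trades against edge/head widths (±5 Å² excursions at 2% noise, with a
mimic branch near A_L ≈ 97 Å²). Like other SDP implementations, the fitter
therefore applies soft Gaussian restraints toward the template: widths
essentially fixed (σ_prior = 0.05 Å; they are known from prior structural
work, not from one relative-scale dataset), head positions ±0.3 Å,
A_L ±5 Å². Peptide envelope centers are unrestrained; its width is
restrained (±1 Å) and bounded to 1.5–4.5 Å. Peptide-location hypotheses
bound the envelope center: hydrocarbon |z| ∈ [0, D_C], headgroup
|z| ∈ [D_C, z_Phos + 10 Å], "both" uses two envelopes with a fitted volume
split. Hypothesis fits for peptide samples should use A_L bounds from the
control fit (±15 Å² here) — hierarchical fitting; without that, the wrong
hypothesis can escape to the mimic branch. Selection is argmin χ², with an
ambiguity flag when the two best differ by < 5%.

### Default composition and study conditions

`data/lipid_components.yaml` holds rounded literature-style effective
one-lipid volumes/electrons for the three membrane mimics (mixtures are
collapsed to one effective lipid because one EDP is fitted per mixture); the
G(−) defaults with A_L = 71 Å² give the canonical control geometry
D_HH = 39.8 Å, 2D_C = 29.0 Å. These constants parameterize the *generator*;
no test depends on their literature accuracy. The peptide envelope default is
a 16-residue AMP (V ≈ 3600 Å³, 1580 e) at 50:1 lipid:peptide — the ratio at
which component EDPs are usually displayed; at 20:1 a headgroup envelope
would exceed unit occupancy in this volume-conserving parameterization.
Recovery at 2% noise (10 seeds, median |error|): A_L 0.45 Å², D_HH 0.25 Å,
2D_C 0.18 Å. Peptide-location selection at 3% noise: 20/20 seeded replicates
correct (the test suite requires at least 90%).

## Synthetic data and noise models

Every generator evaluates its forward model at known parameters, adds the
stated noise, and returns a `GroundTruthBundle` (generator name, parameters,
seed, noise model) — the only source of truth the recovery harness reads.
Same seed ⇒ bit-identical data. Defaults: 2% Gaussian noise (fraction of the
peak signal) for CD spectra, WAXS profiles and |F|; Poisson-like counting
noise for diffuse maps (Gaussian with variance = counts, the large-count
limit), applied to the symmetrized q_r ≥ 0 representation so the lateral
symmetry is preserved. |F| data receive a hidden log-uniform scale in
[0.5, 2], recorded in the bundle, to emulate the arbitrary experimental
normalization.

What passing these tests shows: the estimators invert their own forward
models correctly at realistic noise, sizes and parameter regimes, and the
implementations agree with independent oracles. What they do not show:
robustness to the systematic effects of real measurements — background
subtraction residuals, absorption and footprint corrections, mosaicity,
basis-set mismatch in CD, asymmetric bilayers, or volume constants that
differ from the shipped defaults.

## Known limitations

* Bilayers are symmetric; asymmetric leaflets and neutron contrast variants
  are out of scope.
* The WAXS projection ignores arc smearing and finite rod length.
* B is often weakly determined by diffuse maps; it is reported with its
  confidence interval and a flag rather than suppressed.
* The detector-image reader maps pixels to (q_r, q_z) along the beam-center
  axes (flat detector, small-angle approximation transverse to each axis);
  full curvilinear regridding is not implemented.
* CD deconvolution is a linear four-motif model; modern SVD/library methods
  (CONTIN/CDSSTR) are deliberately not reimplemented.
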