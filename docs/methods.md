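# Methods

## Scope and model

`sandlam` reduces lamellar small-angle neutron diffraction data from
aligned multibilayers and analyses coarse-grained bilayer trajectories.
The structural model is one-dimensional and centrosymmetric: everything is
expressed as functions of the transbilayer coordinate z, with z = 0 at the
bilayer center and the unit cell spanning [−D/2, D/2]. Phases of the
lamellar reflections therefore reduce to signs.

Units: lengths in Å; NSLD in 10⁻⁶ Å⁻²; coherent scattering lengths b in fm
and molecular volumes V in Å³, related by ρ = 10·b/V; sample thickness t in
cm with μ in cm⁻¹; sample length l and beam σ in mm. Angles are 2θ in
degrees at every I/O boundary and θ in radians internally.

## Reduction chain

1. **Rocking scans.** Each reflection is measured as an ω-scan; a
   Gauss+Lorentz (mosaic + diffuse) peak with constant background
   quantifies the orientation spread (σ_G, degrees). Peak areas come from
   Gaussian-plus-background fits; the integrated intensity is the analytic
   Gaussian area normalized to monitor counts, with σ_I from the fit
   covariance. Scans with no significant peak produce flagged results, not
   exceptions, so batch reductions keep going; amplitudes consistent with
   zero yield intensity 0 with a flag.
2. **Indexing.** D is the least-squares solution of 2D·sin θₕ = hλ over
   all reflections. If supplied order labels leave an RMS angular residual
   above 0.05°, consecutive labelings starting at h = 1 (the lamellar
   first order is always present) are tried and the best is adopted with a
   warning; failure names the worst reflection.
3. **Corrections.** |Fₕ| = (Iₕ/(L_f·A_c·F_c))^½ with L_f = 1/sin 2θ,
   A_c = (1 − e⁻ˣ)/x for x = 2μt/sin θ (Taylor branch below x = 10⁻⁴ so the
   μ → 0 limit is exact to float precision), and F_c = erf(l·sin θ/(8σ)).
   The 8σ denominator is implemented as printed in the source convention;
   a `sqrt8_sigma` variant (Gaussian-beam reading) is selectable because
   the two conventions cannot be distinguished a priori. μ is
   user-supplied per contrast — it depends on lipid, thickness and the
   D₂O/H₂O ratio.
4. **Phasing by contrast variation.** For a rigid bilayer the signed Fₕ is
   exactly affine in the water NSLD ρ_w. Per order, the relative signs
   across contrasts are found by exhaustive search for the pattern most
   linear in ρ_w (signed factors may legitimately cross zero between 8%
   and 50% D₂O). The remaining per-order flips are resolved physically:
   the slope vector dFₕ/dρ_w is k times the cosine transform of the water
   distribution, so each of the ≤ 2^hmax flip candidates is fitted against
   the analytic coefficients of an error-function water slab
   (coarse grid over midpoint/width, then continuous least squares); the
   best-fitting candidate wins and a positive slab amplitude (water at the
   cell edge, not the center) fixes the global sign. When forward-
   scattering values are available, the Gibbs identity ∫w dz = ΔF₀ᵃᵇˢ/Δρ_w
   pins the slab midpoint and removes a genuine midpoint/sign degeneracy
   of the slab family; the pipeline always exploits this. Orders with
   near-zero contrast leverage are flagged (`low_leverage_orders`,
   `indeterminate_orders`) rather than silently guessed, and near-tied
   sign patterns are reported as ambiguous with the runner-up.
5. **Absolute scale.** k maps the count-derived factors to the NSLD scale.
   The criterion is that the reconstructed water distribution have a unit
   interbilayer plateau. Two deterministic estimators are provided: the
   direct plateau mean (outer 10% of the cell), and the default
   coefficient-space fit of ⟨ΔFₕ/Δρ_w⟩ to an error-function slab, which is
   free of series-truncation bias (a 5-order plateau mean is biased by a
   few percent; the coefficient fit recovers the generator scale to
   ≲ 10⁻⁵ relative on noiseless data).
6. **Profiles and structure.** ρ(z) is synthesized on a mirror-symmetric
   grid (default 0.5 Å — well below the ~D/2hmax resolution of 5–6 order
   data) and is exactly even by construction; its cell mean equals
   F₀ᵃᵇˢ/D to float precision. D_HH is the distance between the two
   headgroup maxima of the profile at the water-nulling contrast, each
   located by 3-point parabolic interpolation (deterministic and honest
   about the series resolution; no splines). The water distribution is the
   Δρ_w²-weighted average of pairwise profile differences divided by their
   water-NSLD differences; pairs closer than 10⁻³ NSLD units are skipped.
   Its plateau normalization is truncation-consistent: the measured
   plateau mean is referenced to the plateau mean a unit erf slab would
   show after the same truncation. D_B = 2 × the error-function midpoint
   fitted per side and averaged (robust to residual asymmetry); the
   mean-position (Gibbs integral) estimator is always computed alongside
   and used as a flagged fallback. D_W = D − D_B exactly. The area per
   unit cell follows the volumetric identity A = 2(V_l + x·V_a)/D_B (unit
   cell: one lipid plus x alcohols; A·D_B = 2(V_l + x·V_a) is asserted on
   every record), and the interlamellar water count uses the half-slab
   convention n_W = A·D_W/(2V_w) — every output header states this,
   because the factor of two is the field's most common confusion.

## Forward model (synthetic data)

The generator's profile is headgroup Gaussians at ±z_H, a methyl-trough
Gaussian at z = 0, a hydrocarbon plateau confined to the non-water region,
and water entering through an error-function step with midpoint ±z_IF (the
Gibbs surface, so true D_B = 2·z_IF) and width σ_IF. Defaults emulate a
vapor-hydrated fluid-phase DOPC-like bilayer: D = 55 Å, z_H = 18.2 Å,
σ_H = 3 Å, z_IF = 19.5 Å, σ_IF = 2 Å, headgroup amplitude 2.2, methyl
−0.25, chain plateau −0.35 (10⁻⁶ Å⁻²). Water NSLD versus D₂O fraction is
derived from Sears coherent scattering lengths and V_w = 30 Å³, which
places the contrast-match (water-nulling) point at 8.04% D₂O — the reason
the 8% contrast reads out the bilayer alone. The random model ensemble
used in recovery studies draws D ∈ [52, 60] Å, z_H ∈ [16, 19] Å,
z_IF − z_H ∈ [1, 3] Å, σ_IF ∈ [1.5, 2.5] Å and amplitudes over typical
protiated-lipid ranges.

Simulated intensities run the correction chain forwards,
Iₕ = k²·Fₕ²·L_f·A_c·F_c, with Gaussian counting noise σ = noise_scale·√I —
the Gaussian approximation to Poisson statistics keeps the generator
simple and reproducible from a single seed. Reflections whose Bragg angle
is undefined are dropped with a warning. Synthetic coordinate frames
realize a prescribed ensemble P2 by mixing aligned (P2 = 1) or in-plane
(P2 = −½) bonds with an isotropic background, attaining the endpoints
exactly; uniform 2D Poisson point sets and commensurate triangular
lattices serve as RDF null and peak fixtures.

What the generator does **not** emulate: instrument background shapes,
detector pixelation, multiple scattering, mosaic broadening of peak
shapes coupled to order, inter-order correlated noise, or asymmetric
(non-centrosymmetric) bilayers. Passing round-trip tests therefore
demonstrates correctness of the reduction algebra and estimator behavior
under counting noise, not immunity to instrument systematics.

## Trajectory observables

P2 = ½(3⟨cos²θ⟩ − 1) per bond type, pooled over frames and molecules (the
ensemble bracket is a pooled average; per-frame weighting would differ
only if frame populations varied). The bilayer center is the per-frame
mean coordinate of all lipid beads — robust to membrane drift — and
leaflets are assigned by the sign of the centered coordinate, so particles
mid-flip near z = 0 are assigned by instantaneous sign (documented
limitation). Density profiles are leaflet-folded onto |z| with the
[5th, 95th] percentile span reported; bin counts sum exactly to the
selection size. The lateral RDF uses minimum-image distances in the two
lateral box directions and 2D ideal-gas normalization (g → 1 for
homogeneous systems); r_max may not exceed half the smallest lateral box
length. Only orthorhombic periodic boxes are supported (semi-isotropic
simulation cells satisfy this).

## Numerical choices

- Structure factors are trapezoid integrals over the closed cell; for
  profiles whose features decay inside the cell this is spectrally
  accurate (the periodic extension is smooth), and a half-spacing
  refinement changes nothing at the 10⁻⁶ level.
- The Fourier synthesis symmetrizes the cosine series to the last bit so
  the evenness invariant holds exactly despite SIMD summation order.
- Fit initializations are data-derived (center of mass, FWHM estimate,
  plateau scale, Gibbs-integral midpoint), making every estimator
  deterministic; non-convergence always surfaces as a flag or a named
  error, never a silent fallback.
- The hydration extrapolation D(t) = D_∞ − ΔD·e^(−t/τ) accepts negative ΔD
  (approach from above); a fitted τ longer than twice the observation
  window flags the series as non-saturating and returns the last value.

## Known limitations

- Absolute areas depend on user-supplied molecular volumes; the shipped
  defaults (V_DOPC = 1303 Å³, group-contribution alcohol volumes) are
  literature-sourced conveniences, and only identities and trends — not
  absolute A — are validated.
- Orders with vanishing water-slope leverage have contrast-variation-
  indeterminate overall signs; they are flagged, and their weight in the
  synthesis is correspondingly small, but a pathological structure could
  defeat the slab-template resolution.
- The reduction starts from ω-scan arrays or integrated peak tables; 2D
  detector-image geometry is instrument-specific and out of scope, as are
  absolute flux calibration and detector efficiency maps.
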