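# Methods

This note records the models implemented in leafletlab, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Isotherm mechanics

The static compression modulus is ε(π) = −A·dπ/dA evaluated along the
compression branch (identified as the longest strictly-decreasing-area
run; expansion branches are ignored). Because experimental isotherms are
noisy and no canonical differentiation scheme exists, the derivative is
estimated by local polynomial (Savitzky–Golay-style) fits; `window`
(default 11 points, odd) and `polyorder` (default 2) are user
parameters, and the local-fit formulation works on non-uniform area
grids. The estimator is checked against central finite differences on
dense noiseless grids (≤0.5% disagreement) and against the closed form
ε = π of the 2D ideal gas.

Lift-off is the largest area at which the (lightly smoothed) pressure
exceeds a threshold, located by linear interpolation; the default
threshold of 0.5 mN/m sits above typical Wilhelmy-plate noise — no
standard numeric criterion exists, so it is exposed as a parameter, and
`window=1` disables smoothing for noiseless model curves.

Gradient segmentation fits a *continuous* piecewise-linear model of
π(A) to the post-lift-off region (1–3 segments). Breakpoints are found
by profiling the linear-least-squares residual over a coarse grid and
refining with Nelder–Mead; slopes are reported as |dπ/dA| together with
the pressure range each segment covers. Fit ranges are user-controlled
rather than guessed.

Units are fixed throughout: Å²/molecule, mN/m, and kT expressed in
mN/m·Å² (1 mN/m·Å² = 1e-23 J, so kT at 293 K is 404.5 mN/m·Å²).

## Dilatational rheology

A step compression of magnitude u = |ΔA/A₀| (≤ 0.05 enforced) produces a
relaxing pressure excess modelled as Δπ(t) = Δπ∞ + Σ Aᵢ e^(−t/τᵢ).
Fitting uses bounded nonlinear least squares (τ parametrised in log
space) with multi-start initial relaxation times log-spaced over the
record, for each candidate mode count 0..max_modes; the returned model
minimises the small-sample-corrected Akaike criterion. The residual sum
of squares is floored at numerical noise (10⁻⁹ of the signal scale) so
that machine-precision fits of different mode counts tie and the AICc
penalty selects the most parsimonious model. A flat transient returns
zero modes with Δπ∞ equal to the mean.

The frequency-domain modulus is evaluated **analytically on the fitted
model** rather than by FFT of raw data: for a step strain
(d lnA/dt = −u·δ(t)) the transform of the Prony series is

    G′(ω) = (Δπ∞ + Σ Aᵢ ω²τᵢ²/(1+ω²τᵢ²))/u
    G″(ω) = (Σ Aᵢ ωτᵢ/(1+ω²τᵢ²))/u,   ω = 2πν.

FFTs of short noisy transients are ill-conditioned; the analytic route is
exact for the fitted model and is verified against a trapezoidal
numerical transform of the densely sampled transient (with an analytic
exponential tail correction) to ≤1%. u approximates |Δ ln A| by |ΔA/A₀|;
at the 5% perturbation ceiling the difference is <2.6%. Compression
gives Δπ > 0 and ΔA < 0; u is stored as a magnitude.

Cole–Cole analysis fits a circle centred on the G′ axis by linear least
squares on G′² + G″² = 2cG′ + (r² − c²) and scores the RMS geometric
distance to the circle normalised by the radius. A single Maxwell mode
is an exact semicircle (score ~1e-15); a score above 0.05 is taken to
indicate multi-step relaxation (the threshold is a convention — the
distinction is qualitative). The plateau modulus is the mean G′ over a
band (default ν > 100 mHz), flagged non-plateau when the relative spread
exceeds 5%.

## X-ray reflectivity

The interface is a slab stack (acyl tails / headgroups / semi-infinite
subphase at 0.334 e⁻/Å³ unless overridden). Reflectivity uses the
Parratt recursion — a dynamical treatment, required near the critical
edge q_c = 4√(π r_e ρ_e) where the Born approximation fails — with
Névot–Croce factors exp(−2k_{z,i}k_{z,i+1}σ²) for Gaussian interfacial
roughness. Electron density maps to the index of refraction through
δ = r_e λ²ρ_e/2π with r_e = 2.818e-5 Å; absorption is negligible for an
organic film at 8 keV and is not modelled. The implementation is checked
against an independently coded Abeles transfer-matrix oracle to 1e-10
relative.

Fitting minimises residuals of log R with uniform weights (the curve
spans many decades); parameters are per-slab thickness, density and
roughness plus the subphase roughness, each with bounds, any of them
pinnable. 1σ uncertainties come from the least-squares covariance;
parameters that land on a bound are flagged. The first minimum of R/R_F
is located on the grid (requiring a dip of at least 5% below the running
maximum, so numerical ripples on a featureless curve are not reported as
minima) and refined by a parabola through log R/R_F. Density profiles
are sums of erf-smeared steps; the σ→0 limit is the exact step profile,
and the excess integral ∫(ρ − subphase step) dz = Σρᵢdᵢ is conserved
under any roughness.

z increases from air into the subphase with z = 0 at the air/tail
interface. Note that R/R_F does **not** tend to 1 at large q_z for a
sharp multi-interface stack — it oscillates about a contrast-dependent
constant — and decays below 1 for rough interfaces.

## GIXD

q_xy = (4π/λ)sin(2θ_h/2) and q_z = (2π/λ)sin α_f are evaluated exactly.
Peak fitting is least squares of a single peak plus linear background;
the default shape is Lorentzian (the 2D-powder convention), with
Gaussian and 50/50 pseudo-Voigt selectable. d = 2π/q₀ and
L_c = 0.9·2π/fwhm are stored-field identities with uncertainties
propagated from the fit covariance. Instrument-resolution broadening is
not deconvolved — L_c is a Scherrer estimate on the raw width. A fitted
amplitude below 3× the residual noise SD raises a no-significant-peak
error; between 3σ and 5σ the peak is kept but flagged weak ("barely
visible"). Classification: one in-plane peak with the Bragg-rod maximum
at the horizon (|q_z| < 0.1 Å⁻¹ by default) → hexagonal untilted; two or
more resolved peaks or an off-horizon rod maximum → tilted; no peak →
disordered (diffuse halo).

## Trajectory operators

The trajectory container is a static atom table plus (frame, atom, 3)
coordinates in an orthorhombic box, periodic in x and y; fully periodic
test boxes opt in via `periodic_z`. Leaflets are assigned by the sign of
a lipid's mean z relative to the water midplane. The analysis window for
production trajectories defaults to the trailing 5% of frames
(`tail_frames`), and SEMs use 10-block averaging over frames.

*Voronoi area per lipid*: headgroup reference points (three per
phospholipid, one per sterol, so small sterol headgroups are not
over-weighted; defaults N/P/glycerol-C2 and sterol O3) are tessellated
per leaflet with periodicity implemented by 8-image replication before
`scipy.spatial.Voronoi` — exact whenever cells are smaller than the box.
A lipid's area is the sum of its reference-point cells; coincident
points are jittered by 1e-6 Å with a warning. Cell areas tile the box
to 1e-9 relative and agree with Monte-Carlo nearest-point integration.

*Order parameters*: S_CD = −½(3cos²β − 1) per C–H bond against +z,
averaged over bonds, molecules and frames per carbon index. Methylene
geometry confines the per-carbon mean to [−0.5, 1.0]; values outside
(e.g. C–H bonds parallel to the normal) are flagged as geometry errors.
Hydrogens must be explicit — there is no reconstruction; the toy
generator supplies them.

*Thickness*: tail = ⟨|z(terminal C) − z(carbonyl C)|⟩, head =
⟨|z(carbonyl C) − z(P)|⟩, total = tail + head; sterols (no phosphorus)
are excluded. *Electron density*: per-atom electron counts from the
topology (element fallback), histogrammed along z and divided by bin
volume; the two monolayers are averaged after reflection about the water
midplane (optional). *Contacts*: atom-pair events within 4.0 Å
(minimum image), normalised by the total number of atom-pair contact
events for the species pair — the alternative per-molecule-pair
normalisation is documented but not used. *Hydrogen bonds*: geometric
criterion d(D,A) < 3.5 Å and ∠D–H–A > 150°, intermolecular only, one
bond per donor–acceptor pair per frame. *RDF*: shell-histogram
estimator g(r) = ρ_{r,α,β}/ρ_β with minimum-image distances (k-d tree
acceleration for large fully periodic systems); r_max ≤ half the
smallest box edge. *Hydration*: the monolayer surface defaults to the
headgroup heavy atoms (configurable); the minimum-distance histogram is
normalised by box area × bin width × bulk density 0.0334 Å⁻³ so it
plateaus at 1 in bulk water, and per-atom hydration maps (water oxygen
within 4.0 Å) are normalised to sum to 1 over a molecule's heavy atoms.

All pairwise operators are verified against brute-force O(N²)/O(N³)
enumerations on small frames.

## Synthetic data

The generators are pure functions of (parameters, seed); noiseless
outputs are exact fixed points of the corresponding analysis stage.

- *Isotherms*: 2D ideal gas (π = kT/A), a van-der-Waals-like law
  (π = kT/(A−A₀) − a/A²), and a piecewise-linear law reproducing the
  two-gradient phenomenology of condensed mixed films (lift-off 64 Å²,
  slopes 3 then 9 mN m⁻¹ Å⁻² breaking at 22 mN/m as the CLI default —
  the regime reported for oxysterol-containing films). Noise is
  additive Gaussian.
- *Transients*: the Prony series plus additive Gaussian noise, with the
  ≤5% perturbation bound enforced.
- *Reflectivity*: the forward model with multiplicative log-normal noise
  (counting statistics act multiplicatively on a curve spanning
  decades). The default stack (17.3 Å tails at 0.30 e⁻/Å³, 9.0 Å heads
  at 0.45 e⁻/Å³, 3 Å roughness) uses literature-typical densities for
  condensed phospholipid films.
- *GIXD*: a single peak of chosen shape on a linear background with
  additive Gaussian noise.
- *Toy monolayers*: two leaflets of lattice-placed lipids (hexagonal,
  square or random; hexagonal placement requires a factorisation with an
  even row count for periodicity) facing a central water slab of
  randomly placed and oriented 3-site molecules at the bulk number
  density 0.0334 Å⁻³. All-trans chains are ideal zig-zags (C–C 1.54 Å,
  1.27 Å rise) with both C–H bonds perpendicular to the chain axis so
  that S_CD closed forms are exact (0.5 for vertical chains); random
  walks give disordered chains. Toy species are deliberately minimal
  (an N/P/C2 head triad with two explicit-hydrogen tails; a sterol with
  an O3 hydroxyl and a rigid C3→C17 axis).

What the generators do **not** emulate: real conformational ensembles,
force-field energetics, capillary waves, instrument resolution and
backgrounds beyond a linear term, or inter-species interactions. Passing
tests therefore demonstrate the correctness of the estimators and fits,
not the fidelity of any particular experimental system. Instrument noise
magnitudes are placeholders, not calibrated to any spectrometer.

## Problem sizes and numerical choices

Default problem sizes keep the suite quick while leaving comfortable
statistical margins: 400–1200-point curves, 10–20 noise realisations for
recovery studies, 1e5-sample angular averages, 1e7-sample Monte-Carlo
Voronoi checks, and 1e4-point ideal-gas RDFs. Fits use scipy/lmfit
Levenberg–Marquardt or trust-region reflective with analytic forward
models; degenerate inputs (flat transients, featureless patterns, zero
contacts, absent water) raise informative errors rather than returning
numbers.

## Limitations

- The rheology transform assumes an ideal step strain; finite
  compression times (<1 s in practice) bias moduli above ~1 Hz.
- Single-peak GIXD analysis cannot index multi-peak patterns; tilt
  angles are classified, not quantified.
- The XRR fit is a local optimiser: like all reflectivity fitting it can
  park in local minima for poor starting models; multi-start at the user
  level is recommended for blind fits.
- The contact-map normalisation choice (atom-pair events) changes
  absolute values relative to per-molecule-pair normalisation, though
  not the relative pattern within a map.
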