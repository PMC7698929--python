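# Methods

This note documents the models behind `tpmflex`, the defaults that matter,
the numerical choices, and what the synthetic-data generators do and do not
emulate.

## Discrete worm-like chain generator

A chain is a sequence of `n_segments` rigid segments of length `b`
(`segment_length`, nm). Successive tangents differ by a random bend θ whose
cosine is distributed as p(cos θ) ∝ exp(κ cos θ) on [−1, 1] — the von
Mises–Fisher (vMF) polar distribution — with azimuth uniform. This is the
exact Boltzmann distribution for a discretized bending energy
E = κ k_BT (1 − cos θ), so the concentration maps onto the persistence
length as κ = L_p / b. Two closed forms follow and serve as independent
oracles in the tests:

* ⟨cos θ⟩ = coth κ − 1/κ (Langevin function offset), sampled by inverse CDF
  cos θ = 1 + ln(u + (1−u)e^{−2κ})/κ; for κ > 350 the e^{−2κ} term is
  dropped (it underflows and is negligible).
* ⟨t(0)·t(kb)⟩ = (coth κ − 1/κ)^k, which approaches exp(−kb/L_p) for stiff
  chains (within 2% for κ ≥ 50).

An optional deterministic bend (`intrinsic_curvature`, rad/joint) is
composed *before* the random bend as a rotation in the chain's material
plane; the material frame is propagated by parallel transport (minimal
rotations), so no spurious twist accumulates. Chains start at the origin
with the first tangent on +z. Everything is driven by one
`numpy.random.default_rng(seed)` and is bit-reproducible.

Default ensemble (3000 chains × 30 × 1.4 nm, L_p = 161 nm) mirrors the
situation the estimator is meant for: a filament about 42 nm long, i.e.
roughly a quarter of its persistence length, sampled by a few thousand
statistically independent snapshots.

## Skeletonization

Nodes are weighted centroids of the Cα atoms of `window` (default 11)
consecutive residues; the first and last residue of each window carry weight
`end_weight` (default 0.5), giving a normalizer of 10 at the defaults. With
`step = window − 1 = 10`, consecutive windows share exactly one boundary
residue, which therefore contributes total weight 1 across its two windows —
the only stepping consistent with the half-weights. Trailing residues that
do not fill a window are dropped (284 residues → 28 nodes, 3 dropped) and
the count is logged. By default the two chains' atoms are pooled into one
axis (a centroid over 22 Cα per node); a per-chain-averaged mode exists
because either reading of "each polypeptide chain" is defensible, and the
two agree to ~0.1 nm on idealized geometry. Arc length s is the cumulative
Euclidean distance along the node polyline. Skeletonization is exactly
equivariant under rigid motions and its node count depends only on residue
count and scheme.

## Superposition and the secant persistence length

Tangents are normalized node differences positioned at segment arc
midpoints; the reference field t₀(s) is the time average of t(s),
renormalized to unit length (the raw average is sub-unit; renormalization is
toggleable). C(s) = ⟨t(s)·t₀(s)⟩ is fitted as ln C(s) = −s/L_p by weighted
least squares, through the origin by default since C(0) = 1 by construction
(a free-intercept option is kept for diagnostics). When no fit range is
given, the fit runs from the first midpoint to min(total length,
L_p-estimate/2), iterated once from a full-range fit. Points with C ≤ 0 are
excluded and counted. A non-negative slope is reported as an
infinite-persistence flag, not an exception. K = L_p·k_BT with k_BT
defaulting to 4.1 pN·nm (T ≈ 297 K), the unique value consistent with the
standard (L_p, K) pairs 161/660, 218/894 and 203/832.

Superposing only the first *segment* leaves the spin about that tangent
undefined, so two modes exist:

* `first-two-segments` (default): least-squares rotation of nodes {0, 1, 2}
  onto the ensemble-mean leading triad (reference refined once). This fixes
  the torsion and is the right choice for atomistic skeletons, whose leading
  triad carries real orientational information.
* `first-segment`: minimal geodesic rotation of the first tangent onto the
  mean first-tangent direction.

The report always quantifies the disagreement by computing L_p under both
modes. For the synthetic WLC ensemble — whose first tangents are *exactly*
aligned by construction — the first-segment mode is the exact statistic, and
it is what the recovery tests and the acceptance script use. The triad mode
partially aligns the second tangent with the reference, inflating C(s) at
small s and biasing L_p upward by up to ~10% on such ensembles.

Known bias: C at segment k equals m^k (m = coth κ − 1/κ) while the midpoint
abscissa is s_k = (k + ½)b, so the through-origin fit overestimates L_p by
roughly b·⟨s⟩/(2⟨s²⟩) ≈ 2–4% at the default geometry. This is documented
rather than corrected because the midpoint convention is the natural
placement for a polygonal axis; the auxiliary nearest-neighbour estimator
(L_p = −b/ln⟨t_k·t_{k+1}⟩) is bias-free for this generator and is reported
alongside.

## Coiled-coil fixture

An ideal α-helix backbone (φ = −57°, ψ = −47°, standard bond geometry) is
built by internal-coordinate (NeRF) chain extension, aligned to the z axis
via its inter-residue screw transform, optionally rescaled to a requested
Cα radius / rise / twist, and wrapped onto a superhelical axis of radius
4.9 Å and pitch 140 Å (phases 0 and π for the two parallel chains), treating
the straight-chain z as arclength along the superhelix. Zero superhelix
radius degenerates to straight helices with axes on z. Amide hydrogens sit
1.01 Å from N opposing the C(i−1)–N / Cα–N bisector; carbonyl O opposes the
Cα–C / N(i+1)–C bisector at 1.231 Å. The defaults are literature-standard
dimeric coiled-coil values and are fixture geometry for the skeleton and
h-bond tests, not structural claims about any particular protein.

## Hydrogen bonds

Criterion: N···O ≤ 0.35 nm and H–N···O angle ≤ 30° (the de-facto default of
common MD analysis tools; both are configurable). The alternative
deviation-from-linearity convention at the hydrogen is available as
`angle_convention="dha"` because tools differ. Only backbone N–H donors and
C=O acceptors are considered; within a chain a sequence separation |i−j| ≥ 3
is required, inter-chain pairs are unrestricted. Occupancy is attributed to
the donor residue (acceptor attribution is an option) and averaged over the
two chains for identical residue numbers. Missing amide hydrogens are
reconstructed geometrically before detection. Enlarging either cutoff can
only add bonds, so occupancies are monotone in the criterion — asserted as a
property test.

## DSC deconvolution

Model: Cp(T) = Σᵢ ΔH_cal,i ΔH_vH,i/(R T²) · Kᵢ/(1+Kᵢ)² with
Kᵢ = exp[−(ΔH_vH,i/R)(1/T − 1/T_m,i)], temperatures in kelvin internally
(interfaces in °C), R = 8.3145×10⁻³ kJ·mol⁻¹·K⁻¹. The integral of each term
over T is exactly ΔH_cal,i regardless of ΔH_vH,i — a conservation law the
generator and the fit are both tested against. Each domain is parameterized
as (Tm, ΔH_cal, r) with ΔH_vH = r·ΔH_cal and r bounded in [0.2, 5]; the
bound keeps the deconvolution identifiable (unbounded ΔH_vH lets two
domains mimic one). Auto-initialization places Tm at the largest local
maxima (falling back to grid quantiles with a warning when a domain is only
a shoulder) and splits the integral equally. Fitted domains are reported
sorted by Tm, ties broken by ΔH_cal; permuting the initial order does not
change the fitted multiset. Input is assumed baseline-corrected excess heat
capacity; instrument/buffer correction is upstream.

## Dissociation, Hill, load and saturation fits

* Dissociation: y(T) = lower + (upper−lower)/(1+exp((T−T_diss)/w)), fitted
  with scipy `curve_fit`; T_diss is constrained to the data range and the
  fit rejects monotone-increasing input as wrong-signed. The fitted value
  at T_diss is the exact plateau midpoint (model identity).
* Hill: v = v_max(1+10^{n(pCa−pCa₅₀)})⁻¹, unweighted by default (per-point
  sigmas optional), initialized at v_max = max v, pCa₅₀ = pCa of the
  half-max point, n = 2. Flat data raises a non-identifiability error.
  Velocity rescaling multiplies v_max and leaves pCa₅₀ and n unchanged.
* NEM load line: ordinary least squares on points with v > 0 only — stopped
  filaments carry no information about where velocity crosses zero, the
  quantity is an extrapolation; the x-intercept −intercept/slope is the stop
  fraction, and a non-negative slope is an error.
* Saturation: f = plateau·cʰ/(K₅₀ʰ + cʰ) with the binding Hill slope h
  fitted by default (constrainable, e.g. h = 1 for hyperbolic binding);
  non-saturating data is flagged with a warning rather than rejected.

## What the synthetic data does and does not emulate

The generators reproduce the *statistical structure* each estimator assumes:
vMF-bent chains with exactly known L_p, ideal helical geometry whose h-bonds
satisfy the criterion by construction, exact sums of non-two-state
transitions, and curves with additive Gaussian noise. They do not emulate
solvent, force-field energetics, time correlation between frames (chains
are independent, whereas MD snapshots are autocorrelated, so real effective
sample sizes are smaller), anharmonic or sequence-dependent flexibility,
instrument baselines, or irreversible aggregation in melts. Passing
recovery tests therefore demonstrates correctness of the estimators under
their own model assumptions — not that those assumptions hold for any given
experimental system.

## Problem sizes and tolerances

Recovery tests and the acceptance script use 3000 chains × 30 segments
(≈ 10⁵ joints) for the stiffness estimator — enough that Monte-Carlo scatter
in L_p is ~2–3%, well inside the 10% recovery criterion — and grids of a few
hundred points for the curve fits. Nonlinear fits use scipy defaults except
`xtol = ftol = 1e-12` for the DSC deconvolution (the three-domain
recovery is sensitive to early termination). Curve noise levels (0.15 µm/s
for velocities, 0.02 for normalized scattering, 0.2 µm/s for load lines)
match the per-point scatter typical of the corresponding assays.

## Known limitations

* Multi-model PDB is the only trajectory format read natively; binary MD
  formats should be converted upstream (any trajectory tool can emit
  multi-model PDB). Periodic-boundary-broken molecules are not repaired.
* The midpoint-abscissa bias above (~2–4% at default geometry) is inherent
  to the through-origin secant fit on short chains.
* DSC domains closer than their widths may swap identities between inits;
  only the Tm-sorted multiset is stable.
* The saturation fit assumes a plateau exists within ~an order of magnitude
  of the sampled concentrations; far outside that, only the warning flag is
  meaningful.
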