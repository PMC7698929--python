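# tpmflex

Analysis pipeline for the mechanics and stability of two-chain α-helical
coiled-coil filaments such as tropomyosin (Tpm): bending-stiffness
(persistence-length) estimation from multi-frame structural ensembles,
backbone hydrogen-bond occupancy profiling, DSC thermogram deconvolution,
thermal-dissociation fitting, and in vitro motility curve fitting. A
first-class synthetic-data module generates every input with known ground
truth, so the whole pipeline is testable without any external dataset.

## Who it is for

Structural biophysicists who simulate or measure semi-flexible filamentous
proteins and want one consistent, tested toolchain from raw frames/curves to
the standard derived quantities: persistence length L_p and flexural
rigidity K, per-residue h-bond occupancy, calorimetric domain parameters
(Tm, ΔH_cal, ΔH_vH), dissociation temperature T_diss, calcium sensitivity
pCa₅₀, and the NEM-myosin stop fraction.

## The core methods

**Skeletonization and secant persistence length.** Each frame's coiled-coil
axis is approximated by a polygonal line through weighted centroids of the
Cα atoms of 11 consecutive residues of both chains (end residues at half
weight, windows stepped by 10 so boundary residues contribute a total weight
of 1). After superposing the first segments of all frames, the time-average
unit tangent field t₀(s) is formed and the correlation

    C(s) = ⟨t(s) · t₀(s)⟩ = exp(−s / L_p),    K = L_p · k_B T

is fitted log-linearly through the origin. This generalizes worm-like-chain
tangent-correlation analysis to a semi-rigid rod whose mean shape may be
intrinsically bent. With k_B T = 4.1 pN·nm, L_p of 161 / 218 / 203 nm
corresponds to K of 660 / 894 / 832 pN·nm².

**Synthetic worm-like chains.** The generator draws joint bends from a
von Mises–Fisher distribution with concentration κ = L_p / b (the exact
Boltzmann form for a bending energy linear in cos θ), giving the closed-form
oracles ⟨cos θ⟩ = coth κ − 1/κ and ⟨t(0)·t(kb)⟩ = (coth κ − 1/κ)^k used
throughout the tests.

**H-bond occupancy.** Backbone N–H···O=C bonds by the standard geometric
criterion (N···O ≤ 0.35 nm, H–N···O ≤ 30°), occupancy per residue as the
fraction of frames its amide donates a bond, averaged over the two chains.

**Thermal fits.** DSC excess heat capacity is deconvolved into non-two-state
transitions, Cp(T) = Σᵢ ΔH_cal,i ΔH_vH,i / (R T²) · Kᵢ/(1+Kᵢ)² with
Kᵢ = exp[−(ΔH_vH,i/R)(1/T − 1/T_m,i)]; light-scattering melts are fitted
with a four-parameter decreasing Boltzmann sigmoid whose midpoint is T_diss.

**Motility fits.** Hill pCa–velocity, v = v_max (1 + 10^{n(pCa−pCa₅₀)})⁻¹;
linear extrapolation of velocity vs %NEM-myosin to zero velocity (relative
force); and Hill-form co-sedimentation saturation (K₅₀).

## Worked example

`examples/wlc_stiffness.py` generates 3000 worm-like chains (30 segments of
1.4 nm) at a ground truth of L_p = 161 nm and runs the full estimator:

```
ground truth       L_p = 161.0 nm
recovered          L_p = 167.7 nm  (+4.1%)
bending stiffness  K   = 687 pN nm^2  (kBT = 4.1 pN nm)
linear-fit R^2         = 0.9987
nearest-neighbour L_p  = 160.4 nm
```

The recovered L_p carries a small known positive bias from placing tangents
at segment arc midpoints (see `docs/methods.md`); the auxiliary
nearest-neighbour estimator is bias-free for this generator and agrees with
the ground truth. The other examples (`dsc_deconvolution.py`,
`dissociation_fit.py`, `motility_fits.py`, `skeleton_and_hbonds.py`) each
build a small synthetic input, run one fit and print the recovered
parameters next to the ground truth.

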