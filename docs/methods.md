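# Methods

## The equilibrium pore model

### Geometry

The pore connecting the disc to the planar target membrane is modelled on
the bilayer midplane as an inner half-torus: the surface of revolution of a
semicircle of radius H = h/2 + δ/2 whose centre sits at distance
R + H from the symmetry axis, with R = r_po + δ/2. Here r_po is the lumen
radius (the quantity reported by conductance measurements), h the membrane
separation at the disc edge, and δ = 5 nm the bilayer thickness. Both
bounding membranes are treated as tension reservoirs.

For small pores the torus meets both membranes tangentially ("fully
toroidal"). Once r_po + h/2 + δ ≥ D/2 the torus no longer fits inside the
disc of diameter D = 24 nm: the shape is truncated at the disc boundary and
the ApoE scaffold proteins at the rim are twisted through
φ = arcsin[(r_po + h/2 + δ − D/2)/(h/2)]. Shapes whose arcsine argument
exceeds 1 do not exist; this caps the admissible lumen radius at
D/2 − δ = 7 nm, matching the largest pores such discs support.

### Energy terms

* **Bending.** U_bend = κ ∫ C² dA with C the mean curvature and
  κ = 20 kT. Over the full torus this integrates to
  πκ[2(R+H)² arctan(√((R+2H)/R)) / (H√(R(R+2H))) − 4]; the truncated shape
  adds a closed-form correction that vanishes continuously as φ → 0. The
  closed forms are verified against direct numerical quadrature of the
  curvature integrand (relative tolerance 1e−6) in the test suite.
* **Tension.** U_ten = γΔA, γ = 0.66 pN/nm, where ΔA is the midplane area
  of the pore wall minus the flat area it replaces (two discs of radius
  R + H while toroidal; the disc face and the membrane hole when
  truncated). The partial-regime expression is derived from the truncated
  torus so that ΔA is exactly continuous at the regime boundary. At fixed
  shape ∂(γΔA)/∂r_po can be negative, but along the conditionally optimal
  separation h*(r) the tension term rises — the "work against tension" of
  an expanding pore is positive and is the number reported by
  `expansion_work`.
* **Hydration.** Apposed bilayers repel with pressure P₀e^(−d/λ)
  (P₀ = 5×10¹¹ dyn/cm², λ = 0.10 nm). Integrating the work to assemble the
  pore gives a flat–flat term P₀λ(πD²/4)e^(−h/λ) and a pore-rim term
  P₀(2πl)e^(−2r_po/λ)(λr_po/2 + (λ/2)²) with effective rim height
  l = 2√(λ(h/2+δ)). Only fully toroidal shapes carry this term; it is the
  short-ranged wall that sets the position of the free-energy minimum.
* **Scaffold twisting.** U_ApoE = τπDφ with τ = 8.43 pN per unit rim
  length. This is the dominant resistance at large radii.
* **SNAREs.** Of N available v-SNAREs per disc face, N_z are fully
  zippered and form a ring of TMD rods (diameter b = 2 nm) at the pore
  waist. Their free energy is
  −N_z kT [ln((2π(r_po + b/2) − N_z b)/b) + 1] + kT ln N_z!
  − N_z ε_zip − N_z kT ln Ω_z,
  i.e. a one-dimensional free-length entropy for indistinguishable rods
  whose centres live on the waist circle of radius r_po + b/2, the
  zippering energy ε_zip = 9.6 kT, and an orientational restriction to a
  cone of solid angle Ω_z = 0.05 sr (stiff rods). Partially zippered
  SNAREs roam the disc: −N_uz kT [ln(2πD/b) + ln Ω_uz] with Ω_uz = 2π sr,
  the half-space of orientations that avoid the membrane. States whose
  ring cannot hold N_z rods get zero Boltzmann weight.

Three conventions here are deliberate modelling choices. The ln N_z!
indistinguishability term is required for a sensible thermodynamic limit —
without it the high-occupancy states are over-weighted and the landscape
develops a spurious second minimum near 4 nm, moving the global minimum
with N in a way the crowding mechanism does not support. Placing the ring
at the rod centres (radius r_po + b/2 rather than r_po) is the
excluded-volume geometry of finite-diameter cylinders around a lumen.
Taking the unzippered orientational freedom as a hemisphere (2π sr) states
"all orientations that do not intersect the membrane" literally. A
parameter switch (`distinguishable_snares`) restores the distinguishable
counting for comparison; the entropic expansion force −∂U_z/∂r_po is
identical under either counting.

### The observable free energy

U(r_po, N) = −kT ln Σ_{N_z} ∫_b^{h_max} e^(−U_tot/kT) dh, computed by
composite Simpson quadrature with 400 nodes on h ∈ [b, 20] nm after a
per-radius log-sum-exp shift. Doubling the node count or extending h_max
to 30 nm changes U by well under 1e−6 kT (tested). The default radius grid
is 0.25–7.0 nm in 0.025 nm steps. The reported minimum position uses local
quadratic interpolation, so it is not quantised to the grid.

Derived quantities:

* **Net inward force** (`net_inward_force`): the Boltzmann-weighted mean
  of dU/dr_po over radii above 1.5 nm, converted to pN with
  kT = 4.114 pN·nm (T = 298 K, configurable). The weighting e^(−U/kT)
  makes this the mean force experienced by a pore sampling its own
  equilibrium size distribution; an unweighted window mean would instead
  be dominated by the steep, essentially unvisited wall near the disc
  limit. At default parameters this gives 21.7 pN for N = 0 and 5.8 pN for
  N = 15.
* **Expansion decomposition** (`expansion_work`): tension and bending
  changes between (r*, h*(r*)) and (r*+1 nm, h*(r*+1)), where r* is the
  SNARE-free minimum and h*(r) minimises the state energy at fixed r
  (2.95 kT and 2.42 kT at defaults).
* **Mean zippered number** and **Boltzmann-mean radius** from the same
  partition sum.

### Parameter fitting

λ, γ, ε_zip and τ are not independently known; `fitting` reproduces the
sequential recipe: (1) λ from the minimum position of a SNARE-free curve,
(2) γ from the mean slope on 0.5–1.0 nm, (3) ε_zip from the slope on
0.5–2.5 nm at N = 15, (4) τ from the slope on 4.0–4.5 nm at N = 4. Each
stage is a 1-D bracketed root find on a slope (or minimum-position)
mismatch with tolerance 1e−3 in parameter units; because only slopes and
positions are matched, the fits are invariant to the additive constant of
an empirical curve. Slope responses can turn over at extreme parameter
values, so roots are taken on the first (physical) branch located by a
coarse scan. Round-trip recovery from self-generated curves is within 5%
for all four parameters (tested), with mild λ↔γ cross-talk when the
reference was generated far from the defaults.

`lipid_anchor_delta` implements the lipid-anchored-v-SNARE variant: the
zippered bundle footprint is reduced (default 50%, the v-TMD share) in the
ring-packing term only, and ε_zip is lowered by bisection (0.01 kT
tolerance) until the Boltzmann-mean radius matches the unmodified model.
The default copy number is N = 7 per face, matching discs carrying ~15
lipid-anchored copies in total; the shift at defaults is 0.53 kT. Both the
footprint reduction and N are arguments.

## Trace pipeline

Raw cell-attached currents (20 kHz, 16 mV driving force across the patch)
are low-pass filtered at 280 Hz with an 8th-order Butterworth applied
forward–backward (zero phase), optionally notch-filtered at line
frequencies, and block-averaged 80:1 to 125 Hz; 2 pA of white instrument
noise lands at ~0.2 pA rms after this chain. Bursts are maximal episodes
with |I| > 2 pA lasting ≥ 250 ms; sub-threshold gaps shorter than 0.5 s
(configurable `merge_gap_s`) are intra-burst closures, not burst
boundaries — without this, every flicker would split a burst in two. The
burst lifetime T₀ includes those closures. Open sub-periods within a burst
are runs with I < −0.25 pA lasting ≥ 15 decimated points (60 ms); the
flicker count is the number of open runs. Open-state conductance is
|I|/V point by point, and radii follow from the cylindrical-channel
approximation r_po = √(ρλ_c G/π) with channel length λ_c = 15 nm and
solution resistivity ρ = 0.60 Ω·m (0.88 for NMDG-based pipette solution).

Cohort statistics weight pores equally: per-pore histograms on a shared
fixed-width binning (50 pS / 0.1 nm defaults) are normalised individually
and then averaged, so a long-lived pore does not dominate. Boltzmann
inversion U/kT = −ln(P_r) + A masks unvisited bins as NaN rather than ±∞
and sets min U = 0. Flicker counts are fitted by the geometric law
P(n) = p(1−p)ⁿ (MLE p̂ = 1/(1+mean), normal-approximation CI), burst
lifetimes by an exponential (MLE mean, SE = mean/√n), and nucleation rates
are unweighted means of per-recording rates with user-supplied exclusion
windows removed from the denominator.

Conductance-state structure is a two-component Gaussian mixture
(deterministic multi-start EM, seeded); pores are classified dilated when
⟨G_po⟩ > 1 nS (strict), and the dilation fraction versus copies per face
is fitted by the logistic P = e^((N−N₀)/b)/(1+e^((N−N₀)/b)) with
unweighted least squares; Wilson intervals are reported but not used in
the fit.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
bursts arrive as a renewal process (default 0.2/min); each burst has
K = 1 + n open periods with n geometric (default p = 0.0573, mean ~16
reclosures); open dwells are exponential with mean p·P_open·T̄₀, which
makes the total burst lifetime itself approximately exponential
(T̄₀ = 10.3 s default); open current is −G·V plus white Gaussian noise
(default 2 pA raw). Open dwells are floored at 80 ms and intra-burst
closures clipped to [16, 400] ms so that generated events are individually
detectable and one generated burst maps to one detected burst; bursts are
stretched to span ≥ 300 ms for the same reason. These floors slightly
inflate the realised dwell means relative to the nominal exponentials —
statistical tests compare against the realised ground truth, not the
nominal parameters. Per-pore conductances come from a fixed value, a
two-component mixture (defaults 300 pS/7.21 nS at 71/29 weights), or
Boltzmann sampling of a model profile with redraws every 40 ms, which is
what the pipeline-level inversion round trip uses.

What the generator does not emulate: seal drift and unstable baselines,
1/f and line noise (the notch path is exercised with synthetic sinusoids),
correlated open-state noise, multi-pore overlap, and end-of-record pore
pile-up. Passing tests therefore demonstrate correctness of the analysis
chain on data satisfying its assumptions, not robustness to every
pathology of real patches.

## Numerical sizes used by the test suite

Profiles are computed on the 271-point default grid; the detection
sensitivity test uses 12 five-minute recordings at 1 burst/min; the
flicker-statistics tests pool 200 bursts; the CI-coverage test uses 200
replicates of 64 bursts; the pipeline inversion round trip uses a ~13-burst,
8-minute recording with 25 s bursts (>40 000 open samples). These sizes
keep the full suite under a minute while leaving the statistical
assertions well-powered.

## Known limitations

* The model is equilibrium-only: flicker kinetics, nucleation rates and
  dwell-time distributions are treated statistically in the pipeline, not
  derived from the landscape.
* The truncated-shape bending/area corrections assume the cell-side
  membrane remains toroidal down to θ = −π/2; no shape relaxation beyond
  the two-parameter family is performed.
* With 15 SNAREs the net inward force comes out at 5.8 pN, somewhat above
  the ~5 pN scale expected from the crowding mechanism's near-cancellation
  of the 22 pN bare resistance; the residual is sensitive to the
  per-SNARE entropy conventions discussed above.
* Hydration in the truncated regime is omitted (separations there are far
  beyond the decay length).
* The mixture boundary is reported from responsibilities on the linear
  conductance scale by default; for very unbalanced cohorts the log-scale
  option is more stable.
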