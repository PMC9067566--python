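# Methods

This note documents the models, conventions and numerical choices behind
`icemono`, and what its synthetic-data validation does and does not show
about real data.

## Units and geometry

Å, ps, K, bar and mN m⁻¹ everywhere internally; conversions happen only at
I/O boundaries (GRO stores nm; assay tables use °C and say so). Boxes are
orthorhombic only — triclinic input is rejected rather than silently
mangled. Slabs are periodic in x and y with z the interface normal;
periodicity is stored as explicit per-axis flags and honoured by every
minimum-image operation, so a fully aperiodic cluster is handled by the
same code paths.

## Singular freezing statistics

The assay model is the standard singular (site-specific) picture: each
droplet carries a Poisson-distributed number of active sites, the droplet
freezes at the characteristic temperature of its most active site, and the
fraction frozen obeys `f(T) = 1 − exp(−λ(T))` with
`λ(T) = X·n_s(T) + background(T)`. Consequently
`n_mol(T) = −ln(1 − f(T))/X`. Conventions adopted where the field varies:

- Censored droplets (unfrozen at ramp end) stay in the denominator of `f`.
- Grids descend from the start temperature in 0.5 K bins (configurable);
  events are binned left-closed at the cold edge, and a freezing
  temperature exactly on a grid point belongs to that grid point's bin.
- Where `f = 1` the transform is undefined; those grid points are NaN and
  flagged, never ±inf.
- Monte-Carlo bands: the observed per-bin count is the Poisson mean; 1000
  replicate event tables are drawn, re-accumulated, transformed to `n_mol`
  and summarised by the 10th–90th percentiles. Replicates whose cumulative
  count saturates the droplet total are undefined at the affected points
  and excluded via NaN-aware percentiles; points where more than half the
  replicates saturate are flagged invalid. This is a plug-in band: its
  coverage of the truth is close to, but not exactly, the nominal 80%
  (measured ≈ 84% under the default study conditions), which the tests
  assert as a band, not a point.
- Background subtraction must happen on differential (per-bin) spectra:
  cumulative curves are differenced, subtracted with a floor at zero
  (flagging bins where background ≥ sample), and re-accumulated. This is
  the only well-defined subtraction for cumulative site spectra.

## Order parameters and ice classification

Steinhardt coefficients `q_lm(i) = ⟨Y_lm(r̂_ij)⟩_{j∈N(i)}` are computed
over the O–O neighbour graph (hydrogens ignored; a water is its oxygen).
The default cutoff is 3.5 Å — the first minimum of the water O–O pair
correlation — applied inclusively (a pair exactly at the cutoff is kept).
Both a brute-force and a cell-list neighbour search are provided and are
required by the tests to agree exactly; the cell list refuses cutoffs
beyond half the smallest periodic edge.

The classifier thresholds the locally averaged variant `q̄_6` (coefficient
vectors averaged over the molecule and its neighbours before taking the
modulus), a deliberate, tagged stand-in for kernel-based environment
classifiers used in the nucleation literature; the variant tag travels
with every result so the two are never conflated. Two practical points:

- `q_l` over very few bonds is biased high (E[q²] ∝ 1/N_b for random
  directions), so under-coordinated surface molecules would masquerade as
  ice. The classifier therefore also requires at least 4 neighbours — the
  interior coordination of ice. Molecules with no neighbours are flagged
  undefined, never silently zero.
- The threshold is calibrated, not hard-coded: midpoint between the 1st
  percentile of an ice reference distribution (ideal Ic with 0.15 Å
  Gaussian thermal noise) and the 99th percentile of a generated liquid
  reference, with a hard error if they overlap. Under the default
  conditions this lands near 0.45, comfortably below the zero-noise
  lattice values (`q̄_6` ≈ 0.63 tetrahedral Ic, ≈ 0.57 for Ih with its
  eclipsed bonds) and above the liquid bulk (p99 ≈ 0.4).

`q_l` is rotation-, translation- and relabelling-invariant; the tests
assert this to 1e-8 against independently computed associated-Legendre
sums.

## Nuclei, profiles and cages

Nuclei are connected components of the ice-like subgraph (union-find;
cross-checked against an independent graph-library oracle). The largest
nucleus is selected with a deterministic tie-break: smallest minimum
molecule id. Its centre of mass unwraps xy coordinates by minimum image
relative to a seed member — valid for compact nuclei (≲ half the box), the
regime the analyses target — while z is raw on the non-periodic axis.

`P(COM_z)` histograms (0.5 Å bins by default) are folded about the slab
midplane so the two equivalent interfaces superpose, normalised so the
mean density over a bulk baseline window is exactly 1, and aligned so the
maximum bin inside the interface window sits at 0. The interfacial
enhancement is the mean normalised density over the interface window.
Window edges should coincide with bin edges and lie inside the support of
the data; a partially covered edge bin dilutes the window mean (the
package's own validation experiments place nuclei on an explicitly chosen
support for this reason).

Cages are classified topologically from primitive 6-rings (rings with no
geodesic shortcut, enumerated once in canonical order):

- **HC**: two disjoint 6-rings joined by exactly three inter-ring bonds
  pairing alternating vertices of both rings — the two chair rings of the
  hexagonal-ice cage with its three vertical struts (12 molecules).
- **DDC**: an equatorial 6-ring whose two alternating vertex triples each
  carry three distinct bridges converging on an apex — two adamantane
  cages fused at the equator (14 molecules).

Each cage is keyed by its member set. On ideal lattices these definitions
give exact closed-form counts — 16 DDC per conventional Ic cell and 0 HC;
4 HC per orthorhombic Ih cell and 0 DDC — reproduced both by the package
and by an independent exhaustive pattern matcher. Caveat: in very small
periodic supercells (fewer than ~4 cells along a short axis) primitive
6-cycles can wind around the box and create spurious ring pairs; the
validation lattices are sized to exclude this.

## Interface metrics

Surface tension uses the mechanical (Kirkwood–Buff) route for a slab with
two interfaces; the standard error comes from block averaging (5 blocks by
default — the trace lengths used here make finer error models
unnecessary). The surface-pressure identity `π = γ_wv − 2γ` is enforced
structurally: every emitted result computes π from its own γ, with
`γ_wv = 80.1 mN m⁻¹` as an overridable constant.

Orientation analyses measure angles against each leaflet's reference
normal, chosen to point from the monolayer **toward the water phase** (−z
upper leaflet, +z lower). This makes the two leaflets superpose and gives
the intuitive reading that an upright amphiphile with its hydroxyl head on
the water has θ_z ≈ 0. Water dipoles are O → midpoint(H₁,H₂); hydroxyl
vectors are O → H. Densities are per-degree over [0°, 180°] and integrate
to 1; by default they carry no sin θ Jacobian (matching the way such
distributions are usually plotted), and a Jacobian-corrected mode — flat
for isotropic orientations — is available and tagged, since either
convention appears in the literature.

Interfacial water is any water whose oxygen lies within 7 Å (inclusive) of
any surfactant oxygen; the selection is verified to be stable over 5–10 Å
on layered systems with a proper bulk region.

## Synthetic data: what it emulates and what it does not

The generators encode the study conditions: ideal Ih/Ic oxygen lattices on
a 2.75 Å O–O distance (Ih in an orthohexagonal cell so boxes stay
orthorhombic), ice-rule proton decoration by randomized edge orientation
with greedy repair (seeded, verified by exhaustive constraint count),
rigid three-site waters (0.9572 Å, 104.52°), liquid slabs by random
sequential insertion at a 2.5 Å exclusion, two-site rod surrogates for
cholesterol (17 Å C25→C3 axis, hydroxyl beyond the head, heads toward the
water, 3 Å from the surface, 5 Å in-plane exclusion, 64 per leaflet at the
reference coverage), Gaussian pressure traces with known γ, and assays of
96 droplets cooled 0 → −30 °C at 1 °C min⁻¹ on a 0.5 K grid.

These fixtures validate the *analysis machinery*, not molecular realism:
the liquid has no hydrogen-bond network (its `q̄_6` distribution is a
conservative stand-in for real supercooled water, which lies closer to the
ice distribution), planted nuclei are rigid ideal-lattice cutouts rather
than thermalised clusters, and the monolayer surrogate has no internal
degrees of freedom. Passing recovery tests therefore demonstrates
correctness of the statistics and detection chain under known ground
truth; thresholds for production data should be recalibrated on fixtures
matching that data's noise level. Planted-nucleus frames keep the water
count constant by re-inserting displaced waters away from the nucleus, so
trajectory invariants (fixed atom count and ordering) hold.

## Validation experiment sizes

The planted-profile recovery runs 260 frames (tests) / 2000 frames
(acceptance script) of a 280-water slab with 30-molecule nuclei — enough
for the 10:1 enhancement to be recovered within its propagated Poisson
error while keeping the whole suite fast on a single CPU. Assay coverage
is measured over 120–500 simulated assays; γ unbiasedness over 200 seeded
traces. These sizes are the package's validation design, recorded here so
they can be scaled up deliberately rather than accidentally.

## Known limitations

- Orthorhombic cells only; no binary trajectory formats (XTC/TRR/DCD).
- The HC/DDC taxonomy covers the two canonical ice cages only; stacking
  disorder is observable as their coexistence but not quantified further.
- `nucleus_com_z` assumes compact nuclei; percolating clusters that span
  a periodic axis have no well-defined unwrapped COM.
- The MC band is a plug-in (empirical-Bayes-style) band, not an exact
  confidence procedure; its finite-count coverage deviates from nominal
  by a few percent.
- The assay simulator works on the measurement grid, not continuous time;
  cooling-rate effects beyond the grid mapping are out of scope.
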