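# Methods

This note documents the models, estimators, numerical choices and known
limitations of `memsolv`. Lengths are Å, energies kcal/mole, temperatures K
throughout; x and y are periodic, z is free, and the bilayer midplane sits
at z = 0.

## Coarse-grained bilayer model and generators

Each lipid is a rigid template at MARTINI-like granularity: one headgroup
bead 3 Å above the ester midpoint, two ester beads (GL1/GL2) 2.5 Å apart
anchoring the two acyl tails, and chain beads every 3 Å along each tail —
five per tail for the long-chain PO species, three for the short-chain DL
species (so DL tails are 6 Å shorter, the geometric source of every
DL-vs-PO contrast downstream). Lipids sit on a near-square lattice (~64 Å²
per lipid); species are independent Bernoulli draws from the local
DL-fraction field; positional noise is an isotropic Gaussian displacement
of the whole lipid. The defect generator realizes planted fields: the
local ester-plane separation follows the thickness field, the lipid axis is
rotated by the tilt field about the ester midpoint with uniformly random
azimuth (tilt is restricted to [0°, 90°]; azimuthal isotropy mirrors bulk
lipid dynamics), and no lipid is placed with its ester midpoint inside the
protein-footprint disk. Trajectories are lateral Gaussian random walks of
whole lipids with periodic wrapping; species and roster are conserved.
An optional region bias rejects (with given probability) steps that would
take a chosen species out of a named region, producing controlled
accumulation.

What this emulates — and does not: planted fields give exact, noise-free
ground truth for every map estimator, but lipids are rigid and z-frozen, so
a diffusing lipid carries its generation-time z. Recovery studies therefore
use stacks of independent static replicates rather than diffusive
trajectories when the planted field must be preserved exactly (a random
walk would blur the planted depth — a property of the generator, not of the
estimators). Passing tests demonstrate estimator correctness on data with
the assumed statistical structure, not the physics of real membranes: there
is no elasticity, no interdigitation response, no thermal chain disorder.

## Grid maps

Per-lipid values are stamped onto square cells (default edge 1.0 Å): a
datum is added to every cell whose center lies within the stamp radius
(default 2.6 Å, a typical coarse-grained bead van der Waals radius) of
either ester bead — the union, never double-counted — and the cell's
occupancy increments identically; a zero stamp radius still stamps the
containing cell. After time-averaging, cells with occupancy below 40% of
the mean occupancy are masked as not statistically significant; the mean is
taken over cells with occupancy > 0 (optionally excluding a footprint),
since counting never-touched cells would deflate it arbitrarily. The
printed grid-cell area in the original description of this scheme
(0.005 Å²) implies a physically implausible 0.07 Å cell edge and is treated
as a typo; the cell edge is configurable. Distance shells select cells
whose planar distance to the footprint boundary (periodic-aware; zero
inside) falls in [d − w/2, d + w/2), default width 10 Å.

Descriptor conventions: the lipid axis for tilt runs from the ester
midpoint to the tail-end midpoint (headgroup excluded), measured against
−z so a vertical outer-leaflet lipid scores 0° and a vertical inner-leaflet
lipid 180°; a planted tilt t in the inner leaflet therefore reads 180° − t.
The order parameter averages P₂ over consecutive chain-bead bonds.
Interleaflet contacts are bead pairs (not chain pairs) within a cutoff,
default 6.0 Å — the first coordination shell at coarse-grained bead sizes;
the cutoff only scales absolute values on planted fixtures. Water
penetration counts water beads strictly between the local per-cell ester
surfaces (global planes would mislead exactly where the defect is).
Leaflets are assigned by headgroup side of the global per-frame ester-mean
midplane. All intra-lipid vectors use minimum-image lateral deltas, so
boundary-straddling lipids are handled exactly.

## Enrichment

The bulk DL/PO ratio is computed from the system's global species counts
(the preset composition, pooled over frames), not from a far-field region;
`bulk_from="occupancy"` provides the self-referential alternative. A
consequence worth knowing: with a localized DL bump, the far field sits
slightly *below* the global bulk ratio, so far-field %E is mildly negative
rather than exactly zero. Cells with zero PO occupancy or failing the
occupancy mask are undefined. Distance profiles pool occupancies over the
mask before forming the ratio (this is not the mean of cell-level %E —
a two-cell counterexample is in the tests); sliding 10 Å masks are the
default, cumulative shells are available. Interface sectors are angular
wedges about the footprint centroid, the first centered on the
dimerization-axis direction, default three 120° sectors for a
three-interface monomer.

## Photobleaching and thermodynamics

The step-count model: an n-mer with per-subunit labeling probability p
(default 0.663) shows k bleaching steps with truncated-binomial probability
P_k = C(n,k)p^k(1−p)^{n−k}/(1−(1−p)^n); P₁ = P₂ crosses at p = 2/3. The
mixture estimator projects the observed (P₁,P₂,P₃₊) onto the segment
between fixed monomer and dimer control distributions (closed form, exact
on noiseless mixtures, clipped to [0,1] with a flag); its standard error
uses the analytic multinomial variance when counts are available. The
isotherm is evaluated in the cancellation-free form
F = 4x/(1 + 4x + √(1+8x)), x = Keq·χ*, identical algebraically to the
quadratic-root form and stable to x → 0; an independent mass-action solve
(Keq = χ_D/χ_M², χ* = χ_M + 2χ_D) serves as the cross-check oracle, and
Keq = F/(2χ*(1−F)²) inverts a single point. Isotherm fits optimize
log₁₀ Keq (lmfit) with optional 1/se weights; fits with min F > 0.9, or a
fitted K_D outside the sampled χ* range, are flagged lower-limit-only.
ΔG° = −RT ln Keq with R = 1.9872×10⁻³ kcal/(mole·K); T defaults to
298.15 K and is configurable everywhere (room-temperature experiments make
295 K equally defensible; the choice is exposed, not hard-coded).
Titration fits use a single exponential decay F₀e^{−λ·DL} or the two-phase
form F₀[F₁e^{−λ₁·DL} + (1−F₁)e^{−λ₂·DL}] with F₁ constrained to [0,1]
(published two-phase parameter sets in which F₁ exceeds 1 are not
representable under this normalization — documented divergence), rates
bounded at ≥ 0, F₀ fixable to a measured mean. ΔΔG regressions are OLS,
or WLS when per-point standard errors are supplied — necessary because the
free-energy error of a dimer-fraction estimate grows like 1/F + 2/(1−F) as
F → 1, and homoskedastic CIs undercover on titration data.

## Capture simulator and calibrated estimator

The simulator freezes a single bulk equilibrium (F from the isotherm; no
per-liposome re-equilibration, matching equilibration in large fused
membranes before extrusion traps the distribution), then assigns dimers and
monomers to liposomes by independent Poisson draws with means proportional
to liposome area, labels each subunit Bernoulli(p), and reports per-spot
fluorophore counts truncated into 1/2/3+ bins. Liposome areas (in lipids
per liposome, both leaflets) are lognormal, default mean 2×10⁵
(≈70 nm radius at ~65 Å²/lipid, within the size range of 400 nm-extruded
vesicles) with σ_log = 0.7; a mixture and a multilamellar fraction
(area-scaled, optionally excluded) are available. The per-area capture
constant is a free parameter of the model, not calibrated to any specific
vesicle preparation. At the default χ = 10⁻⁶ subunits/lipid the mean
occupancy is ~0.2 subunits/liposome — the dilute regime the assay operates
in — but co-capture of multiple species in one spot is simulated and is
*not* negligible for estimation: it biases the two-control mixture fit.
The spot distribution has an exact closed form (labeled monomers are
Poisson, labels from dimers compound-Poisson, averaged over the area
distribution), implemented in `expected_spot_distribution`; the calibrated
estimator maximizes the trinomial likelihood against it, with standard
errors from the inverse Fisher information. The closed form doubles as the
analytic oracle for the simulator in the test suite.

## Recovery studies (desk-scale problem sizes)

* Planted-map recovery: 400 lipids/leaflet in a 160×160 Å box, 16 replicate
  species draws, thinning depth 8 Å (σ 15 Å) centered on a lattice site so
  the noise-free map minimum is exact, 60° tilt annulus, DL bump from 0.2
  to 0.5; runs in a few seconds.
* Titration slope coverage: truth ΔG°(DL) = −10.4 + 0.135·log₁₀(DL/DL_min)
  kcal/mole over the assay's sub-1% design (10⁻⁸…1 %DL, one condition per
  decade), χ = 10⁻⁶, 5000 spots/condition, 100 replicates; scored by how
  often the WLS 95% CI covers the true slope (93–98% across study seeds).
* Isotherm recovery: Keq = 4×10⁷ (K_D = 2.5×10⁻⁸ subunits/lipid), eight χ*
  points over 10⁻⁹…10⁻⁶, Gaussian F-noise sd 0.05, 100 replicates; median
  |ΔG° error| ≈ 0.05 kcal/mole.
* Efflux recovery: F₀,vol = 0.2, k_leak = 10⁻³ s⁻¹, k_P = 0.05 s⁻¹, noise
  sd 0.01, 300 points over 300 s; median relative errors below 1%.

## Efflux details

The initial-rate window defaults to the larger of the first 5% of the trace
span and the first 10 points; it is a secant estimator, so on strongly
curved traces it underestimates the analytic t = 0 slope
F₀,vol·k_leak + (1−F₀,vol)·k_P (both are reported). Fits start at the
initiation marker and consume already-normalized traces (normalization to
the detergent-release total is upstream). k_P is reported as the faster
branch; near-equal rates and F₀,vol ≈ 1 raise identifiability flags.

## I/O and reproducibility

GRO/PDB reading and writing go through MDAnalysis; internal units are Å
with nm conversion at the GRO boundary. GRO stores three decimals in nm,
so coordinate round trips are exact only to ~0.01 Å (PDB: 10⁻³ Å). Maps
serialize as CSV matrices with a JSON header declaring grid, units and the
−9999 masked-cell sentinel. Pipeline runs derive every stage seed from the
master seed and write a manifest with parameters, seeds and SHA-256 output
hashes; identical configurations reproduce identical hashes. Trajectories
are written one GRO file per frame with a JSON sidecar (no compressed
formats required).

## Known limitations

Two lipid classes only (the enrichment contract is two-species by design);
no curvature or elastic-modulus estimation; no fluorophore photophysics
(blinking, bleach-time distributions) or image analysis; no
turnover-per-protein conversion for efflux; the mixing metric's published
μs-scale value (~0.8 of all leaflet lipids visiting each lipid's first
shell) is a property of long trajectories and is demonstrated here only as
a limiting property of the random-walk generator.
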