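# Methods

This note records the models, conventions, and numerical choices behind
`ionsans`, in the spirit of the methods documentation of packages like
MDAnalysis or statsmodels: what is computed, under which assumptions, and
where the genuinely open design decisions were resolved.

## Scattering model

The predicted solution scattering of a rigid atomic model is the
orientation-averaged Debye sum

    I(Q) = Σᵢ Δbᵢ² + Σ_{i≠j} Δbᵢ Δbⱼ sin(Q rᵢⱼ)/(Q rᵢⱼ),

with per-atom excess scattering lengths

    Δbᵢ = bᵢ + Σ b_{H/D attached} − ρ_solv · vᵢ.

Coherent scattering lengths `bᵢ` are the Sears compilation values;
displaced volumes `vᵢ` are Fraser–Traub-style atomic-group volumes keyed by
element and attached-hydrogen count, with per-element fallbacks. Both ship
as editable dicts in `ionsans.elements`. The solvent scattering-length
density `ρ_solv` follows from the D₂O mole fraction with a 29.9 Å³ water
volume.

**Hydrogens.** Deposited membrane-protein models are heavy-atom only, so
hydrogen accounting is entirely template-based: each heavy atom of the 20
standard residues carries an `(attached H, labile H)` count
(`ionsans.residues`), with Asp/Glu carboxylates ionized at neutral pH (no
labile H), Lys/Arg protonated, and His carrying one labile imidazole H.
Unknown residues contribute geometry but no hydrogens (with a warning);
atoms of unknown element scatter with zero length (with a warning).

**H/D exchange.** Rather than per-residue exchange kinetics, a single
`exchanged_fraction` (default 0.90) gives the probability that an
unshielded labile hydrogen has exchanged to deuterium by measurement time;
the transmembrane region, protected by detergent/lipid, is supplied as a
`shielded_selection` whose labile hydrogens stay ¹H. This one-parameter
model exposes the same physics (contrast increase from exchange, TM
shielding) with an explicitly tunable knob. Match-out deuterated detergent
is assumed contrast-matched and is not modelled.

**Histogram acceleration.** The pair sum is evaluated by binning pair
distances (default bin width 0.5 Å) and accumulating, per bin, the signed
weighted moments Σw, Σw·(d−c), Σw·(d−c)² about the bin center c. The sinc
kernel is then expanded to second order per bin, which reduces the
histogram truncation error to third order in the bin width: on 300-atom
random clusters the curve agrees with the exact O(N²·N_Q) double sum to
~1·10⁻⁵ relative (measured by `scripts/acceptance.py`), and the error
falls monotonically with the bin width. `I(0)` equals `(ΣΔb)²` identically
because the zeroth moment is exact. Memory is kept bounded by blockwise
pdist/cdist accumulation. No instrument-resolution smearing is applied; the
model-curve grid defaults to 120 log-spaced points on 0.005–0.35 Å⁻¹.

## Guinier analysis, molecular weight, curve arithmetic

The Guinier fit is a weighted linear regression of ln I on Q² over the
largest low-Q window satisfying `q_max·R_g ≤ 1.3`, iterated to
self-consistency (R_g stable to 0.1%, at most 50 rounds); `σ_lnI = σ/I`
weights, parameter errors from the normal equations. The 1.3 limit is the
common convention for globular particles. For *noiseless theoretical*
curves the package's own validation uses `q_max·R_g ≤ 1.0`: with no noise
there is no variance penalty for a shorter window, and the tighter limit
reduces the systematic Guinier truncation bias (the recovered R_g of the
toy pentamer then matches the coordinate-space value to <0.1%).

Molecular weight from forward scattering uses
`MW = I(0)·N_A / (c · (Δb/m)²)` with `Δb/m` the excess scattering length
per unit mass (cm/g) computed from the residue composition (or structure)
under the contrast model — the same tables as the curve prediction, so the
two routes are mutually consistent.

Detector-distance merging keeps the long-distance curve up to the merge
limit (0.09 Å⁻¹ by convention for the instrument geometry emulated here)
and the short-distance curve above it; background subtraction removes a
constant, estimated from the top-Q decile mean under the automatic policy.

χ² fitting of a model curve to data solves the 2-parameter weighted least
squares for scale and additive background analytically (model linearly
interpolated onto the data grid) and reports reduced χ² with N−2 degrees of
freedom. Because only scale and flat background are adjusted — no
hydration-shell refinement — χ² values for real systems are comparable to
published fits only within a band of tens of percent.

## Pair distance distributions

From a model, `P(r)` is the Δbᵢ·Δbⱼ-weighted histogram of pair distances
(density per Å); atomic self terms are kept separately so that
`∫P dr + Σ Δbᵢ² = I(0)` holds exactly (rectangle quadrature on the uniform
grid). From data, the indirect Fourier transform solves for non-negative
`P(r)` on a fixed grid (default 100 bins) minimizing
`χ² + α‖D₂P‖²` with a second-difference roughness operator and the
endpoint bins pinned to zero, via NNLS on the augmented system (with a
bounded-variable least-squares fallback for ill-conditioned supports far
beyond the information limit `2π/q_min`). The smoothness weight α is chosen
at the maximum-curvature (Menger) corner of the log-roughness/log-χ²
trade-off curve — a deterministic stand-in for Bayesian evidence
maximization, which can pick a slightly different regularization level than
Bayesian tools on the same data. On noiseless sphere curves the inversion
reproduces the analytic `P(r)` with exact peak position at 1 Å bins; on
noisy curves the broad sphere maximum is recovered within a few bins, since
the peak location of a plateau is intrinsically noise-sensitive. Dmax can
be estimated by scanning the IFT over candidate supports and taking the
knee of χ² versus Dmax; because the density near the support limit is a
tiny area fraction, that knee is only sharp for high-statistics data.

Distribution comparisons normalize both curves to unit area and report the
L1 distance plus the fraction of area beyond a threshold (default 100 Å,
the long-distance range diagnostic of expanded peripheral-domain
conformations).

## Pore profiles

The pore radius at height z along the channel axis is the largest sphere
centered in the plane z, within `max_offaxis` (default 6 Å) of the axis,
that touches no atom: `radius(z) = max_c min_i (|c − xᵢ| − r_vdW,i)` with
Bondi radii and no united-atom correction (structures are heavy-atom). The
maximization runs on a fixed polar candidate lattice (radial step 0.5 Å, 24
angles) followed by compass-search refinement from the 8 best seeds
(deterministic given the profile RNG seed, default 2022). Because the
lattice for a larger `max_offaxis` is a superset of the lattice for a
smaller one, relaxing the off-axis bound can never decrease the profile.
Radii are clipped at a bulk cutoff (default 12 Å); slices with no atoms in
reach are flagged as bulk. The axis comes either from the dominant
principal axis of the Cα distribution (with an ambiguity error for
near-spherical shapes) or from the line through the centers of mass of two
selections; z = 0 is anchored at the mean z of a user-specified selection,
conventionally the Cα atoms of the 9′ gate residue. Exact probe objectives
differ subtly between published pore-profiling tools, so absolute radii
should be compared with a ±0.5 Å allowance.

## Ensemble analysis

Trajectories are (frames × atoms × 3) arrays over a fixed topology, read
from multi-model PDB or XYZ series (text formats keep the pipeline
download-free; binary readers can be layered on top). RMSD series
superpose each frame on a fit selection (Kabsch/SVD) and measure over a
second selection; RMSF aligns frames on the measured selection (or an
explicit one), then reports fluctuation about the time mean, averaged per
residue. Domain tracks express each domain's center of mass in cylindrical
coordinates `(r_xy, z)` about the channel axis, recomputed per frame from a
core selection by default (a fixed axis is available); this mirrors the
standard presentation of peripheral-lobe motions. Frame ranking predicts
each sampled frame's curve on the data grid, fits scale+background, and
sorts by χ² (ties within 0.01 keep input order).

The PCA landscape superposes all frames on a reference (first frame by
default) over a selection, flattens the Cartesian coordinates, and
eigendecomposes via economy SVD; eigenvalues are coordinate variances (Å²),
the basis is orthonormal, and the eigenvalue sum equals the total
per-selection variance. PCA is unweighted by default with a mass-weighting
hook, since Cartesian PCA of aligned frames is the common convention for
conformational landscapes. Projection of new conformations superposes them
on the stored reference first, making projections invariant to rigid
pre-transformations.

## Synthetic ground truth

The toy channel emulates the architecture being analyzed — not its
chemistry: per subunit, four vertical transmembrane rods (radii 9–24 Å
from the axis, z ∈ [−34, 0] Å), an extracellular annular wedge
(r ∈ [14, 32] Å, z ∈ [5, 60] Å, 220 pseudo-atoms), and two peripheral
lobes (NTD1-like at r = 50, z = 78 Å; NTD2-like at r = 32, z = 100 Å;
8 Å cluster radius, 90 pseudo-atoms each), replicated with exact C₅
symmetry. The defaults give ~2,400 pseudo-atoms, R_g ≈ 50.7 Å and
Dmax ≈ 151 Å, mirroring the scale of the real pentamer (measured
R_g ≈ 52 Å). Pseudo-atoms carry a uniform scattering weight by default —
geometry, not contrast, is what these fixtures test — with an
alanine-composition mode for exercising the contrast tables.

Lobe motion is a bounded, mean-reverting (discrete Ornstein–Uhlenbeck)
random walk per lobe in `(r_xy, z, azimuth)` with reflecting bounds that
enclose the start; its stationary variance follows the closed form
`σ²/(1−(1−κ)²)` when the bounds are wide, and strong reversion produces
the reversible excursions seen in the real peripheral domains. Simulated
measurements add Gaussian noise with
`σ² = (floor·I)² + (count·√(I·I₀)/exposure)²` — a relative floor plus a
counting-statistics-like term — and report the generating σ, so fitting
the generating model back to a simulated curve yields reduced χ² ≈ 1 by
construction (the calibration-closure check).

What the synthetic systems deliberately omit: real secondary structure and
side-chain packing, membrane/detergent scattering, instrument smearing,
inter-particle effects, and correlated noise. Passing tests therefore
demonstrate the correctness of the algorithms and their closed-loop
consistency, not agreement with any particular measured protein; checks
against the deposited structures and measured SEC-SANS curves live in the
deposition-gated part of the acceptance suite and run when those public
files are present under `data/accessions/`.

## Problem sizes and determinism

The validation suite uses 300-atom clusters for Debye-oracle comparisons
(the exact double sum is O(N²·N_Q)), 10⁴-point spheres for closed-form
geometry oracles, 20 seeded repeats of the 50-conformer planted-recovery
experiment, and 12+12-frame two-cluster ensembles for the landscape check —
sizes chosen so the complete closed loop runs on a laptop-class single
core in a few minutes. All generators and analyses are deterministic given
their seeds; the acceptance script derives every RNG from its single
`--seed` argument.

## Known limitations

- No hydration-shell or explicit-solvent contrast term; χ² to real data is
  systematically higher than hydration-aware predictors.
- Exchange is uniform over unshielded labile hydrogens; genuinely slow
  exchangers in the protein core are not distinguished.
- The IFT regularization level is chosen geometrically (L-corner), not by
  Bayesian evidence; error bars on P(r) are not propagated.
- Pore profiles assume a single, roughly straight pathway near the given
  axis; branched or strongly kinked channels need a curved-pathway tool.
- The distance between two residues ("E347–E480") has no universal
  convention; minimum heavy-atom, minimum carboxylate-oxygen and centroid
  variants are all expressible through selections, and analyses should
  state which they use.
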