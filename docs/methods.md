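# Methods

This note records the models, conventions and numerical choices behind
`sarcotomo`, and what the synthetic generator does and does not emulate.

## Coordinate and angle conventions

* Internal unit: Å for all coordinates; reported statistics in nm.
  Mixing the two silently is the classic failure mode in this domain,
  so conversion happens only at reporting boundaries.
* Filament axis = +Y.  Tomogram-style slices are XY planes stacked
  along Z; cross-sections are XZ planes.  In A/I-band models +Y runs
  from the M-band toward the Z-disc, so the actin barbed end (which
  faces the Z-disc) is at large Y and the pointed direction is −Y.
* Azimuths are degrees in [0, 360), counter-clockwise from +X in the
  plane normal to the filament axis; angle differences are wrapped to
  (−180, 180].  The −166.6° twist is interpreted in this frame; users
  importing coordinates with the opposite handedness convention can
  negate the twist.
* Files: TSV tables + one JSON metadata file per model; coordinates in
  Å, 0-based indices, axis order (x, y, z).  Volumes are MRC2014
  mode 2 with the voxel size in the header (read/written via gemmi,
  which also parses STAR particle tables; positions are used, Euler
  angles ignored).

## Helical model

The thin filament is the actin genetic helix: twist φ = −166.6°/subunit,
rise r = 27.9 Å/subunit, subunit k at axial offset k·r with azimuth
θ₀ + kφ, strand parity k mod 2, subunit centres 25 Å off-axis.  The
two-strand crossover repeat is 180/(180 − |φ|) = 13.43 subunits =
37.5 nm; it is the period of the myosin target regions and of the
Z-disc cross-link repeat.

`estimate_helical_params` fits the axis by PCA and then refines axis
direction and centre by least squares on the spread of radial
distances (on the true axis every subunit sits at the same radius; a
PCA-only axis is slightly tilted whenever the chain does not sample
whole turns, which biases the twist by ~0.01°).  The twist is the
circular mean of consecutive azimuth increments — circular, not
arithmetic, to avoid wrap artifacts — with the sign preserved.

## Synthetic A-band

`build_lattice` places thick filaments on a triangular lattice
(constant 45 nm) and thin filaments on the two trigonal interstitial
sites per cell (at 45/√3 = 25.98 nm from three thick neighbours); only
interior thin sites with all three neighbours present are kept.
Lattice jitter is an isotropic in-plane Gaussian per filament.  All
thin filaments share θ₀ by default (helical register, as observed in
rigor A-bands).

`simulate_binding` is head-budget-driven.  Each thick filament carries
6 theoretical heads per full 14.3 nm crown; the modeled budget is
scaled by the fraction of its six surrounding thin filaments present
in the model (heads facing absent neighbours would bind outside the
modeled region and are excluded from the census on both sides of the
ratio).  The attached head count per thick filament is drawn
Binomial(budget, p_attach), so occupancy ≈ p_attach with binomial
scatter; molecules are then placed round-robin over crowns.  Topology
fractions `frac_single` and `frac_split` are specified as fractions of
attached heads and converted internally to per-molecule draw
probabilities (a single contributes one head, doubles and splits two).

Eligibility implements the orientation gate: a subunit is a candidate
site for a thick filament iff its azimuth lies within ±gate_halfwidth
(default 60°) of the in-plane bearing to that filament.  With the
trigonal geometry and a 60° gate, the three eligibility windows tile
the circle, so bound-subunit orientations per thick filament span
~120°.  Double heads occupy same-strand adjacent subunits (k, k+2,
55.8 Å apart): the k, k+1 pair differs by 166.6° in azimuth and cannot
both face one thick filament, so strand-adjacent pairing is the only
gate-consistent reading of "adjacent subunits".  Site search is
greedy from the crown outward within a ±20 nm axial reach (S2
flexibility); molecules that find no compatible free sites degrade
(split → double → single → unattached) and the degradations are
logged.  Defaults (p_attach 0.825, frac_single 0.083, frac_split
0.006, gate 60°) encode the rigor-state census the analyses are
checked against.

## Synthetic Z-disc

Two interdigitated antiparallel thin-filament arrays, polarity
alternating by column, overlapping by `overlap_length` (default
60 nm).  The lateral spacing is (L + d)·sin α and the axial throw of a
link −(L + d)·cos α, with L the α-actinin rod length (33 nm), d the
actin diameter (6 nm) and α the obtuse link-to-pointed-end angle, so
every generated link reproduces the prescribed length and angle
exactly; link sites repeat every crossover repeat along each
opposite-polarity pair with an independent random phase per pair.
With probability `doublet_prob` a second link lands on the same-strand
adjacent subunit, 2 × rise = 5.58 nm before or after (the direction is
random, which produces the "repeat minus two doublet offsets" family
of inter-cluster spacings).  Cross-links anchor on the subunit grid on
their first filament but keep the exact axial throw (stored as
`ya`/`yb`); geometry recovery is therefore exact on jitter-free
models, which is what the round-trip tests assert.

Z-disc thickness is measured along the filament axis as the axial
extent between the outermost cross-link binding sites.  At fixed rod
length a more obtuse α throws the two binding sites of each link
further apart axially, so thickness grows with α — the parallel-hinge
relation: ~80 nm at 128°, ~92 nm at 158° with the default overlap.
Angles are measured in 3D by default; a projected (slice-view) mode is
available since 2D annotation tools measure in projection.

## Tracing

The equatorial filter zeroes, per XY slice, all Fourier components
with |ky| above the kept half-width (cycles/voxel); filaments run
along Y so their slice power sits at ky ≈ 0 while transverse
cross-bridge features are suppressed.  It is a projection (idempotent)
and preserves DC exactly.  The band width is a configuration value
(default 0.05), not a claim about any particular dataset.  Detection
is scale-normalized Laplacian-of-Gaussian per XZ plane with separable
quadratic sub-voxel refinement — chosen over learned detectors for
determinism; any detector meeting the oracle property (≥95% filament
recovery at <1 voxel axis error on noiseless renders) is acceptable.
Linking is greedy plane-to-plane with max_step = 1.5 × plane spacing,
max kink 20°, gap bridging over ≤2 missing planes; ties resolve by
smallest step, then smallest direction change, then lower x, making
output deterministic.  ψ₆ uses first-shell neighbours by radius
(≤1.25 × the median nearest-neighbour distance) rather than a fixed
six, so finite patches score 1.0 when perfect.

## Binding analyses

Head assignment uses a 5.5 nm capture radius (one subunit diameter);
unassigned heads are flagged and counted, never dropped.  The
distance rule books exactly three measurements per subunit: a bound
subunit contributes one bound distance (to its binder) and two free;
an unbound subunit three free.  The difference of means uses a Welch
normal-approximation 95% CI by default with a seeded percentile
bootstrap (10,000 reps) as an option; normality is screened by sample
skewness over its standard error against a normal reference.

The profile aligner is an affine-gap global pairwise aligner (Gotoh
three-matrix recursion; gap run of length L costs open + (L−1)·extend)
verified against exhaustive enumeration, merged progressively by
center-star (center = maximal summed pairwise score, ties by input
order).  The substitution matrix — same-colour +3, E–E +1,
colour–colour −2, colour–E −1, gap open −5, extend −1 — rewards
conserved hotspot colour against the abundant E background; the values
are this package's declared defaults, overridable in configuration.
Only strand 1 is aligned (consecutive subunits of a single-strand
reading differ by 166.6° in orientation, which destroys alignability);
strand 2 is projected through strand 1's alignment.  Single-head and
split-head rates are reported against both attached and theoretical
head counts because either normalization is defensible.

## Tropomyosin sections

Sections are 37 nm (one tropomyosin unit), anchored at the A/I
boundary with section 1 the last A-band section and indices growing
into the I-band.  Classification compares the circular mean offset to
the M and C references (21° apart by default) with a 5° margin for a
hard call, otherwise "intermediate"; the rule is invariant under a
global rotation of offsets and references.  This module operates on
the per-subunit angular abstraction; assigning a state to a density
average is a separate problem it does not attempt.

## Rasterization

Filaments render as Gaussian tubes (σ = filament radius, ridge peak
~1), heads as blobs, cross-links as thinner tubes (σ = 0.4 × radius)
peak-matched to the filament ridge.  Noise is additive Gaussian with
σ = rms(signal)/SNR.  The missing wedge is a hard angular mask zeroing
Fourier components within the half-angle of the kz axis in the
(ky, kz) plane (single-tilt geometry, tilt axis X); no CTF is
simulated.  Volume-mode cross-link detection scores candidate
segments by the minimum interpolated intensity over the interior
(t ∈ [0.2, 0.8]) of the bridge — the endpoints sit on bright filament
tubes and carry no information — against 0.7 × the median filament
ridge intensity, with non-maximum suppression on segment midpoints
(radius 40 Å) because tilted near-duplicate candidates shadow a true
bridge along most of its length.

## What the generator does and does not emulate

It reproduces the *statistical* structure the analyses assume: lattice
spacings and their jitter, helical register, orientation-gated
binding at a target occupancy, topology fractions, cross-link
length/angle/doublet structure, tropomyosin state separation.  It does
not model filament bending or lattice compression, cooperative or
strain-dependent binding, CTF or realistic noise spectra, M-band or
MyBP-C cross-links, or the elasticity of the α-actinin hinge
(geometry only, by design).  Passing tests therefore demonstrate that
the estimators recover known ground truth under these idealized
conditions — a necessary check of correctness, not a validation
against experimental variability.

## Problem sizes and determinism

Default test models use 4×4 to 5×5 thick-filament lattices (18–32 thin
filaments, ~300 nm filaments, ~1,500–1,900 theoretical heads) and
volumes of ~80³ voxels at 20 Å — sizes chosen so the full suite and
the acceptance script run in well under a minute each while keeping
binomial standard errors small against the tested tolerances.  Every
stochastic component draws from `numpy.random.default_rng` seeded from
a single integer stored in the model; identical seeds and specs
reproduce bitwise-identical tables, which the tests assert.

## Known limitations

* Straight-filament assumption in the generator and in several
  measurements (bearings use constant lateral positions); the tracing
  stage tolerates gentle curvature but the binding census does not
  model it.
* Center-star MSA is a heuristic: pairwise-optimal against the center
  but not globally optimal; the pairwise core is exact and the tests
  bound the progressive result only through it.
* Occupancy overshoots its target by ≤1 head per thick filament when a
  double placement crosses the binomial target (accepted rather than
  force-converting molecules to singles, which would bias topology).
* The spacing histogram groups cross-links per antiparallel filament
  pair; links from unrelated partners at coincidental heights are not
  treated as neighbours.
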