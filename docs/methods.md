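# Methods

## Scope and model

The package analyses the conformational state of a small (~13 nm)
two-conformer protein from three angles: single-molecule AFM
morphometry, dihedral-PCA free-energy landscapes, and a handful of
deterministic assay calculators.  Because raw instrument data are not
redistributable, first-class synthetic generators stand in for the
instruments; their defaults encode the study conditions, and the tests
verify that the analysis stages recover the generating truth.

## Aspect-ratio populations

A molecule's conformation is read from its footprint aspect ratio
R = length/width: R ∈ [1, 3] closed, (3, 10] open, > 10 excluded.  The
boundary R = 3 counts as closed (the source intervals overlap at the
endpoint; the threshold is configurable).

Two named population fixtures reproduce the printed population
statistics of the two experimental conditions:

* **reduced**: R = 1 + LogNormal(μ = 0.41217, σ = 0.72917).  The
  parameters solve exp(μ + σ²/2) = 1.97 (mean R = 2.97) and
  1 − Φ((ln 2 − μ)/σ) = 0.35 (35 % open).
* **untreated**: R = 1 + Weibull(k, λ) with k ≈ 2.7455, λ ≈ 1.7757,
  solved numerically at import for mean R = 2.58 and P(R > 3) = 0.25.
  (A shifted lognormal has no real solution for this mean/tail pair.)

These families are *not* constrained above R = 5, so the fraction
beyond 5 is computed and reported but is not a matched quantity.

## AFM image simulation

Geometry defaults: 512 × 512 px at 1 nm/px (0.5 µm field).  The raster
resolution is chosen from sampling considerations: a ~13 nm footprint
must span ≳10 px for moment- or contour-based shape measurement, which
fixes ~1 nm/px once the 512-px line sampling is given.  Tip radius
8 nm (inside the < 10 nm class of sharp tapping-mode probes), height
noise σ = 0.06 nm, per-scan-line offsets σ = 0.15 nm, background tilt
(0.02, 0.01) nm/px — all typical of tapping-mode imaging in air on
mica.  Particle height is 1.8 nm ± 10 %, the apparent height of a
monolayer-adsorbed small protein.

Every molecule is rendered as a round-ended tube with an elliptical
cross-section over the distance to its centreline (a short straight
tube for closed molecules, degenerating to a disk at R = 1; a mildly
curved circular arc, ≤ 0.25 rad, for open ones).  The stadium
footprint area W(L − W) + πW²/4 is held constant across classes, so
number density and coverage are condition-independent.  A single
footprint family was chosen deliberately: it gives the tip-correction
model one edge geometry to invert instead of a per-particle model
choice that would be ambiguous exactly at the classification
boundary.

Tip convolution is applied analytically: the imaged surface of a tube
is the 1-D grayscale dilation of its cross-section by the spherical
tip cap, applied radially to the centreline distance.  This equals
the continuous 2-D dilation (the contact plane always contains the
surface normal) and avoids the ~0.2 nm edge underestimate of
grid-based dilation; it also respects dilation's commutation with the
pointwise max used to composite nearby particles.  The exported
`tip_dilate` / `tip_correct` operations provide the standard
grid-based dilation/erosion for externally supplied maps.

Placement is uniform with a margin and a minimum pairwise spacing
(max footprint + 2 tip radii), so simulated footprints never merge;
one seed fans out to independent substreams for ratios, geometry
jitter, placement, and image noise, making ground-truth tables
bit-reproducible.

## Measurement and tip deconvolution

The analysis chain is flatten → (optional) tip-correct → segment →
measure → classify.

*Flatten*: per-row polynomial (order 0–2, default 1) fitted with
iterative one-sided 3σ rejection (particles only protrude upward),
followed by a robust global plane fit and background-median removal.
Idempotent to < 1 µnm.

*Segment*: threshold at median + 3·(1.4826·MAD); 8-connected
components; border-touching components and areas outside
[20, 10⁴] nm² are excluded (single-molecule selection).

*Measure*: without tip knowledge, length/width are the
moment-equivalent ellipse axes of the threshold mask (floored at one
pixel, so a single-pixel component has R = 1).  When the tip radius is
known — always true for simulated data — the measured extents are the
support of the sub-pixel marching-squares contour at 30 % of the
particle's smoothed peak height, and a forward model inverts the tip
broadening.  The model exploits an identity of uniform-edge tubes:
dilation and smoothing broaden the length and the width by the same
edge offset, so L_obs − W_obs = L − W exactly, and only the width
needs numerical inversion.  The forward model (1-D dilation of the
cross-section by the tip cap, Gaussian-smoothed exactly like the
image, read at the measurement level) is tabulated over width × height
and inverted by monotone interpolation; the particle's true height is
iterated so the model's smoothed peak matches the observed one, and a
2-D dome model supplies the small extra erosion of the plan-convex end
caps.  On noise-free single particles this recovers R to ±0.1 over
R = 1.2–9; end-to-end at default noise, the recovered open fraction
tracks the generating fraction to better than ±0.01 at n ≥ 300 (the
tests assert ±0.03) and the mean R to ±0.05 (asserted ±0.15).

Erosion of the image by the tip (`tip_correct`) is also provided; it
yields the morphological opening — a certified upper bound of the
surface — but cannot restore footprints of features narrower than the
tip, which is why classification relies on the model inversion
instead.

What the simulator does *not* emulate: tip asymmetry and double-tip
artifacts, feedback overshoot, thermal drift, overlapping/aggregated
molecules, and real conformational substructure (an S-shaped
intermediate, say).  Passing the recovery tests therefore shows the
measurement chain is unbiased for well-separated particles under the
modelled physics, not that any AFM data set will be measured to
±0.01.

## Population statistics and comparisons

Summaries use linear-interpolation (type-7) quantiles; box plots draw
the 25/75 % box with whiskers at the population minimum/maximum;
percentages print to one decimal.  Open-count comparisons report the
pooled two-proportion z-test and the Fisher exact test side by side,
plus a Mann–Whitney U (asymptotic, tie-corrected) on the full R
samples: for counts reconstructed from 35 % of 351 vs 25 % of 352 the
z-test gives p ≈ 0.0037, and no documented test reproduces the
printed p = 0.0003 from counts alone, so the package deliberately
reports the family of defensible tests rather than forcing agreement.

## Trajectories and landscapes

The trajectory generator is a two-state Markov chain (default
per-frame switch probabilities 0.005 A→B, 0.010 B→A, so stationary
occupancy A:B = 2:1) with von Mises emissions (κ = 40; wells of
circular SD ≈ 9°) around two centre vectors π/2 apart in 4 of 10
dihedrals.  The chain starts in its stationary law; 2×10⁵ frames give
~600 transitions each way.  Note the estimator variance: with
integrated autocorrelation (1+λ)/(1−λ) ≈ 132 (λ = 1 − p_ab − p_ba),
the realized occupancy ratio of one 2×10⁵-frame trajectory has SD
≈ 0.11 around 2.0 — single-trajectory ratios routinely land anywhere
in 1.9–2.1.

dPCA embeds angles as interleaved (cos, sin) pairs — the
circular-statistics-safe representation — and eigendecomposes the
mean-centred covariance; eigenvalue sum equals the covariance trace to
1e−8 and the basis is orthonormal to 1e−8.  The free-energy surface is
a 60 × 60 histogram of the first two projections converted by
ΔG = −k_B T ln(p/p_max) at T = 300 K (k_B = 0.0083145 kJ/mol/K, the
thermostat temperature of the simulations being emulated); empty bins
are masked rather than set to +∞, and the minimum is exactly 0 by
construction.

Basins: bins are flooded in order of increasing ΔG and joined by
union-find.  When two catchments meet, the shallower survives as a
separate basin only if its persistence (saddle − its minimum) reaches
1.0 kJ/mol — below the deliberate two-state separation but above the
Poisson wrinkles of moderately sampled bins — and basins holding
< 1 % of the mass (isolated sparse islands) are dropped.  The barrier
between the two dominant basins is the saddle level minus the
shallower minimum.  For the synthetic fixture the two clusters are
~18 within-cluster SDs apart, the connecting bins hold zero counts,
and the basins never join: the barrier is honestly reported as
undefined (the emission model contains no transition path), while the
occupancy ratio reproduces the hidden-state split to < 1 %.  The
barrier definition itself is exercised on hand-built surfaces.

Kabsch superposition centres both point sets, takes the SVD of the
cross-covariance, and corrects reflections to proper rotations;
mirror-image sets therefore keep a positive RMSD.  RMSD units follow
the input (Å by convention).

## Assay calculators

All three calculators are pure arithmetic with explicit unit
contracts: thiol ratio inverts a cysteine standard curve in mM and
applies the sample dilution (dilution factors are required arguments —
they are experiment-specific and have no defensible default); biotin
ratio applies Beer–Lambert with ε = 34 000 M⁻¹cm⁻¹ (configurable, as
kit inserts differ); MRDE uses Δε = θ/(32980·c·l·N) with θ in mdeg,
c in M, l in cm, N residues.  Sub-blank absorbances clamp to zero
with a warning rather than produce negative concentrations.

## Orchestration and reproducibility

The end-to-end study simulates 351 reduced and 352 untreated molecules
(batches of ≤ 50 per 0.5 µm field to keep spacing feasible), analyses
every image with the tip radius taken from the scan configuration,
summarises and compares the conditions, and runs the
flexible/rigid trajectory pair through the landscape chain.  Reports
are pydantic-validated JSON with a provenance block (seed, config
SHA-256, package version) and no timestamps, so equal seeds produce
byte-identical reports; the shipped JSON schema is generated from the
same models and pinned by a test.  Problem sizes in the test suite
(40–320 molecules per scene, 1.5–4×10⁴-frame unit-test trajectories,
full 2×10⁵-frame fixtures only in the study-level checks) were chosen
so statistical tolerances are meaningful while the whole suite stays
interactive.

## Known limitations

Deconvolution accuracy degrades if the imaged particle violates the
tube model (aggregates, strongly curved molecules, heights far from
the tabulated 0.6–3.2 nm range); particles are assumed non-overlapping
(the simulator guarantees spacing, real images need the area and
border exclusions to do the pruning); the two-proportion comparison
treats particles as independent draws, ignoring replicate/image-level
clustering; the FES barrier is a flooding proxy, not a minimum-energy
path; and the Markov emission model, having no transition
intermediates, cannot exhibit finite barriers by design.
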