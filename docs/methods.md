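# Methods

`chromatinmc` models a chromatin fiber at nucleosome resolution, samples
its equilibrium conformations by Monte Carlo, and compares the resulting
marker-pair distance distributions with two-color FISH distance
measurements. This note records the model, its assumptions, the defaults
and why they were chosen, and what the synthetic data do and do not
establish.

## Chain model

Chromatin is a chain of segments: cylindrical linker-DNA segments
connecting nucleosome "stem" segments. Each segment carries a position
and a right-handed orthonormal frame (u, v, f); u points to the next
segment's position and (v, f) track torsion. Linker DNA lengths come
from the gaps between non-overlapping 147-bp nucleosome footprints,
converted at 0.34 nm/bp, and are discretized into at least 2 segments;
linkers longer than 20 nm get ceil(length / 10 nm) equal segments.
Touching footprints receive a 1-bp (0.34 nm) stub so the chain stays
well-defined. Genomic coordinates (0-based, half-open; "dyad_start" is
the footprint start, since the positioning data fix no dyad convention)
are preserved at every segment boundary, so any bp maps to a chain
point.

Each nucleosome core particle (11 nm diameter, 5.5 nm height) is placed
rigidly relative to its stem by a distance `d` and six angles: polar and
azimuthal angle of the center offset in the (pre-twisted) stem frame,
three ZYZ Euler angles of the body frame, and the pre-twist itself.
The published values of `d` and the angle sets live in instrument- and
study-specific supplementary material we deliberately do not hard-code:
the defaults here (`d` = 8 nm, a generic crossed-linker geometry, and a
slightly tilted variant for the H1-bound state) are config-replaceable
(`NucleosomeGeometry.from_yaml`) and are documented as placeholders, not
measurements.

Linker histone H1 enters in two ways, both selected per nucleosome by a
Boolean flag: (i) the alternative placement angle set, and (ii) the rest
entry/exit kink at the two joints flanking the stem. The H1 stem motif
pulls the entering and exiting linker arms toward each other; in tangent
convention that means a larger rest angle between successive u vectors
(default 145° total versus 40° without H1, split half-and-half across
the two stem joints). This reproduces the qualitative H1 effect —
local back-folding and compaction — without an explicit H1 particle.
The kink is azimuthally unconstrained (a cone, not a fixed dihedral),
a deliberate simplification.

The open parameters above (kink angles, depth weights) were fixed once
by requiring the physically correct baseline regime: simulated 5-kb
distance distributions at E_max = 4 kT that are broad (tens of nm sd),
right-extending toward the ~243 nm beads-on-a-string bound, with means
above 100 nm — the regime this model family reports for active
chromatin. Isotropic-heavy depth weights or large open-state kinks
instead produce a collapsed ~30-nm droplet in which further compaction
by E_max or H1 has no room to act; see the known-limitations section.

## Energy terms (kT at 293 K; temperatures are dimensionless multipliers)

**Elastic.** Harmonic stretch per segment (500 kT/nm²; moves are rigid
rotations, so this term is inert during sampling and only guards
externally supplied configurations), harmonic twist per joint with
torsional persistence length 75 nm, and harmonic bend per joint. The
bend constant is *calibrated*: we solve ⟨cos θ⟩ = exp(−l/Lp) for the
joint constant k under the equilibrium density p(θ) ∝ exp(−kθ²/2) sin θ,
so the discrete chain's tangent correlation decays exactly like a
worm-like chain of persistence length Lp (default 50 nm). The naive
choice k = Lp/l underestimates the realized persistence length by about
l/(2Lp) — an 8–10% bias in ⟨R²⟩ at l = 10 nm — which is a
discretization artifact, not physics, so we remove it.

**Electrostatics.** Debye–Hückel repulsion between charge points at
linker-segment midpoints: U = l_B ν_i ν_j exp(−r/λ_D)/r with Bjerrum
length 0.7 nm, Debye length 0.96 nm (100 mM monovalent salt), and
Manning-reduced linear charge ν = 1.4 e/nm. Adjacent segments are
excluded; interactions are truncated at 6 λ_D. The midpoint-charge
approximation is refinable (`charge_points_per_segment`); the refined
discretization agrees with the exact screened double line integral to
2% (tested against quadrature).

**Internucleosomal attraction.** A uniaxial anisotropic potential of the
Gay-Berne/Zewdie family acting between nucleosome symmetry axes: a
shifted 12-6 in the reduced separation ζ = (r − σ(ω) + σ₀)/σ₀, with
contact range σ(ω) interpolating between side-by-side (11 nm) and
face-to-face (6 nm) and depth ε(ω) largest for coaxial stacking
(weights 0.1 isotropic / 0.3 axis alignment / 0.6 stacking; a
stacking-dominated depth so that the attraction drives local
face-to-face contacts rather than orientation-independent droplet
collapse). The
potential is truncated and shifted to zero at 20 nm and numerically
depth-normalized at model build time so its global minimum is exactly
−E_max (default 4 kT; 6 kT for inactive-chromatin conditions). The
core is clamped below ζ = 0.55 (the excluded-volume term supplies the
gradient there), keeping the energy bounded and continuous.

**Excluded volume.** Capped quartic overlap penalty
U = cap · ((contact − d)/contact)⁴, cap = 1000 kT — soft enough to keep
detailed balance clean (no hard rejections), steep enough that overlaps
are effectively forbidden (> 100 kT well before full overlap). Pair
classes: linker–linker cylinders (radius 1.2 nm, minimum axis–axis
distance), linker–nucleosome (effective nucleosome sphere of 4.5 nm;
the stem's own ±2 neighboring segments are excluded since the entry/exit
geometry necessarily grazes the core), and nucleosome–nucleosome (hard
contact at 0.8 σ(ω), consistent with the anisotropic shape).

## Sampling

Moves are rigid rotations with symmetric proposals: single-segment
twist about u, crankshaft rotation of a short interior sub-chain (≤ 12
segments) about the chord between two joints, and pivot rotation of a
random head or tail about a random axis. One MC step is one attempted
move; a sweep is one move per segment on average. Delta energies touch
only the boundary joints and non-bonded pairs crossing the moved/static
partition; the incremental running energy agrees with a full
recomputation to < 1e-6 kT (tested). Frames are re-orthonormalized
periodically and the energy re-baselined.

Simulated annealing (geometric schedule, default 3.0 → 1.0 in 8
stages) pre-relaxes the start; move amplitudes are tuned toward ~40%
acceptance during annealing and then frozen, because amplitude
adaptation during production would violate detailed balance.

Replica exchange runs M replicas at a strictly increasing ladder of
dimensionless temperatures with adjacent-pair swaps every
`swap_interval` (default 5000) steps at probability
min[1, exp(−(β_i − β_{i+1})(E_{i+1} − E_i))]. Each replica owns an RNG
substream spawned from the control seed, so runs are bit-reproducible.
The ladder can be feedback-optimized: replicas are labeled by the last
ladder endpoint they visited, the fraction of "down"-labeled replicas
per temperature is monotonized and inverted to place temperatures at
uniform flow increments, endpoints fixed, iterating while the measured
round-trip rate improves (geometric fallback with a warning if no flow
is measured).

Equilibration is detected by a running-mean stationarity heuristic on
the energy and end-to-end series (first log-spaced cut whose remaining
halves agree within 0.8 late-half standard deviations, both series),
overridable by an explicit cut; the orchestration layer falls back to a
25% burn-in with a warning on pilot-scale runs too short for the
heuristic. Thinning uses the integrated autocorrelation time with
Sokal's adaptive window (c = 5); note that thinning at stride τ leaves
a residual lag-1 correlation of ≈ e⁻² by construction — use 2τ when
near-independence matters.

## Distance analysis

Marker anchors (probe-set midpoints, bp) map to the nearest segment
boundary; distances are 3D Euclidean in nm. Distances beyond the
maximum extension of a beads-on-a-string fiber — span_bp × 0.34 / 7 nm,
i.e. ≈ 243 nm for 5 kb — are physically implausible and cut off (the
count removed is reported). Comparing 3D simulation with 2D measured
data is supported by isotropic random projection (distance × sin θ, θ
from the uniform-sphere polar density), labeled in the output.

Histograms are density-normalized with a default 10-nm bin width over
[0, max extension]; the binning travels with the histogram object and
mixture fitting/RMSE refuse mismatched binnings structurally. The
mixture weights solve min ‖target − Σ w_k comp_k‖² with w ≥ 0,
Σ w = 1, via Lawson–Hanson NNLS with the equality constraint as a
heavily weighted row, renormalized; this matches an exhaustive
0.01-resolution grid search (tested). The histogram bin width for the
fit is a free parameter; 10 nm is a sensible default given ~7.5 nm
localization noise.

## Spot localization

The brightest spot per channel is the maximum scale-standardized
negative Laplacian-of-Gaussian response over an isotropic scale range
(per-scale z-scores via median/MAD, edge band excluded, deterministic
low-(z, y, x) tie-break, 5σ noise floor). Sub-voxel refinement fits a
3D Gaussian plus constant background by Levenberg–Marquardt over a
±3σ window, with anisotropic z width (STED depletion shapes the z PSF
differently). Chromatic offset and refractive-index corrections are
accepted as per-axis affine calibration inputs, not computed. Quality
control is threshold-based (the noise floor), a documented
simplification of the instrument pipeline's learned classifier.

## Synthetic data: what it emulates and what it does not

The generators produce nucleosome sets (truncated-normal spacings, mean
NRL 183 bp, sd 25 bp, Gamma-distributed occupancy scores), MNase-like
occupancy tracks (jittered 147-bp footprint coverage with Poisson
sampling noise and 10-bp smoothing), right-tailed distance datasets
(lognormal mixtures — right-tailed and positive-support, the natural
family when only skewness is known — with isotropic 3D localization
error of 7.5 nm pairwise RMS), and two-channel image stacks
(Gaussian PSF, Poisson photons, constant background). All generators
are seed-deterministic and emit ground truth.

They do *not* emulate sequence-dependent positioning, MNase digestion
bias, replication intermediates, chromatic aberration, sample drift, or
non-Gaussian PSF structure. A green test against synthetic data
therefore establishes that the pipeline recovers what it is told is
there (estimator correctness and direction of effects), not that the
model parameters are those of any particular cell type.

## Scaled-down defaults

Desk-scale experiment plans default to few replicas and ~10⁵–10⁶ MC
steps with truncated flanking regions; publication-scale runs of this
model family use tens of replicas, 10⁷–10⁸ steps per replica and
~110-nucleosome flanks, which is cluster work. Direction-of-effect
conclusions (nucleosome removal extends, stronger internucleosomal
attraction and H1 compact) are robust at desk scale; absolute means are
not converged there and are not asserted anywhere in the test suite.

## Known limitations

- Nucleosome placement angles and the H1 set are placeholders pending
  study-specific geometry; all are config inputs.
- The azimuthally symmetric stem kink underconstrains the linker
  dihedral at the nucleosome.
- No nucleosome unwrapping/breathing, no explicit ions, no
  sequence-dependent elasticity, no H1 particle.
- Electrostatics uses one charge point per linker segment by default;
  fine for screened 100 mM conditions, refinable for low salt.
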