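# Methods

This note documents the models, conventions and numerical choices behind
`tetradna`, in the order the pipeline applies them.

## Data model and conventions

A trajectory is a table with one record per snapshot.  For an N-level duplex,
junction j (1-based) sits between base-pair levels j and j+1; backbone
torsions are stored per nucleotide per strand, each strand numbered 5′→3′ in
its own direction (so the Crick nucleotide paired with Watson level ℓ has
index N+1−ℓ).  For a junction read along a strand, ε and ζ belong to the
5′-side nucleotide of the phosphodiester linkage and α, β, γ to the 3′-side
nucleotide.  Angles are stored in degrees — backbone torsions on the
[0°, 360°) wheel (so gauche− ≈ 270°, as in the B-DNA literature), helical
rotations on (−180°, 180°] — and distances in Å.  Positions and levels are
1-based and inclusive.

Swapping which strand is called "Watson" renumbers levels end-for-end and
negates exactly four parameters: shift, tilt, shear and buckle.  This sign
rule is both implemented (`trajectory.strand_flip`) and derivable from the
frame algebra below; the test suite checks the two routes against each
other.

## Sequence symmetry

k-mers are grouped into reverse-complement classes; class names use the
reading with the most purines, then the most G, then the alphabetically
first.  For dinucleotides this reproduces the conventional 10 step names.
The published canonical names for the 120 non-symmetric tetranucleotide
pairs are not fully standardized; the same deterministic rule is applied,
and a remapping can be layered on top if a different table is preferred.
Oligomer designs are the orbits of 4-mers under cyclic rotation plus reverse
complementation (39 orbits, verified against a Burnside-count oracle); each
design's 18-mer is GC + CD + (ABCD)×3 + GC, placing every rotation of the
repeat unit away from the GC caps.  The centermost occurrence of a
tetranucleotide is the one whose covered-level midpoint is closest to level
9.5; ties (never triggered by the 39-design set) prefer the 5′-most
Watson-strand occurrence.

## Helical parameters

Each base carries a right-handed orthonormal frame (standard
reference-frame convention; the packaged standard base geometries are
convention fixture data).  A base-pair frame flips the Crick frame 180°
about its own x axis, then takes the half-angle rotation mean and the origin
average.  Parameters between two frames use a symmetric mid-frame
construction: the relative rotation's rotation vector — whose axis is common
to both end frames and the mid frame — supplies (tilt, roll, twist) as its
x, y, z components, and the origin difference expressed in mid-frame
coordinates supplies (shift, slide, rise).  The construction is exactly
invertible (used by the generator to rebuild frame sequences), gimbal-safe
up to 180° total rotation, and satisfies the strand-flip sign rule exactly.
Mid-frame constructions differ subtly between published implementations;
numeric identity with any one of them is not claimed, but all conventions
tested here (sign rule, canonical step, round trip) are exact.

Sugar pucker uses the Altona–Sundaralingam parameterization
ν_j = τ_m cos(P + 144°(j−2)); the phase is undefined (flagged None) below an
amplitude of 1e-6°.  Torsions follow the IUPAC convention (cis = 0°),
reported on [0°, 360°); degenerate geometry (coincident or collinear
consecutive points) raises.

## Circular statistics

All summary statistics are computed from single-pass, mergeable sufficient
statistics.  Circular means come from the resultant vector, the circular SD
is √(−2 ln R̄), and min/max/range report the smallest arc containing the
data, unwrapped around the mean.  Fisher's T-linear association is evaluated
through the identity

    Σ_{i<j} sin(θᵢ−θⱼ) sin(φᵢ−φⱼ) = A·B − C·D
    Σ_{i<j} sin²(θᵢ−θⱼ) = (n² − E² − F²)/4

with A = Σ cosθcosφ, B = Σ sinθsinφ, C = Σ cosθsinφ, D = Σ sinθcosφ,
E = Σ cos2θ, F = Σ sin2θ; the expansion is verified against the O(n²)
pairwise definition to 1e-10 in the tests before being trusted.  Linear
variables are mapped through θₓ = atan(x / 5 Å) whenever they enter a
circular correlation; the 5 Å scale is configurable and is applied uniformly
to the linear member of mixed pairs.  Pearson correlation is used only for
linear–linear pairs; rotational helical parameters are treated as circular
for safety.  A ρ̂_T denominator below 1e-12·n² (antipodal-degenerate data)
is flagged undefined rather than returned.

## Filters and backbone states

Inter-BP parameters at a junction are discarded when **either** adjoining
base pair has any Watson–Crick heavy-atom distance strictly greater than
3.5 Å; intra-BP parameters (notably opening) are never filtered.  Masking
both adjacent junctions is the conservative reading of "parameters involving
broken pairs".  BI/BII uses the wrapped difference ε − ζ mapped to
(−180°, 180°]: BII iff positive (BI ≈ −90°, BII ≈ +90°), with the boundary
assigned to BI.  This sign rule, rather than hard rotamer-wheel cutoffs,
decides the state; the g+/t/g− wheel (thirds at 120°/240°) is exposed for
diagnostics only, and snapshots with ε or ζ in g+ are tallied separately.
The C8-H…O3′ hydrogen bond is detected from the heavy-atom distance alone,
bonded iff < 4.0 Å (strict), and is undefined wherever the strand's 3′ base
at the junction is a pyrimidine — hence never for central RY steps.
Conditional associations P(HB|BII) and P(BII|HB) are snapshot-weighted
relative frequencies from the 2×2 contingency table.

## Shape classification and substates

The reference analysis classed distributions by visual inspection; the
operational surrogate here is: **multi-peaked** when a Gaussian-KDE
(histogram-convolution implementation, Silverman bandwidth, 1024-point grid)
shows ≥ 2 peaks, each with prominence ≥ 5% of the global maximum and
separation ≥ 2 bandwidths; otherwise **non-Gaussian** when |skewness| > 0.5,
excess kurtosis > 1, or a unimodality dip statistic exceeds its 1% critical
value; otherwise **Gaussian**.  The dip statistic is half the minimum over
candidate modes of the largest deviation between the ECDF and its best
unimodal envelope (greatest convex minorant left of the mode, least concave
majorant right); it is computed on a fixed 120-point subsample and
calibrated by 400 seeded uniform-null simulations, cached per size.  All
thresholds live in `ShapeConfig`.

3-D densities in (shift, slide, twist) use uniform bins of 0.25 Å / 0.25 Å /
2°, normalized to total probability 1; connected regions above isolevels
(default 15/30/45/60% of the maximum) are labelled by 26-connectivity with
their peak coordinates.  The reading direction of each non-self-complementary
tetranucleotide places its central dinucleotide in the negative-average-shift
set {GG, GA, AG, AA, GT, CA}; self-complementary central steps keep the
canonical name direction.  Substate assignment first tags snapshots by
backbone state (RR: central-junction Watson BI/BII; YR: BI₃′/BII₃′ from the
two 3′-flanking junctions; RY: single canonical tag), estimates substate
centres from each tagged population, and then assigns each snapshot to the
nearest centre with coordinates scaled by their pooled SDs — the three-state
picture is emergent from the data, not imposed.

## Convergence

Repeat-position agreement compares parameter means between the identical
tetranucleotides at levels 6–9 and 10–13 of a repeating design;
half-trajectory agreement compares each half's means with the full-series
means.  Angular differences are circular, wrapped to [0°, 180°].  The
default thresholds (repeat: 0.25 Å translational / 2° rotational / 5°
backbone; halves: 0.1 Å / 2° / 3° with ε and ζ allowed 8°) are the agreement
bounds observed for well-converged microsecond trajectories, repurposed as
QC defaults; they are descriptions of converged behaviour, not laws, and are
configurable.  The default equilibration trim drops the first 10% of
snapshots (100 ns of a 1 μs trajectory at 1 ps spacing).

## Synthetic generator

The generator emulates the statistical structure of the microsecond
trajectories, not their physics.  Per junction, a hidden first-order Markov
chain switches between substates (resampled from the stationary weights with
probability 1/dwell per snapshot; default dwell 100 snapshots — kinetics are
free parameters since only occupancies and couplings are measured).  Helical
parameters are state-conditional Gaussians; backbone torsions are wrapped
normals with BI emitting (ε≈187°, ζ≈265°) and BII (ε≈250°, ζ≈172°);
Watson–Crick distances sit near 2.95 Å with rare Markov break bursts beyond
3.5 Å.  The `paper2014` preset encodes the reported statistics: canonical
twist 32.5°, propeller −11°, inclination 7°, Xdisp −1.5 Å; CG twist wells at
20°/40°; an RR high-twist substate at +5° tied to Watson BII; YR low-twist
substates tied to 3′-flank BII states; BII↔H-bond coupling targeting
P(HB|BII) = 0.90 and P(BII|HB) = 0.87.

The H-bond coupling is parameterized by the two conditionals plus the BII
marginal.  Because the bonded (N(3.5 Å, 0.2)) and unbonded (N(4.8 Å, 0.4))
distance regimes overlap the 4 Å cutoff, the regime probabilities are solved
in closed form *through* that overlap, so the conditionals measured by
re-classifying distances equal the targets in expectation.  For contexts
with small BII marginals the unbonded regime's leakage below 4 Å alone can
exceed what P(BII|HB) permits; the BI-state bonded-regime probability then
clamps at zero and the achieved P(BII|HB) saturates slightly below target —
only the high-BII (RR-like) presets are used for coupling recovery checks.

What the generator does **not** emulate: autocorrelation beyond a single
dwell scale, cross-junction coupling in full-oligomer mode (substate↔3′-flank
coupling is honoured in 4-level fragment mode, where the analysis needs it),
non-Gaussian emission shapes within a substate, sequence-dependent
force-field energetics, and solvent/ion structure.  Passing tests therefore
demonstrate that the analysis recovers known statistical structure, not that
it is validated against real MD output.

## Problem sizes and determinism

The test suite uses 2×10⁴–10⁵-snapshot fragments and a 3×10⁴-snapshot
18-level oligomer; coupling recovery uses one 10⁶-snapshot fragment and mode
recovery a 10⁵-snapshot CG fragment — sizes at which binomial/KDE standard
errors are comfortably inside the stated tolerances.  All simulation flows
from a single integer seed through one generator stream; identical
seed+configuration reruns are bit-identical.  `scripts/acceptance.py`
derives per-target sub-seeds from its `--seed` argument.

## Known limitations

* Helical-axis (Xdisp/Ydisp/inclination/tip) and groove parameters are
  pass-through fields; no curvilinear axis is fitted from coordinates.
* The canonical-name rule for non-symmetric tetranucleotide pairs may differ
  from other published tables for some pairs (deterministic and documented;
  remappable).
* The dip calibration is simulation-based at a fixed subsample size; it is a
  screening diagnostic, not an exact test.
* ρ̂_T p-values and rank-based circular correlations are out of scope.
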