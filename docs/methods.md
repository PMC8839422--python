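# Methods

## Scope and model system

mgatekit analyzes trajectories of pseudo-symmetric membrane carriers of
the mitochondrial carrier family (MCF) fold: three homologous domains,
each contributing an odd- and an even-numbered transmembrane helix
(domain 1: H1–h12–H2, domain 2: H3–h34–H4, domain 3: H5–h56–H6), with a
salt-bridge/H-bond network — the matrix gate (m-gate) — sealing the
pocket near the matrix side of the cytosol-open state. The package
computes the analyses this kind of study rests on: interaction
occupancies and their intra-/inter-helical classification, inter-domain
attachment scores, the triplet-based C3-symmetry deviation ψ, RMSF
profiles, minimum-distance time series, interface gap (crevice) events
and bridging-solvent counts.

Because microsecond all-atom trajectories of the real carrier are not
publicly deposited, validation runs on a synthetic toy carrier whose
correct answers are known exactly (below). Real structures and
trajectories enter through standard PDB / multi-model PDB files.

## The ψ symmetry metric

A *triplet* is the set of three residues occupying equivalent positions
in the three homologous domains, indexed by the domain-1 residue
number. Members sit at fixed sequence offsets; for the bovine ADP/ATP
carrier numbering the odd-helix offsets are (0, +105, +202), so triplet
33 is (L33, T138, R235). Offsets are configurable because the exact
H3/H5 registration can differ between carriers.

For each frame, the three Cα atoms of a triplet form a triangle with
interior angles θ₁, θ₂, θ₃. The symmetry deviation is

    ψ = ( |θ₁ − 60°| + |θ₂ − 60°| + |θ₃ − 60°| ) / 3    [degrees]

ψ = 0 exactly for any equilateral configuration (perfect threefold
symmetry) and tends to 80° as the triangle degenerates toward
collinearity (180°, 0°, 0°). Deviations are taken as absolute values
before averaging: signed deviations sum to zero for every triangle, so
the absolute-value reading is the only non-degenerate one. An RMS
variant (`psi_mode: rms`) is provided for conventions that average
quadratically; it is never smaller than the mean-absolute value.

ψ is internal to each triangle — invariant under rigid motion, uniform
scaling and permutation of the three points — so no superposition is
applied before computing it. Coincident points (side < 1e-6 Å) raise a
degenerate-triangle error rather than returning 80°, to distinguish
corrupted coordinates from genuine extreme asymmetry.

## Interaction criteria

The geometric criteria are the widely used conventions; all are
configurable per run and per interaction:

| interaction | criterion | default |
|---|---|---|
| salt bridge | min side-chain N···O distance ≤ cutoff | 4.0 Å (boundary = formed) |
| H-bond | donor–acceptor heavy-atom distance ≤ d, and H–D–A angle ≤ α when an H exists | 3.5 Å, 30° |
| guanidinium stacking | plane-centroid distance ≤ d and interplanar angle (folded to [0°, 90°]) ≤ α | 5.0 Å, 30° |
| ligand contact | minimum-distance criterion against a HETATM selection | 4.0 Å |

Charged sites are NH1/NH2/NE (Arg), NZ (Lys), OD1/OD2 (Asp), OE1/OE2
(Glu); coarse models may carry a single charge-site pseudo-atom ("CS")
per residue instead. Hydrogen-free topologies (crystal structures, toy
models) use the distance-only H-bond criterion.

Occupancy is the percentage of analysis-window frames in which the
criterion holds. The default window discards the first 20% of frames
(the usual equilibration discard); it can be given as frames or as
fractions, with an optional frame stride. Occupancies are reported to
one decimal, rounded half away from zero. Rows under the 5% reporting
floor are flagged `below_floor` but retained, so system-to-system
comparisons never lose edges. Replicate trajectories can be combined
either as the mean of per-trajectory occupancies or by frame-count
weighting (equivalent to pooling frames); both are exposed because
published averages rarely state which was used.

Classification: an edge is *intra-helical* if both residues fall in the
same transmembrane helix of the configured helix map, *inter-helical*
if in two different helices, and *other* if either partner lies on a
loop or matrix-helix segment. The inter-domain attachment score of a
domain pair is the sum of occupancy percentages over inter-helical
edges bridging the two domains — a scalar summary of how strongly two
domains hold together (e.g. domains 2–3 tight, domain 1 loose).

## Superposition, RMSF, distances, gap events

Superposition is the least-squares optimal rigid fit (proper rotation,
det = +1), computed with scipy's Kabsch-style `Rotation.align_vectors`;
degenerate (collinear/coincident) fit groups are rejected. RMSF uses
the standard trajectory-analysis reference: window frames are fitted
onto the window-average structure, the average is refined once from the
fitted frames, frames are re-fitted, and RMSF_i = sqrt(⟨|r_i − ⟨r_i⟩|²⟩)
is taken about the final mean. Fitting on the crystal structure instead
is available by disabling the fit and superposing externally.

Minimum-distance series take, per frame, the minimum over all
heavy-atom (non-hydrogen) cross pairs of two disjoint groups. Gap
events are maximal runs of frames in which such a series exceeds an
openness cutoff (default 6.0 Å, strictly greater) for at least a
minimum duration (default 10 frames); events carry inclusive frame
bounds and the widest gap reached. The literature does not quantify
"crevice", so both parameters are explicit configuration. Bridging
solvent is counted as solvent oxygens (HOH/WAT/SOL) within a radius
(default 4.0 Å) of *both* interface groups.

## The synthetic toy carrier

The generator produces the study conditions for every recovery test; it
is not a tuning knob.

Geometry: six ideal α-helical Cα traces (rise 1.5 Å/residue, twist
100°/residue, helix radius 2.3 Å — the textbook α-helix idealization;
only relative geometry matters to the analyses), arranged as three
two-helix domains at 0°, 120°, 240° around the bundle axis at a bundle
radius of 12 Å, odd helices running up and even helices down, 50°
between the two helix axes of a domain. Domains 2 and 3 are exact
rotation images of domain 1, so the reference is C3-symmetric to
floating-point precision and every triplet's ψ is 0. Asymmetry is
injected by rotating domain 1 about the bundle axis and/or shifting it
radially; ψ responds strictly monotonically to rotations in [0°, 30°].

Channels: each channel is a two-state Markov chain (per-frame
transition probabilities k_on, k_off; stationary on-probability
k_on/(k_on+k_off)) driving the distance between two charge-site
pseudo-atoms. The moving site is re-placed each frame on the reference
inter-site axis at d_on (default 3 Å) or d_off (default 8 Å) plus
Gaussian jitter clamped to ±3σ_jitter; specs are rejected unless
d_on + 3σ < detection cutoff < d_off − 3σ, so geometric detection
reproduces the state sequence with zero errors and the measured
occupancy equals the realized on-fraction exactly. Channel residues are
named ARG/ASP so role resolution and basic×acidic auto-enumeration
treat them like all-atom residues.

Noise and solvent: isotropic Gaussian noise of standard deviation
noise_sigma is added to every atom each frame (expected RMSF =
σ√3); solvent pseudo-oxygens are resampled uniformly per frame within a
user-defined slab, with no excluded volume. One global seed expands
into independent per-component seeds (noise; each channel, keyed by its
residue pair; solvent), so adding a channel never changes another
component's realization and identical spec+seed gives bit-identical
output.

What the toy does *not* emulate: physical forces, a membrane,
correlated backbone motions, side-chain rotamers, water structure, or
any real carrier's occupancy values. Passing the recovery tests
demonstrates that the analysis stack measures what it claims on inputs
with known truth — not that any biological number is reproduced.

## Numerical choices

- Coordinates in Å, residue numbers 1-based (PDB), frames 0-based,
  times in ps; trajectory frame times use the common 10 ps save stride.
- PDB round-trips preserve coordinates to the 0.001 Å field precision;
  altloc keeps the highest-occupancy conformer; insertion codes are
  rejected (deterministic parsing); single-chain lookups may omit the
  chain when unambiguous.
- Angle computations clip cosines into [−1, 1] before arccos; triangle
  sides below 1e-6 Å are degenerate errors.
- Salt-bridge boundary distances (exactly at cutoff) count as formed;
  gap openness is strictly greater than the cutoff, making the two
  criteria complementary on band-structured synthetic data.
- Occupancy rounding: half away from zero, one decimal.
- Stationarity checks on channel on-fractions use the Markov-chain
  standard error sqrt(p(1−p)(1+ρ)/(1−ρ)/n), ρ = 1 − k_on − k_off: the
  i.i.d. binomial SE understates the noise of slowly mixing chains.
- CSVs are written with fixed float formatting and line terminators and
  the provenance block contains no timestamps, so identical inputs give
  byte-identical outputs.

## Problem sizes

The validation suite runs at sizes where the statistical tolerances are
meaningful yet the whole suite stays interactive: 20,000 frames for
occupancy recovery (stationary-law check at 3 chain-SE), 10,000 frames
for RMSF recovery (±5% of σ√3), 2,000 frames for gap-event recovery,
and a 6×30-residue, 5,000-frame, 3-channel, 200-water system for the
end-to-end determinism run.

## Known limitations

- The toy carrier has one atom per residue (plus pseudo-sites), so
  side-chain-specific criteria (stacking, H-bond angles) are exercised
  on purpose-built fixtures rather than on the toy trajectories.
- No periodic-boundary imaging: real trajectories must be pre-imaged.
- The H-bond detector enumerates donor/acceptor/hydrogen selections
  pairwise; it is meant for named pairs, not proteome-wide scans.
- `gap_events` operates on any scalar series; it does not itself verify
  that the series is a distance.
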