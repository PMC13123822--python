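# Methods

## Scope and data model

`carmap` quantifies binned, symmetric, intra-chromosomal (cis) contact
matrices and generates synthetic ones from an explicit loop-extrusion
model. Coordinates are 0-based and half-open everywhere (BED-native); bins
tile each chromosome at a fixed width (default 400 bp, the map resolution
used for yeast Micro-C-style analyses), with the last bin per chromosome
possibly short. CAR (cohesin-associated region) intervals are reduced to
their integer midpoints, floor((start+end)/2): the pile-up and offset
statistics need a single, symmetric anchor point per site, and overlapping
intervals are kept as separate anchors unless their midpoints coincide.
Raw counts are stored without iterative balancing; the observed/expected
transform plays the normalizing role for all loop statistics, and every
classification is invariant to global count scaling by construction.
Trans contacts are out of scope — every statistic here operates at
separations ≤ ~200 kb.

## Decay curves and derivative slopes

P(s) is the mean count per valid pixel pair: each separation diagonal d
contributes its summed counts over the (n − d) pairs at that separation,
aggregated on log-spaced distance bins with factor 1.25 per bin (an
exposed parameter). The diagonal itself is excluded and the default
minimum separation is two bins, the conventional guard against
self-ligation artifacts. Bins with zero valid pairs are flagged rather
than zeroed. Multiple chromosomes pool by concatenating diagonal sums and
pair counts before normalization, giving genome-wide curves. P(s) is not
normalized to unit mass; cross-sample comparability comes from simulating
every sample at an identical contact budget.

The slope curve is d log₁₀ P / d log₁₀ s computed on log₁₀ P after a
centered moving average over 3 bins (endpoints unsmoothed), using centered
finite differences with one-sided differences at the ends. On an exact
power law the slope is recovered to machine precision at interior points;
smoothing window and log factor are parameters, since the appropriate
values depend on sequencing depth.

Named distance bands summarize the curve (valid-pair-weighted mean of P
over bins intersecting the band): 2–10 kb (small random loops), 10–20 kb
(the cohesin-dependent regime), 20–50 kb (CAR-spacing loops), 50–200 kb
(the loop-expansion regime). The *slope shift* of a sample versus a
reference is the plain mean of the pointwise slope difference over a band;
because the mean of a derivative telescopes, the statistic is mostly
sensitive to contact mass entering or leaving the band at its edges, which
is exactly the expansion signature it is meant to capture.

## Observed/expected, pile-ups and offset profiles

E(d) is the per-diagonal mean count; O/E divides by it where E > 0 and
propagates undefined pixels as missing (never zero). With the per-matrix
expected, the mean of defined O/E values along every diagonal is exactly 1
(asserted to 1e−9 in the tests); a pooled-expected mode exists for
cross-sample comparison at matched depth.

Pile-ups stack ±5 kb windows centered on CAR–CAR anchor pairs with
separations in 15–100 kb (defaults; the lower bound must exceed twice the
window half-width so windows cannot cross the diagonal, and the range
covers the +1..+5 CAR-spacing regime for the shipped CAR density).
Out-of-bounds windows are skipped and counted. The map stores the
pixel-wise mean of log₂(O/E) with per-pixel denominators; pixels whose
O/E is undefined or zero in a window are excluded from that pixel's mean
(log₂ of zero is undefined), a convention that slightly favors non-empty
pixels at low depth and applies identically to every sample. The corner
enrichment score exponentiates the map back to linear O/E and divides the
center pixel by the mean over four corner blocks (default 3×3 pixels,
symmetric over all four corners; the block size is a documented default,
not a measurement). The map width is forced odd so a unique center exists.

CAR offset profiles take the mean O/E at single (CARₘ, CARₘ₊ₖ) pixels for
k = 1..5 across all m (a small-window averaging mode exists); undefined
pixels are skipped and per-offset pair counts are reported.

## The extrusion model

The generator is a discrete-time, bin-lattice, two-leg symmetric extruder
— the simplest mechanism that exhibits all the qualitative contrasts the
statistics measure. Per cell and chromosome, Poisson(λ · length in kb)
extruders load at uniformly random positions with legs on adjacent bins.
Each step, every live extruder releases with probability μ (multiplied by
γ ≤ 1 while both legs are halted at boundaries — boundary residence can
stabilize the complex), then each non-halted leg independently moves one
bin outward with probability v, the ATPase-speed proxy. A leg entering a
boundary bin (a CAR) halts there with probability p_stop; halting is
permanent per leg ("stop-and-stay"; a pause-and-resume variant is a config
flag, off by default). Legs clamp at chromosome ends. Every
`snapshot_interval` steps (default 15) each live extruder registers one
contact at (left bin, right bin), a stand-in for crosslinking
probability. Extruder–extruder collisions are ignored (legs pass through
each other): none of the target statistics depends on a collision rule.
Sister-chromatid cohesion and tethering are deliberately not modeled.

The cohesin-independent background draws contacts whose separation follows
a truncated power law s^−α (α = 1.5 by default), with the left endpoint
uniform over feasible positions; it carries no loop structure by
construction and is what remains in the cohesin-null sample. Total output
contacts equal registered extruder contacts plus background draws exactly,
and a fixed (seed, config) pair is bit-reproducible. All cells advance in
lock-step from a single seeded generator — vectorizing across cells is
what keeps a 2,000-cell, 7-sample panel under ten seconds on one core.

Because speed, processivity and boundary stabilization are distinct
candidate explanations for how ATPase activity shapes loop positioning,
the model exposes all three as independent knobs (v, μ, γ) rather than
committing to one.

## Study defaults and presets

The default study condition is one 500-kb chromosome at 400-bp bins,
2,000 cells, 1,000 steps, 1,200 background contacts per cell, and a CAR
ladder with 14-kb mean spacing (±2.5 kb jitter, 14-kb end margins; ~34
sites), emulating the dense, quasi-regular CAR spacing of yeast
chromosome arms. At these sizes the statistics resolve a graded +1..+5
offset decline above counting noise while the whole panel stays in the
seconds-to-minutes range.

Preset kinetics are calibration constants, not measurements: they were
chosen so the panel reproduces the qualitative phenotype orderings and
then frozen.

| preset   | λ /kb | v    | μ      | p_stop | γ    | encodes |
|----------|-------|------|--------|--------|------|---------|
| WT       | 0.015 | 0.35 | 0.0015 | 0.97   | 0.35 | near-complete boundary capture, stabilized positioned loops |
| MCD1-AID | 0     | —    | —      | —      | —    | cohesin depletion: background only |
| ECO1-AID | 0.015 | 0.35 | 0.0015 | 0      | 1.0  | boundary-blind extrusion: expanded, unpositioned loops |
| K112R    | 0.015 | 0.35 | 0.0015 | 0.90   | 0.35 | mildly weakened capture: positioned, slightly longer |
| K113R    | 0.011 | 0.35 | 0.0015 | 0.90   | 0.5  | as K112R with attenuated activity |
| DE       | 0.015 | 0.34 | 0.0015 | 0      | 1.0  | ATPase-site mutant: phenocopies ECO1-AID, slightly slower motor |
| TI       | 0.015 | 0.70 | 0.0015 | 0.97   | 0.12 | fast motor, strong boundary residence: more positioned, less fuzz |

Two structural choices matter and are deliberate. First, wild-type capture
is nearly complete (p_stop 0.97) and CAR spacing is 14 kb, so positioned
mass above ~45 kb is negligible relative to the background: this keeps the
50–200 kb slope of every non-expanded sample background-like, which is
what makes the expansion classification specific (a leakier wild type
plants positioned peaks at the band edge and spuriously separates it from
the cohesin-null sample). Second, leaked loops still receive γ
stabilization, which is what produces the graded, strictly decreasing
+1..+5 offset signal above pixel noise.

## Classification

Positioned loops are called present iff corner enrichment ≥ 1.5; loop
expansion iff the 50–200 kb slope shift versus the designated wild-type
reference ≥ 0.05. Both thresholds are explicit calibration constants
(CLI-tunable, recorded in the report header): real studies make these
calls visually, and the point here is to make them reproducible, not to
claim measured cutoffs. Ties classify as present/expanded (≥ convention).
The wild-type and cohesin-null references are explicit named samples in
the report configuration.

## What the generator does and does not emulate

The synthetic matrices contain the three ingredients the statistics are
built to separate — distance-decaying background, extrusion fuzz with
variable anchors, and positioned CAR–CAR spots — with realistic relative
amplitudes. They do not emulate restriction/MNase digestion bias,
mappability structure, balancing artifacts, trans contacts, inter-sister
contacts, replicate variation, or collision-mediated traffic jams of
extruders. Positioned anchors are delta-like (a halted leg sits in exactly
one bin), so pile-up enrichments are numerically much larger than in real
chromatin data, where anchor spread and noise dilute the center pixel;
passing the ordering and classification tests therefore demonstrates that
the statistics rank architectures correctly, not that real-data effect
sizes are reproduced.

## Numerical conventions and degenerate inputs

Log-binned curves use geometric-mean bin midpoints; empty log bins are
flagged and excluded from slopes. Slopes require ≥ 3 usable bins.
Pile-ups require ≥ 1 window; offset profiles require ≥ K+1 anchors;
corner blocks with no defined pixel raise a degenerate-input error (the
pile-up constructor stores NaN enrichment in that case so partial results
remain inspectable). COO round trips are exact for integer counts.
Matrices are validated (symmetry, non-negativity) on every construction
and read.

## Known limitations

Single-chromatid, collision-free extrusion on a 1D lattice; permanent
halting by default; no Wpl1-style unloading pathway (wpl1Δ-like presets
would need a distinct unloading mechanism and are an extension point); no
balancing, so externally supplied matrices should be raw or pre-normalized
consistently across samples; genome-wide pooling assumes a shared bin size
across chromosomes.
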