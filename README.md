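# carmap

Contact-map loop statistics and a stochastic loop-extrusion simulator for
budding-yeast cohesin biology.

In yeast, the cohesin complex extrudes chromatin loops that stall at
recurrent cohesin-associated regions (CARs), producing "positioned loops"
visible as off-diagonal spots in Micro-C/Hi-C contact maps, on top of a
diffuse "fuzz" of random loops and a polymer background. Mutations that
perturb cohesin's ATPase activity or its Smc3 acetylation change this
architecture in characteristic ways: losing cohesin removes the loop signal
entirely, losing acetylation lets extrusion run past CARs (loop expansion
with loss of positioned loops), and a hyperactive ATPase converts random
loops into positioned ones.

`carmap` provides the quantification pipeline used to read these phenotypes
out of binned cis contact matrices, plus a generative model to produce such
matrices from explicit extrusion kinetics:

- **Decay curves and slopes** — contact probability *P(s)* versus genomic
  separation *s* on log-spaced bins, and its derivative
  d log₁₀ *P* / d log₁₀ *s*, whose bumps report characteristic loop sizes.
- **Observed/expected and pile-ups** — *O/E(i,j) = counts(i,j) / E(j−i)*
  with *E(d)* the mean count at separation *d*; windows around CAR–CAR
  anchor pairs are stacked into a mean log₂(O/E) map, scored by **corner
  enrichment** (center-pixel O/E over the mean of the four corner blocks),
  the fold-change statistic for positioned-loop strength.
- **CAR offset profiles** — mean O/E at (CAR*ₘ*, CAR*ₘ₊ₖ*) pixels for
  *k* = 1..5, the graded decline of looping with anchor distance.
- **Loop-extrusion simulator** — a discrete-time two-leg extruder on a bin
  lattice: loading rate λ (per cell per kb), per-step leg speed *v*, release
  rate μ, boundary capture probability *p*<sub>stop</sub> at CAR bins, and
  boundary stabilization γ (release slowed while both legs are stalled),
  over a power-law polymer background *P(s)* ∝ *s*<sup>−α</sup>. Seven
  phenotype presets (WT, MCD1-AID, ECO1-AID, K112R, K113R, DE, TI) encode
  the mutant-panel contrasts as parameter changes.
- **Phenotype report** — per-sample band summaries, slope shifts versus a
  wild-type and a cohesin-null reference, corner enrichment and offset
  profiles, plus two explicit classifications: *positioned loops present*
  (corner enrichment ≥ 1.5) and *loop expansion* (mean slope shift versus
  WT in the 50–200 kb band ≥ 0.05).

## Worked example

Simulate a four-sample panel (2,000 cells each, 500-kb chromosome at 400-bp
bins, ~34 CARs) and classify it:

```toml
# panel.toml
binsize = 400
n_cells = 2000
n_steps = 1000
seed = 1
reference = "WT"
null_reference = "MCD1-AID"

[genome]
chromosomes = [{name = "chrSim", length = 500000}]

[car_ladder]
spacing = 14000
jitter = 2500
margin = 14000
seed = 2

[samples.WT]
preset = "WT"
[samples.MCD1-AID]
preset = "MCD1-AID"
[samples.ECO1-AID]
preset = "ECO1-AID"
[samples.DE]
preset = "DE"
```

```text
$ carmap --quiet report panel.toml -o out
  sample  corner_enrichment  slope_shift_vs_wt_50-200kb  positioned_loops  loop_expansion
      WT          32.926501                    0.000000              True           False
MCD1-AID           1.005911                    0.017623             False           False
ECO1-AID           0.949155                    0.358393             False            True
      DE           0.964443                    0.301316             False            True
```

Reading the numbers: the wild type shows a 33-fold center-over-corner
enrichment at CAR pairs — strong positioned loops — and defines the slope
reference. Depleting cohesin (MCD1-AID) leaves only the polymer background:
no enrichment (≈1.0) and essentially no long-range slope shift. Removing
acetylation (ECO1-AID) or the ATPase active-site mutation (DE) abolishes
boundary capture: enrichment collapses to ≈1 while the decay slope in the
50–200 kb band rises by +0.36 and +0.30 — expanded loops with random
anchors. Per-sample decay curves, slopes, band summaries, pile-up maps and
CAR offset profiles are written next to `report.tsv` in `out/`.

The same statistics are available as functions (`contact_decay`,
`derivative_slope`, `observed_over_expected`, `pileup`,
`corner_enrichment`, `car_offset_profile`, `simulate`, ...) and as the CLI
subcommands `simulate`, `decay`, `pileup`, `profile` and `report`.

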