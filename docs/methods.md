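# Methods

## The forward model

S-phase on a chromosome is modelled as a set of point origins and
constant-velocity bidirectional forks. In each cell, origin *i* fires with
probability `efficiency_i`; if it fires, its firing time is drawn from a
normal distribution `N(mean_firing_time_i, firing_sd_i)` truncated at 0
(the distributional form is a modelling choice; the assay constrains only
the population median). A locus at position *x* is replicated at

    T(x) = min_i over fired origins ( t_i + |x − p_i| / v )

so unfired origins are replicated passively by incoming forks. There is no
re-firing and no fork stalling or pausing, and chromosomes are linear with
no telomere-specific delay. Cells that fire no origin on a chromosome are
resampled, since a chromosome must finish replication; this slightly
conditions the joint firing pattern when all efficiencies are small, which
is irrelevant at the default efficiency (0.85).

At the population level each cell receives an S-entry delay
`N(40, 10) min` truncated at 0 (cultures released at t = 0 enter S around
40 min) and enters S-phase at all with probability `fraction_cycling`
(default 0.8). Kinetic curves therefore plateau below 100%, which is why
locus T_rep is measured against the plateau of a genomic probe rather than
against 100%.

The centromere's influence on origin timing is phenomenological: a
functional centromere advances the mean firing time of an origin at
distance *d* by `max_advance · decay(d)`, floored at 0 min. The decay
shape is configurable (`linear` — the default, reaching 0 at `range_bp` =
19 kb; `exponential`; `step`) because the assay constrains only that the
effect is strong within ~11.5 kb and severely diminished by ~19 kb, not
its functional form. A centromere whose CDEIII core differs from the
wild-type `TCCGAA` assembles no kinetochore and confers no advance;
functionality is derived from the sequence, never stored separately.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `fork_velocity` | 800 | bp/min | the published replication indices of the pericentric origin cluster (ARS1424 → ARS1426, 25.8 kb apart, 26 min apart in the rearranged strain) are mutually consistent only for v ≲ 1 kb/min; 800 bp/min sits inside the measured yeast fork-rate range |
| `s_entry_mean`, `s_entry_sd` | 40, 10 | min | synchronous release with entry by ~40 min and 2C DNA content by ~140 min |
| `fraction_cycling` | 0.8 | — | sub-100% kinetic plateaus; the exact level is not published |
| `firing_sd` | 4 | min | cell-to-cell origin timing spread; combined with entry spread gives curves spanning ~40 min |
| `efficiency` | 0.85 | — | deliberately identical across scenarios and origins, because 2D gels showed the centromere does not change origin efficiency |
| RI anchors | 45, 95 | min | T_rep of the early/late standards, inside the observed S-phase window |
| `n_cells` | 500 | cells | Monte-Carlo population size; per-timepoint sampling error ~2 percentage points |

## Scenarios and their truth tables

Absolute coordinates are invented; only the published relative geometry is
binding: the native centromere 6.8 kb left of ARS1426, ARS1424 19 kb left
of the native centromere, the MET2 BglII site 8.5 kb left of ARS1410, and
the ectopic centromere 11.5 kb from ARS1410. The MET2 *tracked locus* is
the midpoint of the probed restriction fragment, placed 4.0 kb left of
ARS1410 (between the BglII site and the origin): the fragment spans that
interval, and a fragment is scored replicated when its midpoint is
replicated.

Each scenario's ground truth is a per-locus table of true replication
times, `trep = 45 + RI·(95 − 45)` from the published replication indices;
origin mean firing times are set as `trep − 40` (entry mean). The truth is
parameterized per scenario rather than derived from the distance-decay
modifier because no single decay law reproduces all published indices
simultaneously (the implied advance is ~31.5 min at 6.8 kb but ~27 min at
11.5 kb); the decay modifier is retained as a model component and
validated qualitatively — applying it to a centromere-naive chromosome
XIV inverts the ARS1410/ARS1426 ordering exactly as moving the centromere
does. MET2 carries **no** origin (2D gels show none): its timing emerges
from passive replication by ARS1410's forks, which reproduces the
wild-type MET2 index but makes rearranged met2 recover ~0.33 rather than
the published 0.24 — fork travel over 4 kb cannot be 0.5 min, a known
limit of single-velocity kinematics.

Filler origins (RI 0.40–0.50, identical across scenarios, spacing
~65–82 kb) stand in for the rest of the origin complement so every
chromosome finishes replication by ~120 min and the genomic probe truly
plateaus; the real genome is denser still. A standards chromosome carries
the ARS306-role, ARS1-role and R11-role loci and no centromere; a
chromosome XV-like chromosome carries ARS1531, whose single-base ACS
mutant can be injected as an origin knockout (`efficiency = 0`) to emulate
the strain polymorphism that silences it.

## Observation models

**Gradients.** A locus with replicated fraction *f* contributes HH mass
(1 − f) and HL mass 2f (each replicated molecule yields two hybrid
daughters — total mass 1 + f, conserved). Masses spread as Gaussians
across 25 fractions (HH peak at fraction 17, HL at 9, sd 1.2 — denser DNA
lower in the gradient), then gain an additive background (0.02) and
multiplicative lognormal noise (CV 5%). Pooling windows default to ±3
fractions around each peak; the median of out-of-window fractions is
subtracted as background, floored at 0. The genomic probe averages *f*
over a 5-kb grid across all chromosomes.

**Arrays.** Probes on a 2-kb grid; per probe hh ∝ (1 − f) + background,
hl ∝ 2f + background, each with independent lognormal noise and a global
per-channel scale factor. Median channel equalization removes the channel
scales exactly but does not calibrate the absolute HL/HH ratio (the two
channels' underlying masses have different medians), so per-probe percent
values carry a shared monotone distortion; every profile comparison (peaks,
Z-scores, differences) is invariant to it because both strains are
processed identically. One cell population is shared across all probes of
a chromosome, so spatial structure is coherent within a cell.

## Inference choices

- **Percent replication** `100·HL/(HL + 2·HH)`: HL mass is halved to count
  molecules.
- **Plateau** = mean of the final 3 genomic-curve points; the number of
  trailing points is a parameter (`plateau_k`).
- **T_rep** = first upward crossing of plateau/2, linearly interpolated
  between the bracketing samples; a first sample already above the half
  level returns the first time; the first-crossing rule resolves
  non-monotone noisy curves deterministically.
- **Replication index** uses denominator `(late − early)` so the anchors
  (early → 0, late → 1) hold.
- **Smoothing**: 18 kb interpreted as full width (±9 kb), unweighted mean
  over probes in the window, truncated at chromosome ends; a box mean is
  the documented choice where the kernel is not otherwise constrained.
- **Z-scores** use the population (ddof = 0) standard deviation, computed
  genome-wide per timed sample; with thousands of probes the
  sample/population distinction is negligible but the choice is fixed.
- **Peaks**: strict local maxima with prominence (height above the higher
  flanking minimum) ≥ `min_prominence` (default 2 percentage points,
  calibrated on noise-free simulations); chromosome-end probes are never
  peaks.
- **Sample matching**: two same-timepoint samples are comparable when
  their genome-mean percent replication differs by ≤ 10 points; mismatched
  pairs are excluded with a logged report.
- **Timing differences**: maximal runs of ≥ 3 consecutive probes with
  |ΔZ| ≥ 1.5 at *every* matched timepoint. The default comparison
  timepoints are mid-S samples (55, 65, 75 min): at the simulated
  synchrony, very early samples carry almost no replicated signal at loci
  whose shifted T_rep is ~56 min, so a persistence rule that includes them
  cannot flag genuine differences at any threshold. Thresholds are
  calibrated so the wild-type-vs-rearranged simulation flags exactly the
  two pericentric loci; both are exposed as flags.

## Problem sizes

Recovery experiments use 25 replicate simulated time courses per scenario
(15 samples each, 500 cells per chromosome); array comparisons use a 2-kb
probe grid over ~1.4 Mb of simulated genome and 3 timepoints; the
false-positive control uses 20 independent same-scenario pairs. These
sizes put Monte-Carlo error well below the 0.05 RI tolerance of the
recovery checks while keeping any single experiment under a few seconds.

## What passing tests do and do not show

The generator emulates synchronized release, incomplete S-phase entry,
multiplicative signal noise and the published chromosome XIV geometries.
It does not emulate dye-bias curves or spatial artifacts on arrays,
partially replicated fragments at intermediate buoyant density, fork
stalling (the centromeric pause site), replication checkpoints, telomere
effects, or probe-length effects (probes are points). Parameter recovery
on these fixtures therefore demonstrates that the inference chain is
correct and well-calibrated under the stated noise model — not that real
arrays or gradients are free of platform-specific systematics.

## Known limitations

- Single global fork velocity; loci whose published timing implies
  locally different effective fork progression (rearranged met2) recover
  with a ~0.1 RI offset.
- The centromere decay law is phenomenological and cannot reproduce every
  published index simultaneously; scenario truth comes from the indices
  themselves.
- Median channel equalization leaves a shared monotone distortion in
  per-probe percent values (see above).
- A locus that never reaches half-maximal replication within the time
  course is an error by design, not an extrapolation.
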