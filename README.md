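# repkin

Replication-timing analysis for Meselson–Stahl **density-transfer**
experiments in budding yeast, with a stochastic origin-firing simulator that
regenerates the classic centromere-relocation experiments on chromosome XIV.

Cells pre-grown on heavy isotopes (¹³C/¹⁵N) are released synchronously into
light medium: unreplicated DNA stays heavy-heavy (**HH**) while replicated
DNA becomes hybrid heavy-light (**HL**), and the two classes separate in
CsCl gradients. From timed samples, `repkin` infers when each locus
replicates and whether two strains differ — the assay used to show that a
*functional* centromere advances the firing time of nearby origins in *cis*
over ~19 kb.

## What it computes

**Locus level (slot blots).** For each probed restriction fragment and
timepoint, gradient fractions are pooled into HH and HL masses
(median-background subtracted) and converted to percent replication at the
molecule level,

```
% replication = 100 · HL / (HL + 2·HH)
```

(each replicated duplex yields *two* HL daughters). Percent-vs-time curves
give **T_rep**, the time of half-maximal replication measured against the
plateau of a total-genomic probe (not all G1 cells enter or complete
S-phase). T_rep values are rescaled to **replication indices**,

```
RI(X) = (T_rep(X) − T_rep(early)) / (T_rep(late) − T_rep(early))
```

so the early standard (ARS306 role) maps to 0 and the late standard (R11
role) to 1.

**Genome level (arrays).** Per-probe percent replication from two-channel
HH/HL intensities (median channel equalization), 18-kb sliding-window
smoothing, Z-score normalization `Z = (X − μ)/σ` with genome-wide μ, σ per
timed sample, origin-peak calling, and detection of inter-strain timing
differences as runs of probes whose |ΔZ| exceeds a threshold at **every**
compared timepoint (differences must persist across S-phase).

**Simulator.** A forward model of S-phase — origins with firing-time
distributions, efficiencies, constant-velocity bidirectional forks, a
non-cycling cell fraction, and a distance-decaying centromere timing
advance — plus observation models for gradients and arrays. Shipped
scenarios (`wt`, `rearranged`, `cen_dead`) encode the published chromosome
XIV geometries (centromere 6.8 kb from ARS1426; ectopic centromere 11.5 kb
from ARS1410; ARS1424 19 kb from the native centromere; CDEIII-dead
centromere at MET2) with truth tables parameterized from the published
replication indices.

## Worked example

```
$ repkin simulate --scenario wt --seed 1 --out-dir demo/wt
simulate: wrote 124 files to demo/wt
$ repkin kinetics --scans demo/wt/scans.tsv --out demo/wt_timing.tsv
kinetics: plateau 70.43%, 7 fragments -> demo/wt_timing.tsv
$ cat demo/wt_timing.tsv
fragment_id  trep_min     replication_index
ARS1         79.23126646  0.67326962
ARS1410      84.70124928  0.7876890764
ARS1424      51.4932853   0.09305486685
ARS1426      55.45036042  0.1758277749
ARS306       47.0446667   0
MET2         88.86331698  0.8747499578
R11          94.85107116  1
```

One simulated wild-type run: the standards anchor the scale (ARS306 → 0,
R11 → 1); the pericentric origins ARS1424 and ARS1426 replicate early
(RI ≈ 0.09 and 0.18 against published 0.11 and 0.16) while ARS1410 and
MET2, far from the centromere, replicate late (RI ≈ 0.79 and 0.87 against
published 0.77 and 0.87). The genomic plateau sits below 80% because only
80% of simulated cells cycle and origins fire in 85% of cells.

`repkin profile` turns probe tables into raw/smoothed/Z bedGraphs and a
peak BED; `repkin compare` reports persistent Z-score difference regions
between two strains as BED intervals. On simulated wild-type vs rearranged
arrays it flags exactly two chromosome XIV regions — around ARS1410 and
ARS1426 — and nothing elsewhere.

## Layout

- `repkin.model` — stochastic S-phase forward model (origins, forks,
  centromere effect, cell populations)
- `repkin.kinetics` — gradient pooling, percent replication, T_rep,
  replication index, full pipeline
- `repkin.profile` — array profiles, smoothing, Z-scores, peaks,
  persistent-difference detection
- `repkin.scenarios` — scenario bundles, observation simulators, sequence
  utilities (CDEIII/ACS), fixture emission
- `repkin.workflows` — simulate→analyze recovery experiments
- `repkin.cli` — `repkin simulate | kinetics | profile | compare`

See `docs/methods.md` for the model, its assumptions and parameter choices.
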