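"""Synthetic density-transfer experiments on chromosome XIV-like scenarios.

Three scenarios reproduce the geometry of the centromere-relocation
experiments on chromosome XIV:

``wt``
    The native centromere sits 6.8 kb to the left of ARS1426; the MET2
    BglII site lies 8.5 kb to the left of ARS1410; ARS1424 lies ~19 kb to
    the left of the native centromere.
``rearranged``
    The native centromere is replaced (URA3 marker) and a functional
    centromere is integrated at MET2, ~11.5 kb from ARS1410.
``cen_dead``
    A CDEIII point-mutated (TCCGAA -> TCTAGA), non-functional centromere is
    integrated at MET2 while the native centromere is retained.

Each scenario carries a per-locus table of true replication times derived
from the published replication indices through trep = early + RI*(late -
early) with anchors 45 and 95 min; origin mean firing times are set from
those targets (minus the mean S-entry delay), so the centromere's timing
effect is encoded in the scenario truth rather than re-derived from the
phenomenological distance-decay modifier (see docs/methods.md).  A
standards chromosome carries the ARS306-role early standard, the R11-role
late standard and an ARS1-role trans-chromosome control; a chromosome
XV-like chromosome carries ARS1531, whose ACS point mutant can be injected
as an origin knockout.

The observation simulators emulate the two assays: CsCl gradient slot blots
(HH and HL Gaussian peaks across gradient fractions, lognormal signal
noise, additive background) and two-channel arrays (per-probe HH/HL
intensities with channel scale factors and lognormal noise).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .kinetics import GradientScan, scans_to_frame
from .model import (
    CDEIII_WILDTYPE,
    Centromere,
    CentromereEffect,
    ChromosomeModel,
    Origin,
    SimulationParams,
    population_locus_times,
    sample_population,
)

__all__ = [
    "ACS_WILDTYPE",
    "CDEIII_DEAD",
    "EARLY_TREP",
    "LATE_TREP",
    "SCENARIO_NAMES",
    "NoiseModel",
    "GradientGeometry",
    "ScenarioBundle",
    "build_scenario",
    "intrinsic_chrxiv",
    "simulate_slotblot_experiment",
    "simulate_array_experiment",
    "hamming_distance",
    "acs_is_functional",
    "write_fixture_set",
]

#: Wild-type ARS consensus sequence (ACS); the single T->C substitution at
#: position 4 abolishes origin activity.
ACS_WILDTYPE = "ATATTTATATTTAGA"
#: CDEIII core of the point-mutated, non-functional centromere.
CDEIII_DEAD = "TCTAGA"

#: RI -> minutes anchors: T_rep of the early (ARS306-role) and late
#: (R11-role) standards, inside the observed S-phase window.
EARLY_TREP = 45.0
LATE_TREP = 95.0

SCENARIO_NAMES = ("wt", "rearranged", "cen_dead")

# ---------------------------------------------------------------------------
# Invented absolute coordinates satisfying the published relative geometry.
# ---------------------------------------------------------------------------
CHR14 = "chrXIV"
CHR14_LEN = 784_000
ARS1410_POS = 412_000
MET2_BGLII_POS = ARS1410_POS - 8_500  # BglII site in MET2, 8.5 kb left of ARS1410
# Midpoint of the probed MET2 restriction fragment: the fragment spans the
# region between the BglII site and ARS1410, and a fragment counts as
# replicated when its midpoint is replicated.
MET2_POS = ARS1410_POS - 4_000
NATIVE_CEN_POS = 628_800
ARS1426_POS = NATIVE_CEN_POS + 6_800  # CEN 6.8 kb to the left of ARS1426
ARS1424_POS = NATIVE_CEN_POS - 19_000  # ~19 kb left of the native centromere
ECTOPIC_CEN_POS = ARS1410_POS - 11_500  # integrated at MET2, ~11.5 kb from ARS1410

CHRSTD = "chrSTD"
CHRSTD_LEN = 240_000
ARS306_POS = 40_000
ARS1_POS = 130_000
R11_POS = 220_000

CHR15 = "chrXV"
CHR15_LEN = 400_000
ARS1531_POS = 200_000

# Filler origins keep inter-origin gaps near the genome's real origin
# density so every chromosome finishes replication well inside the 140-min
# time course; their timing is identical across scenarios.
_FILLER_RI = {
    "oriXIV_L1": (40_000, 0.40),
    "oriXIV_L2": (115_000, 0.40),
    "oriXIV_L3": (190_000, 0.40),
    "oriXIV_L4": (265_000, 0.40),
    "oriXIV_L5": (330_000, 0.40),
    "oriXIV_M1": (480_000, 0.45),
    "oriXIV_M2": (545_000, 0.45),
    "oriXIV_R1": (700_000, 0.45),
    "oriXIV_R2": (760_000, 0.45),
}
_CHRSTD_FILLER_RI = {"oriSTD_1": (175_000, 0.50)}
_CHR15_RI = {
    "oriXV_1": (30_000, 0.50),
    "oriXV_2": (110_000, 0.55),
    "ARS1531": (ARS1531_POS, 0.15),
    "oriXV_3": (290_000, 0.55),
    "oriXV_4": (370_000, 0.50),
}

# Published replication indices per scenario (origin loci and the passively
# replicated MET2 fragment).  The MET2 entry parameterizes the truth table;
# in the simulation MET2 carries no origin and is replicated by forks.
_SCENARIO_RI: dict[str, dict[str, float]] = {
    "wt": {
        "MET2": 0.87,
        "ARS1410": 0.77,
        "ARS1424": 0.11,
        "ARS1426": 0.16,
        "ARS306": 0.0,
        "ARS1": 0.68,
        "R11": 1.0,
    },
    "rearranged": {
        "MET2": 0.24,
        "ARS1410": 0.23,
        "ARS1424": 0.27,
        "ARS1426": 0.79,
        "ARS306": 0.0,
        "ARS1": 0.66,
        "R11": 1.0,
    },
    "cen_dead": {
        "MET2": 0.81,
        "ARS1410": 0.74,
        "ARS1424": 0.11,
        "ARS1426": 0.16,
        "ARS306": 0.0,
        "ARS1": 0.68,
        "R11": 1.0,
    },
}

#: Centromere-naive ("intrinsic") RIs used by :func:`intrinsic_chrxiv`:
#: each origin's timing when no functional centromere is nearby.
_INTRINSIC_RI = {"ARS1410": 0.77, "ARS1424": 0.27, "ARS1426": 0.79}

_LOCI: dict[str, tuple[str, int]] = {
    "MET2": (CHR14, MET2_POS),
    "ARS1410": (CHR14, ARS1410_POS),
    "ARS1424": (CHR14, ARS1424_POS),
    "ARS1426": (CHR14, ARS1426_POS),
    "ARS306": (CHRSTD, ARS306_POS),
    "ARS1": (CHRSTD, ARS1_POS),
    "R11": (CHRSTD, R11_POS),
}

GENOMIC_ID = "GENOMIC"


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal signal noise plus an additive background level."""

    signal_cv: float = 0.05
    background: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.signal_cv < 0:
            raise ValueError("signal_cv must be >= 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")

    def multiplier(self, rng: np.random.Generator, size) -> np.ndarray:
        """Unit-mean lognormal factors with the configured CV."""
        if self.signal_cv == 0:
            return np.ones(size)
        sigma = float(np.sqrt(np.log1p(self.signal_cv**2)))
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


@dataclass(frozen=True)
class GradientGeometry:
    """Positions and widths of the HH and HL peaks across gradient fractions.

    Denser (HH, unreplicated) DNA sits lower in the gradient, i.e. at a
    higher fraction index than the hybrid-density HL peak.
    """

    n_fractions: int = 25
    hh_peak_fraction: int = 17
    hl_peak_fraction: int = 9
    peak_sd: float = 1.2

    def __post_init__(self) -> None:
        if not self.hh_peak_fraction > self.hl_peak_fraction:
            raise ValueError("HH peak must sit at a higher fraction than the HL peak")
        if self.hh_peak_fraction - self.hl_peak_fraction < 4 * self.peak_sd:
            raise ValueError("HH and HL peaks must be separated by >= 4 * peak_sd")
        if self.n_fractions <= max(self.hh_peak_fraction, self.hl_peak_fraction):
            raise ValueError("peak fractions must lie within the gradient")

    @property
    def hh_window(self) -> tuple[int, int]:
        """Default half-open pooling window (+/- 3 fractions around the HH peak)."""
        return (self.hh_peak_fraction - 3, self.hh_peak_fraction + 4)

    @property
    def hl_window(self) -> tuple[int, int]:
        return (self.hl_peak_fraction - 3, self.hl_peak_fraction + 4)


@dataclass(frozen=True)
class ScenarioBundle:
    """A fully parameterized synthetic experiment."""

    name: str
    chromosomes: tuple[ChromosomeModel, ...]
    loci: Mapping[str, tuple[str, int]]
    true_trep: Mapping[str, float]
    effect: CentromereEffect
    params: SimulationParams
    noise: NoiseModel = field(default_factory=NoiseModel)
    geometry: GradientGeometry = field(default_factory=GradientGeometry)
    early_trep: float = EARLY_TREP
    late_trep: float = LATE_TREP

    @property
    def true_ri(self) -> dict[str, float]:
        span = self.late_trep - self.early_trep
        return {k: (v - self.early_trep) / span for k, v in self.true_trep.items()}

    def chromosome(self, name: str) -> ChromosomeModel:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)


def _ri_to_trep(ri: float) -> float:
    return EARLY_TREP + ri * (LATE_TREP - EARLY_TREP)


def _origin(oid: str, pos: int, ri: float, params: SimulationParams,
            firing_sd: float = 4.0, efficiency: float = 0.85) -> Origin:
    """Origin whose population half-replication time lands at the RI target."""
    return Origin(
        id=oid,
        position=pos,
        mean_firing_time=max(0.0, _ri_to_trep(ri) - params.s_entry_mean),
        firing_sd=firing_sd,
        efficiency=efficiency,
    )


def build_scenario(
    name: str,
    seed: int = 0,
    params: SimulationParams | None = None,
    noise: NoiseModel | None = None,
    ars1531_dead: bool = False,
) -> ScenarioBundle:
    """Construct the wt, rearranged or cen_dead scenario bundle.

    ``ars1531_dead`` injects the ACS point-mutant origin knockout on the
    chromosome XV-like chromosome (efficiency 0), emulating the strain
    polymorphism that silences ARS1531.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    if params is None:
        params = SimulationParams(seed=seed)
    if noise is None:
        noise = NoiseModel()
    ri = _SCENARIO_RI[name]

    xiv_origins = sorted(
        [
            _origin(oid, pos, fri, params)
            for oid, (pos, fri) in _FILLER_RI.items()
        ]
        + [
            _origin("ARS1410", ARS1410_POS, ri["ARS1410"], params),
            _origin("ARS1424", ARS1424_POS, ri["ARS1424"], params),
            _origin("ARS1426", ARS1426_POS, ri["ARS1426"], params),
        ],
        key=lambda o: o.position,
    )
    if name == "wt":
        centromeres = (Centromere(NATIVE_CEN_POS, CDEIII_WILDTYPE),)
    elif name == "rearranged":
        centromeres = (Centromere(ECTOPIC_CEN_POS, CDEIII_WILDTYPE),)
    else:  # cen_dead: native centromere retained, dead CDEIII at MET2
        centromeres = (
            Centromere(ECTOPIC_CEN_POS, CDEIII_DEAD),
            Centromere(NATIVE_CEN_POS, CDEIII_WILDTYPE),
        )
    chr14 = ChromosomeModel(CHR14, CHR14_LEN, tuple(xiv_origins), centromeres)

    chrstd = ChromosomeModel(
        CHRSTD,
        CHRSTD_LEN,
        tuple(
            sorted(
                [
                    _origin("ARS306", ARS306_POS, ri["ARS306"], params),
                    _origin("ARS1", ARS1_POS, ri["ARS1"], params),
                    _origin("R11", R11_POS, ri["R11"], params),
                ]
                + [
                    _origin(oid, pos, fri, params)
                    for oid, (pos, fri) in _CHRSTD_FILLER_RI.items()
                ],
                key=lambda o: o.position,
            )
        ),
    )

    xv_origins = []
    for oid, (pos, fri) in _CHR15_RI.items():
        o = _origin(oid, pos, fri, params)
        if oid == "ARS1531" and ars1531_dead:
            o = replace(o, efficiency=0.0)
        xv_origins.append(o)
    chr15 = ChromosomeModel(CHR15, CHR15_LEN, tuple(sorted(xv_origins, key=lambda o: o.position)))

    true_trep = {locus: _ri_to_trep(r) for locus, r in ri.items()}
    return ScenarioBundle(
        name=name,
        chromosomes=(chr14, chrstd, chr15),
        loci=dict(_LOCI),
        true_trep=true_trep,
        effect=CentromereEffect(),
        params=params,
        noise=noise,
    )


def intrinsic_chrxiv(
    centromere: Centromere | None = None,
    params: SimulationParams | None = None,
) -> ChromosomeModel:
    """Chromosome XIV with centromere-naive origin timing.

    Origin firing times reflect each origin's intrinsic (no functional
    centromere nearby) behaviour; attach a centromere and apply a
    :class:`CentromereEffect` to study the advance it confers.
    """
    if params is None:
        params = SimulationParams()
    origins = sorted(
        [_origin(oid, pos, fri, params) for oid, (pos, fri) in _FILLER_RI.items()]
        + [
            _origin("ARS1410", ARS1410_POS, _INTRINSIC_RI["ARS1410"], params),
            _origin("ARS1424", ARS1424_POS, _INTRINSIC_RI["ARS1424"], params),
            _origin("ARS1426", ARS1426_POS, _INTRINSIC_RI["ARS1426"], params),
        ],
        key=lambda o: o.position,
    )
    cens = (centromere,) if centromere is not None else ()
    return ChromosomeModel(CHR14, CHR14_LEN, tuple(origins), cens)


# ---------------------------------------------------------------------------
# Observation simulators
# ---------------------------------------------------------------------------

def _locus_fractions(
    bundle: ScenarioBundle,
    times: np.ndarray,
    rng: np.random.Generator,
    genomic_grid_bp: int,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """True replicated fraction per named locus and for the genomic average.

    One cell population per chromosome is shared by all loci and grid
    positions on it.
    """
    locus_f: dict[str, np.ndarray] = {}
    genomic_hits = []
    for chrom in bundle.chromosomes:
        pop = sample_population(chrom, bundle.params, rng)
        here = {k: pos for k, (cname, pos) in bundle.loci.items() if cname == chrom.name}
        grid = np.arange(0, chrom.length + 1, genomic_grid_bp, dtype=float)
        positions = np.concatenate([np.array(list(here.values()), dtype=float), grid])
        t_rep = population_locus_times(pop, chrom, positions, bundle.params)
        replicated = t_rep[:, :, None] <= times[None, None, :]  # (cells, pos, times)
        frac = replicated.mean(axis=0)  # (pos, times)
        for i, k in enumerate(here):
            locus_f[k] = frac[i]
        genomic_hits.append(frac[len(here):])
    genomic_f = np.concatenate(genomic_hits, axis=0).mean(axis=0)
    return locus_f, genomic_f


def _gradient_signal(
    f: float,
    geometry: GradientGeometry,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spread HH mass (1-f) and HL mass (2f) into Gaussian gradient peaks."""
    fractions = np.arange(geometry.n_fractions, dtype=float)
    def peak(center: float) -> np.ndarray:
        w = np.exp(-0.5 * ((fractions - center) / geometry.peak_sd) ** 2)
        return w / w.sum()
    mass = (1.0 - f) * peak(geometry.hh_peak_fraction) + 2.0 * f * peak(
        geometry.hl_peak_fraction
    )
    return (mass + noise.background) * noise.multiplier(rng, fractions.size)


def simulate_slotblot_experiment(
    bundle: ScenarioBundle,
    times: Sequence[float],
    geometry: GradientGeometry | None = None,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
    genomic_grid_bp: int = 5_000,
) -> tuple[list[GradientScan], list[GradientScan]]:
    """Simulate slot-blot gradient scans for every named locus plus a genomic probe.

    At each timepoint the locus' replicated fraction f sets the HH mass to
    (1 - f) and the HL mass to 2f (each replicated molecule yields two
    hybrid daughters, doubling its mass contribution); the genomic probe is
    the grid-average over all chromosomes.  Returns
    ``(locus_scans, genomic_scans)``.
    """
    t = np.asarray(sorted(times), dtype=float)
    if t.size == 0:
        raise ValueError("times must be non-empty")
    if geometry is None:
        geometry = bundle.geometry
    if noise is None:
        noise = bundle.noise
    if rng is None:
        rng = np.random.default_rng(bundle.params.seed)
    locus_f, genomic_f = _locus_fractions(bundle, t, rng, genomic_grid_bp)
    fraction_idx = np.arange(geometry.n_fractions)
    scans: list[GradientScan] = []
    for locus in bundle.loci:
        for i, ti in enumerate(t):
            scans.append(
                GradientScan(
                    fragment_id=locus,
                    time=float(ti),
                    fraction_index=fraction_idx,
                    signal=_gradient_signal(float(locus_f[locus][i]), geometry, noise, rng),
                )
            )
    genomic_scans = [
        GradientScan(
            fragment_id=GENOMIC_ID,
            time=float(ti),
            fraction_index=fraction_idx,
            signal=_gradient_signal(float(genomic_f[i]), geometry, noise, rng),
        )
        for i, ti in enumerate(t)
    ]
    return scans, genomic_scans


def simulate_array_experiment(
    bundle: ScenarioBundle,
    times: Sequence[float],
    probe_spacing: int = 2_000,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
    channel_scales: tuple[float, float] = (1.25, 0.8),
) -> pd.DataFrame:
    """Simulate a two-channel array time course over all chromosomes.

    Probes sit on a regular grid; per probe, hh ~ (1 - f) and hl ~ 2f plus
    the additive background level, with independent lognormal noise per
    channel and global channel scale factors
    (``channel_scales = (hh_scale, hl_scale)``) that median channel
    equalization is expected to remove.  Returns a tidy probe table
    (chrom, position, time_min, hh_intensity, hl_intensity).
    """
    if probe_spacing <= 0:
        raise ValueError("probe_spacing must be > 0")
    t = np.asarray(sorted(times), dtype=float)
    if t.size == 0:
        raise ValueError("times must be non-empty")
    if noise is None:
        noise = bundle.noise
    if rng is None:
        rng = np.random.default_rng(bundle.params.seed)
    s_hh, s_hl = channel_scales
    frames = []
    for chrom in bundle.chromosomes:
        positions = np.arange(0, chrom.length + 1, probe_spacing)
        if positions.size == 0:
            raise ValueError("no probes on chromosome; decrease probe_spacing")
        pop = sample_population(chrom, bundle.params, rng)
        t_rep = population_locus_times(pop, chrom, positions.astype(float), bundle.params)
        for i, ti in enumerate(t):
            f = (t_rep <= ti).mean(axis=0)
            hh = (1.0 - f + noise.background) * s_hh * noise.multiplier(rng, f.size)
            hl = (2.0 * f + noise.background) * s_hl * noise.multiplier(rng, f.size)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom.name,
                        "position": positions,
                        "time_min": ti,
                        "hh_intensity": hh,
                        "hl_intensity": hl,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Sequence utilities
# ---------------------------------------------------------------------------

def hamming_distance(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length DNA strings."""
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if set(a) - set("ACGT") or set(b) - set("ACGT"):
        raise ValueError("sequences must be over the ACGT alphabet")
    return sum(x != y for x, y in zip(a, b))


def acs_is_functional(seq: str) -> bool:
    """Whether a 15-bp ARS consensus sequence retains origin activity.

    Only the wild-type ACS is functional; the known single T->C substitution
    (and any other change) abolishes origin activity.
    """
    seq = seq.upper()
    if len(seq) != 15:
        raise ValueError("ACS must be 15 bp")
    if set(seq) - set("ACGT"):
        raise ValueError("ACS must be over the ACGT alphabet")
    return seq == ACS_WILDTYPE


# ---------------------------------------------------------------------------
# Fixture emission
# ---------------------------------------------------------------------------

def bundle_to_dict(bundle: ScenarioBundle) -> dict:
    """Plain-dict form of a scenario (YAML/JSON serializable)."""
    return {
        "name": bundle.name,
        "early_trep": bundle.early_trep,
        "late_trep": bundle.late_trep,
        "params": {
            "fork_velocity": bundle.params.fork_velocity,
            "s_entry_mean": bundle.params.s_entry_mean,
            "s_entry_sd": bundle.params.s_entry_sd,
            "fraction_cycling": bundle.params.fraction_cycling,
            "n_cells": bundle.params.n_cells,
            "seed": bundle.params.seed,
        },
        "effect": {
            "max_advance": bundle.effect.max_advance,
            "range_bp": bundle.effect.range_bp,
            "mode": bundle.effect.mode,
        },
        "noise": {
            "signal_cv": bundle.noise.signal_cv,
            "background": bundle.noise.background,
        },
        "geometry": {
            "n_fractions": bundle.geometry.n_fractions,
            "hh_peak_fraction": bundle.geometry.hh_peak_fraction,
            "hl_peak_fraction": bundle.geometry.hl_peak_fraction,
            "peak_sd": bundle.geometry.peak_sd,
        },
        "loci": {k: [c, int(p)] for k, (c, p) in bundle.loci.items()},
        "true_trep": {k: float(v) for k, v in bundle.true_trep.items()},
        "chromosomes": [
            {
                "name": c.name,
                "length": c.length,
                "origins": [
                    {
                        "id": o.id,
                        "position": o.position,
                        "mean_firing_time": o.mean_firing_time,
                        "firing_sd": o.firing_sd,
                        "efficiency": o.efficiency,
                    }
                    for o in c.origins
                ],
                "centromeres": [
                    {"position": cen.position, "cdeiii_seq": cen.cdeiii_seq}
                    for cen in c.centromeres
                ],
            }
            for c in bundle.chromosomes
        ],
    }


def write_fixture_set(
    bundle: ScenarioBundle,
    out_dir: str | Path,
    times: Sequence[float] | None = None,
    array_times: Sequence[float] = (55.0, 65.0, 75.0),
    probe_spacing: int = 2_000,
) -> dict:
    """Emit a complete, deterministic fixture set for a scenario.

    Writes the combined gradient table, one gradient TSV per locus per
    timepoint, the probe table, the scenario config (YAML), a truth table
    (locus, chrom, position, true_trep, true_ri), and a JSON manifest.
    Deterministic for a fixed scenario seed.  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if times is None:
        times = [float(x) for x in range(0, 150, 10)]
    rng = np.random.default_rng(bundle.params.seed)
    scans, genomic = simulate_slotblot_experiment(bundle, times, rng=rng)
    probes = simulate_array_experiment(
        bundle, array_times, probe_spacing=probe_spacing, rng=rng
    )

    files: list[str] = []

    def _write(df: pd.DataFrame, rel: str) -> None:
        path = out / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        files.append(rel)

    _write(scans_to_frame(scans + genomic), "scans.tsv")
    for s in scans + genomic:
        rel = f"gradients/{s.fragment_id}_t{int(round(s.time)):03d}.tsv"
        _write(
            pd.DataFrame({"fraction": s.fraction_index, "signal": s.signal}), rel
        )
    _write(probes, "probes.tsv")

    truth = pd.DataFrame(
        {
            "locus": list(bundle.true_trep),
            "chrom": [bundle.loci[k][0] for k in bundle.true_trep],
            "position": [bundle.loci[k][1] for k in bundle.true_trep],
            "true_trep": [bundle.true_trep[k] for k in bundle.true_trep],
            "true_ri": [bundle.true_ri[k] for k in bundle.true_trep],
        }
    )
    _write(truth, "truth.tsv")

    with open(out / "scenario.yaml", "w") as fh:
        yaml.safe_dump(bundle_to_dict(bundle), fh, sort_keys=True)
    files.append("scenario.yaml")

    manifest = {
        "scenario": bundle.name,
        "seed": bundle.params.seed,
        "times": [float(x) for x in times],
        "array_times": [float(x) for x in array_times],
        "probe_spacing": probe_spacing,
        "files": sorted(files),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
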