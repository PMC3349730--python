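"""End-to-end recovery workflows shared by the tests, the CLI and the
acceptance script: simulate a scenario, run the inference chain, collect
replication indices or timing-difference regions."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import profile as prof
from .kinetics import run_kinetics_pipeline
from .scenarios import (
    GENOMIC_ID,
    NoiseModel,
    ScenarioBundle,
    build_scenario,
    simulate_array_experiment,
    simulate_slotblot_experiment,
)

__all__ = [
    "DEFAULT_SAMPLE_TIMES",
    "DEFAULT_ARRAY_TIMES",
    "replicate_seed",
    "slotblot_recovery",
    "mean_recovered_ri",
    "array_zsets",
    "compare_scenarios",
]

#: Slot-blot sampling: every 10 min from release through 140 min.
DEFAULT_SAMPLE_TIMES: tuple[float, ...] = tuple(float(t) for t in range(0, 150, 10))
#: Mid-S array samples used for Z-score comparisons.
DEFAULT_ARRAY_TIMES: tuple[float, ...] = (55.0, 65.0, 75.0)

STANDARD_IDS = ("ARS306", "R11")


def replicate_seed(base_seed: int, replicate: int) -> int:
    """Deterministic per-replicate seed below 2**31."""
    return int(
        np.random.SeedSequence([int(base_seed), int(replicate)]).generate_state(1)[0]
        % (2**31)
    )


def slotblot_recovery(
    scenario: str,
    n_replicates: int = 25,
    base_seed: int = 1,
    times: Sequence[float] = DEFAULT_SAMPLE_TIMES,
    signal_cv: float = 0.05,
    background: float = 0.02,
) -> pd.DataFrame:
    """Recover replication indices from replicate simulated slot-blot runs.

    Each replicate draws a fresh cell population and fresh signal noise,
    simulates gradients for every named locus plus the genomic probe, and
    runs the full pooling -> percent -> T_rep -> RI pipeline.  Returns a
    tidy frame (replicate, fragment_id, trep_min, replication_index).
    """
    rows = []
    for rep in range(n_replicates):
        seed = replicate_seed(base_seed, rep)
        bundle = build_scenario(
            scenario, seed=seed, noise=NoiseModel(signal_cv=signal_cv, background=background)
        )
        scans, genomic = simulate_slotblot_experiment(bundle, times)
        result = run_kinetics_pipeline(
            scans,
            genomic,
            standards_ids=STANDARD_IDS,
            hh_window=bundle.geometry.hh_window,
            hl_window=bundle.geometry.hl_window,
        )
        frame = result.to_frame()
        frame.insert(0, "replicate", rep)
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def mean_recovered_ri(recovery: pd.DataFrame) -> pd.Series:
    """Mean replication index per fragment over replicates."""
    return recovery.groupby("fragment_id")["replication_index"].mean()


def array_zsets(
    scenario: str | ScenarioBundle,
    seed: int = 0,
    times: Sequence[float] = DEFAULT_ARRAY_TIMES,
    probe_spacing: int = 2_000,
    signal_cv: float = 0.05,
    window_bp: int = 18_000,
    ars1531_dead: bool = False,
) -> tuple[dict[float, list[prof.ZProfile]], dict[float, list[prof.ReplicationProfile]]]:
    """Simulate an array time course and Z-normalize its smoothed profiles.

    Returns ``(zsets, percent_profiles)`` keyed by timepoint; percent
    profiles are the smoothed per-chromosome profiles used for sample
    matching.
    """
    if isinstance(scenario, ScenarioBundle):
        bundle = scenario
    else:
        bundle = build_scenario(
            scenario, seed=seed, noise=NoiseModel(signal_cv=signal_cv),
            ars1531_dead=ars1531_dead,
        )
    probes = simulate_array_experiment(bundle, times, probe_spacing=probe_spacing)
    profiles = prof.profiles_from_probes(probes)
    smoothed: dict[float, list[prof.ReplicationProfile]] = {}
    for p in profiles:
        smoothed.setdefault(p.time, []).append(prof.smooth_profile(p, window_bp))
    zsets = {t: prof.zscore_profile(plist) for t, plist in smoothed.items()}
    return zsets, smoothed


def compare_scenarios(
    scenario_a: str,
    scenario_b: str,
    seed_a: int,
    seed_b: int,
    times: Sequence[float] = DEFAULT_ARRAY_TIMES,
    probe_spacing: int = 2_000,
    signal_cv: float = 0.05,
    delta_z: float = 1.5,
    min_probes: int = 3,
    matching_tol: float = 10.0,
    ars1531_dead_b: bool = False,
) -> tuple[list[prof.TimingDifference], list[dict]]:
    """Full inter-strain comparison: simulate both, match samples, detect differences.

    Timepoints whose genome-mean percent replication differs by more than
    ``matching_tol`` between the two experiments are excluded (with a
    report entry) before persistence-based difference detection.  Returns
    ``(regions, matching_reports)``.
    """
    za, pa = array_zsets(
        scenario_a, seed=seed_a, times=times, probe_spacing=probe_spacing,
        signal_cv=signal_cv,
    )
    zb, pb = array_zsets(
        scenario_b, seed=seed_b, times=times, probe_spacing=probe_spacing,
        signal_cv=signal_cv, ars1531_dead=ars1531_dead_b,
    )
    reports = []
    matched_a, matched_b = {}, {}
    for t in sorted(set(za) & set(zb)):
        ok, report = prof.check_sample_matching(pa[t], pb[t], tol=matching_tol)
        reports.append(report)
        if ok:
            matched_a[t] = za[t]
            matched_b[t] = zb[t]
    regions = prof.detect_timing_differences(
        matched_a, matched_b, delta_z=delta_z, min_probes=min_probes
    )
    return regions, reports
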