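"""Genome-wide replication profiling from two-channel array intensities.

Per-probe percent replication is computed from HH (unreplicated) and HL
(replicated) channel intensities after median channel equalization, smoothed
with an 18 kb sliding window, and normalized to Z-scores, Z = (X - mu)/sigma,
with mu and sigma taken genome-wide per timed sample.  Profile peaks mark
active origins; inter-strain timing differences are called as runs of probes
whose Z-score difference exceeds a threshold at every compared timepoint
(timing changes must persist over the course of S-phase to count).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

__all__ = [
    "ProbeSample",
    "ReplicationProfile",
    "ZProfile",
    "PeakCall",
    "TimingDifference",
    "probe_percent_replication",
    "profiles_from_probes",
    "smooth_profile",
    "zscore_profile",
    "check_sample_matching",
    "call_peaks",
    "detect_timing_differences",
    "zprofiles_to_frame",
    "zprofiles_from_frame",
]


@dataclass(frozen=True)
class ProbeSample:
    """One array probe in one timed sample: position plus channel intensities."""

    chrom: str
    position: int
    time: float
    hh_intensity: float
    hl_intensity: float

    def __post_init__(self) -> None:
        if self.hh_intensity < 0 or self.hl_intensity < 0:
            raise ValueError("intensities must be >= 0")


@dataclass(frozen=True)
class ReplicationProfile:
    """Percent replication along one chromosome at one timepoint."""

    chrom: str
    positions: np.ndarray
    values: np.ndarray
    time: float
    smoothed: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=int)
        val = np.asarray(self.values, dtype=float)
        if pos.shape != val.shape or pos.ndim != 1 or pos.size == 0:
            raise ValueError("positions and values must be 1-D, non-empty, equal length")
        if (np.diff(pos) <= 0).any():
            raise ValueError("positions must be strictly increasing")
        if (val < 0).any() or (val > 100).any():
            raise ValueError("percent values must lie in [0, 100]")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)


@dataclass(frozen=True)
class ZProfile:
    """Z-normalized profile sharing coordinates with its ReplicationProfile."""

    chrom: str
    positions: np.ndarray
    zvalues: np.ndarray
    mu: float
    sigma: float
    time: float


@dataclass(frozen=True)
class PeakCall:
    """A profile peak: a candidate origin location."""

    chrom: str
    position: int
    height: float
    prominence: float


@dataclass(frozen=True)
class TimingDifference:
    """A run of probes whose Z-scores differ at every compared timepoint."""

    chrom: str
    start: int
    end: int  # 0-based half-open
    max_abs_delta_z: float
    times_supporting: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must be > start")


def probe_percent_replication(
    probes: pd.DataFrame, channel_norm: str = "median"
) -> pd.DataFrame:
    """Per-probe percent replication from channel intensities of ONE timed sample.

    ``channel_norm='median'`` rescales the HL channel so both channels share
    the same genome-wide median before applying the molecule-counting
    formula 100*hl/(hl + 2*hh); ``'none'`` uses raw intensities.  Probes with
    both intensities zero are dropped; the returned frame carries a
    ``dropped_probes`` attribute with their count.
    """
    if channel_norm not in ("median", "none"):
        raise ValueError("channel_norm must be 'median' or 'none'")
    hh = probes["hh_intensity"].to_numpy(dtype=float)
    hl = probes["hl_intensity"].to_numpy(dtype=float)
    if (hh < 0).any() or (hl < 0).any():
        raise ValueError("intensities must be >= 0")
    if channel_norm == "median":
        med_hh = np.median(hh)
        med_hl = np.median(hl)
        if med_hh <= 0 or med_hl <= 0:
            raise ValueError("median channel equalization needs positive medians")
        hl = hl * (med_hh / med_hl)
    keep = (hh + hl) > 0
    out = probes.loc[keep, ["chrom", "position", "time_min"]].copy()
    out["percent"] = 100.0 * hl[keep] / (hl[keep] + 2.0 * hh[keep])
    out.attrs["dropped_probes"] = int((~keep).sum())
    return out


def profiles_from_probes(
    probes: pd.DataFrame, channel_norm: str = "median"
) -> list[ReplicationProfile]:
    """Split a probe table into per-chromosome, per-timepoint percent profiles.

    Channel normalization is applied per timed sample (each sample is an
    independent hybridization).
    """
    profiles: list[ReplicationProfile] = []
    for t, sample in probes.groupby("time_min", sort=True):
        pct = probe_percent_replication(sample, channel_norm=channel_norm)
        for chrom, g in pct.groupby("chrom", sort=True):
            g = g.sort_values("position")
            profiles.append(
                ReplicationProfile(
                    chrom=str(chrom),
                    positions=g["position"].to_numpy(dtype=int),
                    values=g["percent"].to_numpy(dtype=float),
                    time=float(t),
                )
            )
    return profiles


def smooth_profile(
    profile: ReplicationProfile, window_bp: int = 18_000
) -> ReplicationProfile:
    """Sliding-window mean smoothing with an 18 kb full-width window.

    Each probe's value becomes the unweighted mean of all probes within
    +/- window_bp/2, with the window truncated at chromosome ends.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    pos = profile.positions.astype(float)
    half = window_bp / 2.0
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    csum = np.concatenate(([0.0], np.cumsum(profile.values)))
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    return replace(profile, values=smoothed, smoothed=True)


def zscore_profile(
    profiles: Sequence[ReplicationProfile],
) -> list[ZProfile]:
    """Z-normalize one timed sample's profiles with genome-wide mu and sigma.

    All profiles must share the timepoint; mu and sigma (population standard
    deviation) are computed over every probe of every chromosome supplied.
    A degenerate sample (fewer than two probes, or sigma = 0) is an error.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    times = {p.time for p in profiles}
    if len(times) != 1:
        raise ValueError("zscore_profile expects profiles from a single timepoint")
    pooled = np.concatenate([p.values for p in profiles])
    if pooled.size < 2:
        raise ValueError("need at least 2 probes to Z-normalize")
    mu = float(pooled.mean())
    sigma = float(pooled.std(ddof=0))
    if sigma == 0:
        raise ValueError("degenerate profile: zero genome-wide standard deviation")
    return [
        ZProfile(
            chrom=p.chrom,
            positions=p.positions,
            zvalues=(p.values - mu) / sigma,
            mu=mu,
            sigma=sigma,
            time=p.time,
        )
        for p in profiles
    ]


def _genome_mean(profiles: Sequence[ReplicationProfile]) -> float:
    return float(np.concatenate([p.values for p in profiles]).mean())


def check_sample_matching(
    profiles_a: Sequence[ReplicationProfile] | ReplicationProfile,
    profiles_b: Sequence[ReplicationProfile] | ReplicationProfile,
    tol: float = 10.0,
) -> tuple[bool, dict]:
    """Decide whether two same-timepoint samples are comparable.

    Samples match when their genome-mean percent replication values differ
    by at most ``tol`` percentage points; mismatched pairs should be excluded
    from Z-score comparison (the motivating case being S-phase samples whose
    genomic percent replication was not well matched between strains).
    """
    a = [profiles_a] if isinstance(profiles_a, ReplicationProfile) else list(profiles_a)
    b = [profiles_b] if isinstance(profiles_b, ReplicationProfile) else list(profiles_b)
    times_a = {p.time for p in a}
    times_b = {p.time for p in b}
    if times_a != times_b or len(times_a) != 1:
        raise ValueError("samples must share a single timepoint label")
    mean_a = _genome_mean(a)
    mean_b = _genome_mean(b)
    matched = abs(mean_a - mean_b) <= tol
    report = {
        "time": next(iter(times_a)),
        "mean_a": mean_a,
        "mean_b": mean_b,
        "difference": abs(mean_a - mean_b),
        "tol": tol,
        "matched": matched,
    }
    return matched, report


def call_peaks(
    profile: ReplicationProfile, min_prominence: float = 2.0
) -> list[PeakCall]:
    """Call origin peaks on a smoothed profile.

    Peaks are strict local maxima whose prominence (height above the higher
    of the two flanking minima) reaches ``min_prominence``; chromosome-end
    probes are never peaks.  An empty list is a valid result.
    """
    if not profile.smoothed:
        raise ValueError("call_peaks expects a smoothed profile")
    if profile.values.size < 3:
        return []
    idx, props = _signal.find_peaks(profile.values, prominence=min_prominence)
    return [
        PeakCall(
            chrom=profile.chrom,
            position=int(profile.positions[i]),
            height=float(profile.values[i]),
            prominence=float(props["prominences"][j]),
        )
        for j, i in enumerate(idx)
    ]


ZSet = Mapping[float, Sequence[ZProfile]]


def detect_timing_differences(
    z_a: ZSet,
    z_b: ZSet,
    delta_z: float = 1.5,
    min_probes: int = 3,
) -> list[TimingDifference]:
    """Call persistent inter-strain timing differences from Z-profile sets.

    ``z_a`` and ``z_b`` map timepoint -> Z-profiles (one per chromosome).
    A difference region is a maximal run of at least ``min_probes``
    consecutive probes with |Z_a - Z_b| >= delta_z at EVERY shared
    timepoint.  At least two matched timepoints are required, enforcing the
    persistence rule.  Reported intervals are 0-based half-open in bp.
    """
    times = sorted(set(z_a) & set(z_b))
    if len(times) == 0:
        raise ValueError("no matched timepoints to compare")
    if len(times) < 2:
        raise ValueError("persistence requires at least two matched timepoints")
    chroms = sorted(
        {p.chrom for t in times for p in z_a[t]}
        & {p.chrom for t in times for p in z_b[t]}
    )
    regions: list[TimingDifference] = []
    for chrom in chroms:
        per_time_a = {t: _chrom_profile(z_a[t], chrom) for t in times}
        per_time_b = {t: _chrom_profile(z_b[t], chrom) for t in times}
        common = per_time_a[times[0]].positions
        for t in times:
            common = np.intersect1d(common, per_time_a[t].positions)
            common = np.intersect1d(common, per_time_b[t].positions)
        if common.size == 0:
            continue
        dz = np.empty((len(times), common.size))
        for i, t in enumerate(times):
            pa, pb = per_time_a[t], per_time_b[t]
            za = pa.zvalues[np.searchsorted(pa.positions, common)]
            zb = pb.zvalues[np.searchsorted(pb.positions, common)]
            dz[i] = np.abs(za - zb)
        persistent = (dz >= delta_z).all(axis=0)
        for i0, i1 in _runs(persistent):
            if i1 - i0 < min_probes:
                continue
            regions.append(
                TimingDifference(
                    chrom=chrom,
                    start=int(common[i0]),
                    end=int(common[i1 - 1]) + 1,
                    max_abs_delta_z=float(dz[:, i0:i1].max()),
                    times_supporting=tuple(times),
                )
            )
    return regions


def _chrom_profile(profiles: Sequence[ZProfile], chrom: str) -> ZProfile:
    for p in profiles:
        if p.chrom == chrom:
            return p
    raise ValueError(f"chromosome {chrom!r} missing from a Z-profile set")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index intervals."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def zprofiles_to_frame(zsets: ZSet) -> pd.DataFrame:
    """Flatten timepoint -> ZProfile mappings to a (chrom, position, time_min, z) table."""
    frames = []
    for t in sorted(zsets):
        for p in zsets[t]:
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": p.chrom,
                        "position": p.positions,
                        "time_min": t,
                        "z": p.zvalues,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def zprofiles_from_frame(df: pd.DataFrame) -> dict[float, list[ZProfile]]:
    """Rebuild Z-profile sets from a (chrom, position, time_min, z) table.

    mu/sigma are not stored in the table; they are set to 0/1 markers since
    downstream difference detection uses only the z values themselves.
    """
    zsets: dict[float, list[ZProfile]] = {}
    for t, sample in df.groupby("time_min", sort=True):
        plist = []
        for chrom, g in sample.groupby("chrom", sort=True):
            g = g.sort_values("position")
            plist.append(
                ZProfile(
                    chrom=str(chrom),
                    positions=g["position"].to_numpy(dtype=int),
                    zvalues=g["z"].to_numpy(dtype=float),
                    mu=0.0,
                    sigma=1.0,
                    time=float(t),
                )
            )
        zsets[float(t)] = plist
    return zsets
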