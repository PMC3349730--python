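"""Locus-level replication-timing inference from density-transfer slot blots.

The chain mirrors the classic Meselson-Stahl density-transfer analysis:
gradient fractions are pooled into heavy-heavy (HH, unreplicated) and
heavy-light (HL, replicated) masses; percent replication is computed at the
molecule level as 100*HL/(HL + 2*HH) (each replicated duplex yields two HL
daughters, so HL mass is halved to count molecules); percent-vs-time curves
give the time of half-maximal replication T_rep, measured against the
plateau of a genomic probe because not every G1 cell enters or completes
S-phase; and T_rep values are rescaled to replication indices (RI) anchored
at an early standard (ARS306 role, RI = 0) and a late standard (R11 role,
RI = 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GradientScan",
    "PooledDensities",
    "KineticCurve",
    "TimingStandards",
    "TimingResult",
    "PipelineResult",
    "pool_fractions",
    "percent_replication",
    "estimate_plateau",
    "estimate_trep",
    "replication_index",
    "run_kinetics_pipeline",
    "scans_from_frame",
    "scans_to_frame",
]


@dataclass(frozen=True)
class GradientScan:
    """Slot-blot signal across the fractions of one CsCl gradient.

    One scan corresponds to one probed restriction fragment in one timed
    sample.  Fraction indices run dense-to-light (HH DNA sits lower in the
    gradient, i.e. at higher fraction index here).
    """

    fragment_id: str
    time: float
    fraction_index: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        fi = np.asarray(self.fraction_index, dtype=int)
        sig = np.asarray(self.signal, dtype=float)
        if fi.shape != sig.shape or fi.ndim != 1:
            raise ValueError("fraction_index and signal must be 1-D and equal length")
        if (np.diff(fi) <= 0).any():
            raise ValueError("fraction indices must be strictly ordered")
        if (sig < 0).any():
            raise ValueError("signals must be >= 0")
        object.__setattr__(self, "fraction_index", fi)
        object.__setattr__(self, "signal", sig)


@dataclass(frozen=True)
class PooledDensities:
    """Pooled heavy-heavy and heavy-light signal for one scan."""

    hh: float
    hl: float

    def __post_init__(self) -> None:
        if self.hh < 0 or self.hl < 0:
            raise ValueError("pooled densities must be >= 0")


@dataclass(frozen=True)
class KineticCurve:
    """Time-ordered percent-replication values for one fragment."""

    fragment_id: str
    times: np.ndarray
    percent: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.percent, dtype=float)
        if t.shape != p.shape or t.ndim != 1:
            raise ValueError("times and percent must be 1-D and equal length")
        if (np.diff(t) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if (p < 0).any() or (p > 100).any():
            raise ValueError("percent values must lie in [0, 100]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "percent", p)


@dataclass(frozen=True)
class TimingStandards:
    """Measured T_rep of the early and late timing-standard fragments."""

    early_id: str
    late_id: str
    early_trep: float
    late_trep: float

    def __post_init__(self) -> None:
        if not self.late_trep > self.early_trep:
            raise ValueError("late standard must replicate after the early standard")


@dataclass(frozen=True)
class TimingResult:
    """T_rep and replication index for one fragment."""

    fragment_id: str
    trep: float
    replication_index: float


def pool_fractions(
    scan: GradientScan,
    hh_window: tuple[int, int],
    hl_window: tuple[int, int],
) -> PooledDensities:
    """Pool gradient fractions into HH and HL masses.

    Windows are half-open ``[lo, hi)`` intervals of fraction index and must
    be disjoint, non-empty, and within the scan's fraction range.  The
    median signal of fractions outside both windows is treated as
    background, subtracted from every fraction and floored at zero before
    summing.
    """
    for name, (lo, hi) in (("hh", hh_window), ("hl", hl_window)):
        if hi <= lo:
            raise ValueError(f"{name}_window is empty")
    lo = min(hh_window[0], hl_window[0])
    hi = max(hh_window[1], hl_window[1])
    fi = scan.fraction_index
    if lo < fi.min() or hi > fi.max() + 1:
        raise ValueError("pooling windows must lie within the scanned fractions")
    if max(hh_window[0], hl_window[0]) < min(hh_window[1], hl_window[1]):
        raise ValueError("hh and hl windows must be disjoint")
    in_hh = (fi >= hh_window[0]) & (fi < hh_window[1])
    in_hl = (fi >= hl_window[0]) & (fi < hl_window[1])
    if not in_hh.any() or not in_hl.any():
        raise ValueError("a pooling window contains no fractions")
    outside = ~(in_hh | in_hl)
    background = float(np.median(scan.signal[outside])) if outside.any() else 0.0
    corrected = np.clip(scan.signal - background, 0.0, None)
    return PooledDensities(hh=float(corrected[in_hh].sum()), hl=float(corrected[in_hl].sum()))


def percent_replication(p: PooledDensities) -> float:
    """Percent of molecules replicated: 100 * HL / (HL + 2 * HH).

    Each replicated molecule contributes two hybrid-density daughters, so
    the HL mass is halved to count molecules.
    """
    if p.hh + p.hl <= 0:
        raise ValueError("percent replication undefined: no pooled signal")
    return 100.0 * p.hl / (p.hl + 2.0 * p.hh)


def estimate_plateau(genomic_curve: KineticCurve, k: int = 3) -> float:
    """Plateau of a kinetic curve: mean of its final ``k`` percent values."""
    if k <= 0:
        raise ValueError("k must be a positive integer")
    if genomic_curve.times.size < k:
        raise ValueError("curve has fewer points than k")
    return float(genomic_curve.percent[-k:].mean())


def estimate_trep(curve: KineticCurve, plateau: float) -> float:
    """Time of half-maximal replication against the given plateau.

    Returns the time of the first upward crossing of ``plateau / 2``,
    linearly interpolated between the bracketing samples.  If the first
    sample already exceeds the half level, its time is returned.  A curve
    that never reaches the half level is an error.
    """
    if plateau <= 0:
        raise ValueError("plateau must be > 0")
    half = plateau / 2.0
    p = curve.percent
    t = curve.times
    if p[0] >= half:
        return float(t[0])
    above = np.nonzero(p >= half)[0]
    if above.size == 0:
        raise ValueError(
            f"{curve.fragment_id}: locus did not reach half-maximal replication"
        )
    i = int(above[0])
    # first upward crossing: interpolate between samples i-1 and i
    frac = (half - p[i - 1]) / (p[i] - p[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def replication_index(trep_x: float, standards: TimingStandards) -> float:
    """Rescale a T_rep so the early standard maps to 0 and the late to 1.

    RI = (T_rep(X) - T_rep(early)) / (T_rep(late) - T_rep(early)).  Values
    outside [0, 1] are allowed for loci earlier than the early standard or
    later than the late one.
    """
    denom = standards.late_trep - standards.early_trep
    if denom == 0:
        raise ValueError("timing standards have equal T_rep")
    return (trep_x - standards.early_trep) / denom


@dataclass(frozen=True)
class PipelineResult:
    """Output of the full kinetics pipeline for one experiment."""

    results: tuple[TimingResult, ...]
    curves: Mapping[str, KineticCurve]
    genomic_curve: KineticCurve
    plateau: float
    standards: TimingStandards

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fragment_id": [r.fragment_id for r in self.results],
                "trep_min": [r.trep for r in self.results],
                "replication_index": [r.replication_index for r in self.results],
            }
        )

    def ri(self, fragment_id: str) -> float:
        for r in self.results:
            if r.fragment_id == fragment_id:
                return r.replication_index
        raise KeyError(fragment_id)


def _curve_from_scans(
    fragment_id: str,
    scans: Sequence[GradientScan],
    hh_window: tuple[int, int],
    hl_window: tuple[int, int],
) -> KineticCurve:
    ordered = sorted(scans, key=lambda s: s.time)
    times = np.array([s.time for s in ordered])
    percent = np.array(
        [percent_replication(pool_fractions(s, hh_window, hl_window)) for s in ordered]
    )
    return KineticCurve(fragment_id=fragment_id, times=times, percent=percent)


def run_kinetics_pipeline(
    scans: Iterable[GradientScan],
    genomic_scans: Iterable[GradientScan],
    standards_ids: tuple[str, str],
    hh_window: tuple[int, int],
    hl_window: tuple[int, int],
    plateau_k: int = 3,
) -> PipelineResult:
    """Pooling -> percent -> curves -> T_rep -> RI for a set of fragments.

    Every fragment must have a scan at every timepoint, and both timing
    standards must be present among the fragments.  T_rep for every fragment
    is measured against the plateau of the genomic-probe curve.  The
    standards appear in the output with RIs of exactly 0 and 1.
    """
    early_id, late_id = standards_ids
    by_fragment: dict[str, list[GradientScan]] = {}
    for s in scans:
        by_fragment.setdefault(s.fragment_id, []).append(s)
    if not by_fragment:
        raise ValueError("no scans provided")
    for sid in standards_ids:
        if sid not in by_fragment:
            raise ValueError(f"standard fragment {sid!r} has no scans")
    timepoints = {fid: tuple(sorted(s.time for s in ss)) for fid, ss in by_fragment.items()}
    reference = next(iter(timepoints.values()))
    for fid, tp in timepoints.items():
        if tp != reference:
            raise ValueError(f"fragment {fid!r} is missing timepoints: {tp} != {reference}")

    genomic = list(genomic_scans)
    if not genomic:
        raise ValueError("genomic probe scans are required for the plateau")
    genomic_curve = _curve_from_scans(genomic[0].fragment_id, genomic, hh_window, hl_window)
    plateau = estimate_plateau(genomic_curve, k=plateau_k)

    curves = {
        fid: _curve_from_scans(fid, ss, hh_window, hl_window)
        for fid, ss in by_fragment.items()
    }
    treps = {fid: estimate_trep(curve, plateau) for fid, curve in curves.items()}
    standards = TimingStandards(
        early_id=early_id,
        late_id=late_id,
        early_trep=treps[early_id],
        late_trep=treps[late_id],
    )
    results = tuple(
        TimingResult(
            fragment_id=fid,
            trep=trep,
            replication_index=replication_index(trep, standards),
        )
        for fid, trep in sorted(treps.items())
    )
    return PipelineResult(
        results=results,
        curves=curves,
        genomic_curve=genomic_curve,
        plateau=plateau,
        standards=standards,
    )


def scans_from_frame(df: pd.DataFrame) -> list[GradientScan]:
    """Build GradientScans from a tidy table (fragment_id, time_min, fraction, signal)."""
    scans = []
    for (fid, t), group in df.groupby(["fragment_id", "time_min"], sort=True):
        g = group.sort_values("fraction")
        scans.append(
            GradientScan(
                fragment_id=str(fid),
                time=float(t),
                fraction_index=g["fraction"].to_numpy(dtype=int),
                signal=g["signal"].to_numpy(dtype=float),
            )
        )
    return scans


def scans_to_frame(scans: Iterable[GradientScan]) -> pd.DataFrame:
    frames = [
        pd.DataFrame(
            {
                "fragment_id": s.fragment_id,
                "time_min": s.time,
                "fraction": s.fraction_index,
                "signal": s.signal,
            }
        )
        for s in scans
    ]
    return pd.concat(frames, ignore_index=True)
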