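"""Sonar vocal behavior: pulse intervals, sound groups, stereotypy.

Echolocating bats shorten their pulse interval (PI) as they close in on
objects, and embed *sonar sound groups* (SSGs): clusters of two or more
calls at near-constant PI, flanked on both sides by distinctly longer
intervals.  SSGs mark epochs of close-range sonar inspection and serve
downstream as the behavioral attention label.

The detector implements the standard rule: internal PIs within 5% of the
group's mean PI, flanking PIs at least 1.2x the group mean (for two-call
groups, at least 1.2x the single internal PI).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve


@dataclass
class SonarSequence:
    """An ordered series of call onset times (seconds, at the source)."""

    t_emit: np.ndarray
    durations: Optional[np.ndarray] = None

    def __post_init__(self):
        self.t_emit = np.asarray(self.t_emit, float)
        if np.any(np.diff(self.t_emit) <= 0):
            raise ValueError("call times must be strictly increasing")
        if self.durations is not None:
            self.durations = np.asarray(self.durations, float)

    @property
    def pulse_intervals(self) -> np.ndarray:
        """PI_i = t_emit[i+1] - t_emit[i]; length n_calls - 1."""
        return np.diff(self.t_emit)

    @property
    def pulse_rates(self) -> np.ndarray:
        """Instantaneous pulse rate, Hz (1/PI)."""
        return 1.0 / self.pulse_intervals

    def __len__(self):
        return len(self.t_emit)


@dataclass(frozen=True)
class SonarSoundGroup:
    """A detected SSG: member call indices (contiguous) and mean internal PI."""

    calls: tuple
    mean_pi: float


def detect_ssgs(seq: SonarSequence, *, pi_tolerance: float = 0.05,
                flank_ratio: float = 1.2,
                flank_reference: str = "mean") -> List[SonarSoundGroup]:
    """Detect sonar sound groups in a call sequence.

    Greedy left-to-right scan for maximal runs of internal PIs that are each
    within ``pi_tolerance`` of the run mean and whose flanking PIs are at
    least ``flank_ratio`` times the reference PI.  ``flank_reference`` is
    ``"mean"`` (group mean PI, the default) or ``"adjacent"`` (the internal
    PI next to each flank).  Groups never overlap; edge calls lacking a flank
    cannot belong to a group.
    """
    pis = seq.pulse_intervals
    n = len(pis)
    groups: List[SonarSoundGroup] = []
    # internal PIs occupy index range [i, j); flanks are pis[i-1] and pis[j]
    i = 1
    while i < n - 1:
        best = None
        j = i + 1
        while j < n:  # grow the internal run [i, j)
            run = pis[i:j]
            mean = run.mean()
            if np.any(np.abs(run - mean) > pi_tolerance * mean):
                break
            left_ref = mean if flank_reference == "mean" else run[0]
            right_ref = mean if flank_reference == "mean" else run[-1]
            if pis[i - 1] >= flank_ratio * left_ref and pis[j] >= flank_ratio * right_ref:
                best = (j, mean)
            j += 1
        if best is not None:
            j_end, mean = best
            groups.append(SonarSoundGroup(calls=tuple(range(i, j_end + 1)),
                                          mean_pi=float(mean)))
            i = j_end + 1
        else:
            i += 1
    return groups


def ssg_membership(seq: SonarSequence, groups: Sequence[SonarSoundGroup]) -> np.ndarray:
    """Boolean per-call SSG membership vector."""
    member = np.zeros(len(seq), dtype=bool)
    for g in groups:
        member[list(g.calls)] = True
    return member


def behavior_vs_distance(seq: SonarSequence, distances,
                         bin_width: float = 0.25,
                         d_max: float = 4.0) -> pd.DataFrame:
    """Mean +/- sd of PI and duration as a function of object distance.

    ``distances`` gives the nearest-ensonified-object distance per call (m).
    The PI attributed to call i is the interval to the next call.  Bins with
    no calls are reported with NaN statistics (missing, not zero); single-
    call bins have NaN sd.
    """
    d = np.asarray(distances, float)[:-1]          # calls that have a next PI
    pis = seq.pulse_intervals
    has_dur = seq.durations is not None
    durs = seq.durations[:-1] if has_dur else None
    edges = np.arange(0.0, d_max + bin_width, bin_width)
    idx = np.digitize(d, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        rows.append(dict(
            d_lo=edges[b], d_hi=edges[b + 1], n=n,
            pi_mean=pis[sel].mean() if n else np.nan,
            pi_sd=pis[sel].std(ddof=1) if n > 1 else np.nan,
            dur_mean=durs[sel].mean() if has_dur and n else np.nan,
            dur_sd=durs[sel].std(ddof=1) if has_dur and n > 1 else np.nan,
        ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Flight-path stereotypy


def _occupancy_2d(xy: np.ndarray, edges_a, edges_b) -> np.ndarray:
    h, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=[edges_a, edges_b])
    total = h.sum()
    return h / total if total > 0 else h


def stereotypy_matrix(trials: Sequence[np.ndarray], *, bin_size: float = 0.10,
                      room=(6.0, 6.0, 2.5), projection: str = "xy") -> np.ndarray:
    """Trial-by-trial flight-path similarity from 2D occupancy maps.

    Each trial is an (n, 3) position array (m).  Positions are histogrammed
    into ``bin_size`` x ``bin_size`` squares on the requested plan projection
    ("xy" or "xz"), normalised to unit mass, and compared by the peak of the
    2D cross-correlation divided by the geometric mean of the two
    autocorrelation peaks.  By Cauchy-Schwarz every entry is in [0, 1] and
    the diagonal is exactly 1.
    """
    cols = {"xy": (0, 1), "xz": (0, 2)}[projection]
    sizes = {"xy": (room[0], room[1]), "xz": (room[0], room[2])}[projection]
    edges_a = np.arange(0.0, sizes[0] + bin_size, bin_size)
    edges_b = np.arange(0.0, sizes[1] + bin_size, bin_size)
    maps = []
    for traj in trials:
        xy = np.asarray(traj, float)[:, cols]
        xy = np.clip(xy, [0, 0], [sizes[0] - 1e-9, sizes[1] - 1e-9])
        maps.append(_occupancy_2d(xy, edges_a, edges_b))
    n = len(maps)
    auto = np.array([float((m * m).sum()) for m in maps])  # zero-lag peak
    out = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            cc = fftconvolve(maps[a], maps[b][::-1, ::-1], mode="full")
            out[a, b] = out[b, a] = float(cc.max()) / np.sqrt(auto[a] * auto[b])
    return out
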