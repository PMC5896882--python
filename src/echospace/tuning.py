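"""Occupancy-normalised spatial tuning of echo-driven sensory units.

Each first-arriving echo is one discrete stimulus with an egocentric
(azimuth, elevation, range) location; a unit's response to it is binary
(>= 1 spike in the response window).  Along each dimension the spike-count
histogram is divided by the stimulus-coverage histogram, yielding a spiking
probability per bin; poorly covered bins are excluded and the profile is
summarised by a least-squares Gaussian fit (mean, sd, FWHM).

SSG-conditioned analyses split the stimuli by the emitting call's sound-
group membership and test for sharpening (Brown-Forsythe on dispersion) and
proximal shift (Wilcoxon rank-sum on location) of the range tuning, with a
permutation screen guarding against under-powered comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .classify import RESPONSE_WINDOW
from .errors import FitError

#: Default bin edges per dimension: 10 cm in range, 10 deg in angle.
DEFAULT_BINS = {
    "range": np.arange(0.0, 4.0 + 0.1, 0.1),
    "azimuth": np.arange(-90.0, 90.0 + 10.0, 10.0),
    "elevation": np.arange(-90.0, 90.0 + 10.0, 10.0),
}

GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


def associate_spikes(spike_times, echoes: pd.DataFrame, *,
                     window=RESPONSE_WINDOW,
                     ssg_member=None) -> pd.DataFrame:
    """Bind a unit's spikes to first-echo stimuli.

    One row per order-1 echo event, carrying the egocentric stimulus
    coordinates, a binary ``response`` flag (>= 1 spike inside
    [arrival + lo, arrival + hi]), and the emitting call's SSG membership.
    When consecutive response windows overlap (rapid SSG calls), a spike
    counts only toward the nearest preceding echo; affected rows are flagged
    ``overlap``.
    """
    first = echoes[echoes["order"] == 1].sort_values("t_arrival").reset_index(drop=True)
    st = np.sort(np.asarray(spike_times, float))
    arr = first["t_arrival"].to_numpy()
    lo = np.searchsorted(st, arr + window[0], side="left")
    hi = np.searchsorted(st, arr + window[1], side="right")
    response = hi > lo
    # windows overlapping the next echo's window start
    overlap = np.zeros(len(arr), dtype=bool)
    if len(arr) > 1:
        overlap[:-1] = arr[:-1] + window[1] > arr[1:] + window[0]
        # spikes in the overlapped tail belong to the *next* (nearer) echo
        cut = np.searchsorted(st, arr[1:] + window[0], side="left")
        response[:-1] = np.where(overlap[:-1], cut > lo[:-1], response[:-1])
        overlap[1:] |= overlap[:-1]
    out = first[["voc_id", "t_emit", "t_arrival", "azimuth", "elevation",
                 "range"]].copy()
    out["response"] = response.astype(int)
    out["overlap"] = overlap
    if ssg_member is not None:
        lookup = dict(ssg_member)
        out["ssg"] = out["voc_id"].map(lookup).fillna(False).astype(bool)
    else:
        out["ssg"] = False
    return out


def selectivity_anova(samples: pd.DataFrame, dimension: str,
                      bins=None, *, min_per_bin: int = 2) -> float:
    """One-way ANOVA p-value of response vs stimulus bin along a dimension.

    Groups the binary response flags by stimulus bin and tests equality of
    group means.  Returns NaN (undefined) with fewer than two usable bins or
    when responses are constant; callers treat NaN as "not selective".
    """
    edges = np.asarray(bins if bins is not None else DEFAULT_BINS[dimension], float)
    x = samples[dimension].to_numpy()
    y = samples["response"].to_numpy()
    idx = np.digitize(x, edges) - 1
    groups = [y[idx == b] for b in range(len(edges) - 1)]
    groups = [g for g in groups if len(g) >= min_per_bin]
    if len(groups) < 2 or y.sum() == 0 or len(np.unique(y)) < 2:
        return float("nan")
    stat, p = stats.f_oneway(*groups)
    return float(p)


def is_selective_3d(samples: pd.DataFrame, *, alpha: float = 0.05,
                    bins: Optional[Dict] = None) -> bool:
    """True when the ANOVA rejects (p < alpha) on all three dimensions."""
    bins = bins or {}
    ps = [selectivity_anova(samples, dim, bins.get(dim))
          for dim in ("range", "azimuth", "elevation")]
    return all(np.isfinite(p) and p < alpha for p in ps)


@dataclass
class TuningProfile:
    """Occupancy-normalised spiking probability along one dimension."""

    dimension: str
    edges: np.ndarray
    event_counts: np.ndarray
    spike_counts: np.ndarray
    probability: np.ndarray          # NaN outside included bins
    included: np.ndarray             # bool mask over bins
    mu: float = float("nan")
    sigma: float = float("nan")
    amplitude: float = float("nan")
    baseline: float = float("nan")
    mu_se: float = float("nan")
    r2: float = float("nan")
    anova_p: float = float("nan")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def fwhm(self) -> float:
        """Full width at half maximum of the fitted Gaussian."""
        return GAUSS_FWHM * self.sigma

    @property
    def half_width(self) -> float:
        """Half width at half maximum (the field's 'half width')."""
        return 0.5 * self.fwhm


def _gauss(x, a, mu, sigma, b):
    return b + a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def tuning_profile(samples: pd.DataFrame, dimension: str, bins=None, *,
                   min_included: int = 4, fit: bool = True) -> TuningProfile:
    """Build the occupancy-normalised profile and fit a Gaussian.

    Per bin: probability = spike count / event count.  Bins whose event
    count falls more than one standard deviation below the mean per-bin
    event count (over occupied bins) are excluded, as are empty bins.  The
    Gaussian (amplitude, mu, sigma, baseline) is fit to included bins by
    least squares.

    Raises :class:`FitError` when fewer than ``min_included`` bins survive.
    """
    edges = np.asarray(bins if bins is not None else DEFAULT_BINS[dimension], float)
    x = samples[dimension].to_numpy()
    y = samples["response"].to_numpy()
    events, _ = np.histogram(x, bins=edges)
    spikes_, _ = np.histogram(x[y == 1], bins=edges)
    occupied = events > 0
    if occupied.sum() >= 2:
        floor = events[occupied].mean() - events[occupied].std(ddof=0)
    else:
        floor = 0.0
    included = occupied & (events >= floor)
    prob = np.full(len(events), np.nan)
    prob[included] = spikes_[included] / events[included]
    tp = TuningProfile(dimension=dimension, edges=edges, event_counts=events,
                       spike_counts=spikes_, probability=prob, included=included)
    if not fit:
        return tp
    if included.sum() < min_included:
        raise FitError(f"{dimension}: only {included.sum()} included bins")
    _fit_gaussian(tp)
    return tp


def _fit_gaussian(tp: TuningProfile) -> None:
    xs = tp.centers[tp.included]
    ys = tp.probability[tp.included]
    span = xs.max() - xs.min()
    b0 = float(ys.min())
    a0 = float(max(ys.max() - b0, 1e-6))
    w = np.clip(ys - b0, 0, None) + 1e-12
    mu0 = float((xs * w).sum() / w.sum())
    s0 = float(np.sqrt(((xs - mu0) ** 2 * w).sum() / w.sum())) or span / 4
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                _gauss, xs, ys, p0=[a0, mu0, s0, b0],
                bounds=([0, xs.min() - span, 1e-4, 0],
                        [1.0, xs.max() + span, 2 * span, 1.0]),
                maxfev=5000)
    except RuntimeError as exc:
        raise FitError(f"{tp.dimension}: Gaussian fit did not converge") from exc
    a, mu, sigma, b = popt
    resid = ys - _gauss(xs, *popt)
    ss_tot = float(((ys - ys.mean()) ** 2).sum())
    tp.amplitude, tp.mu, tp.sigma, tp.baseline = float(a), float(mu), float(sigma), float(b)
    tp.mu_se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else float("nan")
    tp.r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else float("nan")


def fit_all_dimensions(samples: pd.DataFrame, bins: Optional[Dict] = None,
                       **kw) -> Dict[str, TuningProfile]:
    bins = bins or {}
    out = {}
    for dim in ("range", "azimuth", "elevation"):
        tp = tuning_profile(samples, dim, bins.get(dim), **kw)
        tp.anova_p = selectivity_anova(samples, dim, bins.get(dim))
        out[dim] = tp
    return out


def stability_split(samples: pd.DataFrame, *, alpha: float = 0.05,
                    bins: Optional[Dict] = None) -> dict:
    """Compare first- versus second-half tuning of a session.

    Splits the stimulus samples at the median emission time, requires 3D
    selectivity in both halves (otherwise ``indeterminate``), fits per-
    dimension Gaussians, and flags a change when the fitted means differ
    beyond their joint 95% confidence interval.
    """
    t_split = samples["t_emit"].median()
    halves = [samples[samples["t_emit"] <= t_split],
              samples[samples["t_emit"] > t_split]]
    if not all(is_selective_3d(h, alpha=alpha, bins=bins) for h in halves):
        return dict(indeterminate=True, changed={}, fits=None)
    changed, fits = {}, []
    for h in halves:
        try:
            fits.append(fit_all_dimensions(h, bins))
        except FitError:
            return dict(indeterminate=True, changed={}, fits=None)
    for dim in ("range", "azimuth", "elevation"):
        f1, f2 = fits[0][dim], fits[1][dim]
        se = np.sqrt(np.nansum([f1.mu_se ** 2, f2.mu_se ** 2]))
        changed[dim] = bool(abs(f1.mu - f2.mu) > 1.96 * se) if se > 0 else False
    return dict(indeterminate=False, changed=changed, fits=fits)


# ---------------------------------------------------------------------------
# SSG versus non-SSG statistics


@dataclass
class SSGComparison:
    """Per-unit comparison of range tuning between SSG and non-SSG echoes."""

    included: bool
    reason: str = ""
    n_ssg: int = 0
    n_nonssg: int = 0
    sigma_ssg: float = float("nan")
    sigma_nonssg: float = float("nan")
    mu_ssg: float = float("nan")
    mu_nonssg: float = float("nan")
    bf_stat: float = float("nan")
    bf_p: float = float("nan")
    ranksum_stat: float = float("nan")
    ranksum_p: float = float("nan")
    perm_p_bf: float = float("nan")
    perm_p_ranksum: float = float("nan")
    sharpened: bool = False
    shifted_closer: bool = False


def brown_forsythe(a, b):
    """Brown-Forsythe test (Levene with group medians) for equal dispersion."""
    return stats.levene(np.asarray(a, float), np.asarray(b, float), center="median")


def _ranksum_stat(ranks_a_sum: float, n1: int, n2: int) -> float:
    """Standardised rank-sum z statistic from the group-1 rank total."""
    mean = n1 * (n1 + n2 + 1) / 2.0
    sd = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    return (ranks_a_sum - mean) / sd


def permutation_power_screen(ssg_samples, nonssg_samples, *,
                             statistic: str = "ranksum", reps: int = 1000,
                             rng=None) -> float:
    """Permutation p-value of the observed SSG/non-SSG test statistic.

    Pools both sample sets, shuffles them into groups of the original sizes
    (without replacement), recomputes the chosen statistic per rep, and
    returns p = (1 + #{|shuffled| >= |observed|}) / (reps + 1).  Units enter
    the SSG comparison only when p < 0.05, which screens out comparisons too
    weak for the split to matter.
    """
    a = np.asarray(ssg_samples, float)
    b = np.asarray(nonssg_samples, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both sample sets must be non-empty")
    if reps < 100:
        import warnings
        warnings.warn(f"permutation screen with only {reps} reps", stacklevel=2)
    rng = np.random.default_rng(rng)
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    if statistic == "ranksum":
        # ranks of the pooled sample are invariant under shuffling, so each
        # rep reduces to summing a random subset of the fixed rank vector
        ranks = stats.rankdata(pooled)
        obs = abs(_ranksum_stat(ranks[:n1].sum(), n1, n2))
        perm = rng.permuted(np.broadcast_to(ranks, (reps, n1 + n2)), axis=1)
        shuf = np.abs(_ranksum_stat(perm[:, :n1].sum(axis=1), n1, n2))
    elif statistic == "bf":
        obs = abs(brown_forsythe(a, b).statistic)
        shuf = np.empty(reps)
        for k in range(reps):
            p = rng.permutation(pooled)
            shuf[k] = abs(brown_forsythe(p[:n1], p[n1:]).statistic)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return float((1 + np.sum(shuf >= obs)) / (reps + 1))


def compare_ssg_nonssg(samples: pd.DataFrame, *, alpha: float = 0.05,
                       n_min: int = 10, reps: int = 1000,
                       rng=None) -> SSGComparison:
    """Sharpening and shift of range tuning under sonar sound groups.

    Uses the ranges of spike-eliciting first echoes per condition as the
    per-condition response samples.  Dispersion equality is tested by
    Brown-Forsythe (sharpening when sigma_SSG < sigma_nonSSG and p < alpha),
    location by Wilcoxon rank-sum (shift toward shorter range when the SSG
    median is nearer and p < alpha).  Units failing the permutation power
    screen (p >= 0.05 on both statistics) or with fewer than ``n_min``
    responses per condition are excluded.
    """
    resp = samples[samples["response"] == 1]
    a = resp.loc[resp["ssg"], "range"].to_numpy()
    b = resp.loc[~resp["ssg"], "range"].to_numpy()
    if len(a) < n_min or len(b) < n_min:
        return SSGComparison(included=False, reason="insufficient responses",
                             n_ssg=len(a), n_nonssg=len(b))
    rng = np.random.default_rng(rng)
    perm_rs = permutation_power_screen(a, b, statistic="ranksum", reps=reps, rng=rng)
    perm_bf = permutation_power_screen(a, b, statistic="bf", reps=reps, rng=rng)
    bf = brown_forsythe(a, b)
    rs = stats.ranksums(a, b)
    out = SSGComparison(
        included=True, n_ssg=len(a), n_nonssg=len(b),
        sigma_ssg=float(np.std(a, ddof=1)), sigma_nonssg=float(np.std(b, ddof=1)),
        mu_ssg=float(np.median(a)), mu_nonssg=float(np.median(b)),
        bf_stat=float(bf.statistic), bf_p=float(bf.pvalue),
        ranksum_stat=float(rs.statistic), ranksum_p=float(rs.pvalue),
        perm_p_bf=perm_bf, perm_p_ranksum=perm_rs)
    if perm_bf >= alpha and perm_rs >= alpha:
        out.included = False
        out.reason = "failed permutation power screen"
        return out
    out.sharpened = bool(out.bf_p < alpha and out.sigma_ssg < out.sigma_nonssg)
    out.shifted_closer = bool(out.ranksum_p < alpha and out.mu_ssg < out.mu_nonssg)
    return out


def compare_first_last_ssg(samples: pd.DataFrame, groups, seq_voc_ids, *,
                           n_min: int = 10) -> dict:
    """Spike probability to echoes of the first versus last call of each SSG.

    ``groups`` are :class:`~echospace.sonar.SonarSoundGroup` objects indexing
    into ``seq_voc_ids`` (the session's ordered call ids).  For each group
    with >= 2 calls, the response flags to the first-call and last-call first
    echoes form one pair; pairs are compared by Wilcoxon sign-rank.
    """
    ids = np.asarray(seq_voc_ids)
    by_voc = samples.set_index("voc_id")["response"]
    first_resp, last_resp = [], []
    for g in groups:
        if len(g.calls) < 2:
            continue
        vf, vl = ids[g.calls[0]], ids[g.calls[-1]]
        if vf in by_voc.index and vl in by_voc.index:
            first_resp.append(int(by_voc[vf]))
            last_resp.append(int(by_voc[vl]))
    n = len(first_resp)
    if n < n_min:
        return dict(included=False, n=n, p=float("nan"),
                    p_first=float("nan"), p_last=float("nan"))
    first_resp = np.array(first_resp)
    last_resp = np.array(last_resp)
    diff = last_resp - first_resp
    if np.all(diff == 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(last_resp, first_resp, zero_method="wilcox").pvalue)
    return dict(included=True, n=n, p=p,
                p_first=float(first_resp.mean()), p_last=float(last_resp.mean()))
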