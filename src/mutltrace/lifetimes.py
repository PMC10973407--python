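"""Observed-lifetime distributions, censored repair kinetics, and the
short/long classification of foci.

A focus observed on k consecutive frames has observed lifetime k·Δt.  For
repaired errors the true lifetime is exponential with mean τ, and because the
acquisition grid has an unknown phase relative to the focus onset, the span k
of a *detected* focus is geometric:

    P(k) ∝ e^(−(k−1)Δt/τ) − e^(−kΔt/τ),  k = 1, 2, ...

`CensoredExponential` fits τ by maximum likelihood under this phase-averaged
interval censoring.  The bimodal lifetime distribution at coarse (2-min)
frames separates repaired errors (mode at one frame) from unrepaired ones
(mode near the doubling time); `determine_cutoff` finds the valley between
the two modes of a kernel-smoothed density on log-lifetime, and
`classify_foci` applies the threshold (strictly greater than the cutoff is
long-lived, so the 14-min printed threshold at 2-min frames makes k ≥ 8 the
long-lived set).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LifetimeDistribution",
    "lifetime_distribution",
    "CensoredExponential",
    "CensoredExponentialResults",
    "estimate_tau_censored",
    "CutoffResult",
    "determine_cutoff",
    "classify_foci",
    "drop_edge_foci",
    "compare_bleaching",
]


@dataclass
class LifetimeDistribution:
    """Histogram of observed foci spans at one frame interval.

    ``counts[i]`` is the number of foci seen on exactly ``spans[i]`` frames.
    """

    frame_interval_s: float
    spans: np.ndarray   # distinct k >= 1, increasing
    counts: np.ndarray  # nonnegative ints, same length

    def __post_init__(self) -> None:
        self.spans = np.asarray(self.spans, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.spans.size != self.counts.size:
            raise ValueError("spans and counts must have equal length")
        if (self.counts < 0).any() or (self.spans < 1).any():
            raise ValueError("spans must be >= 1 and counts nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def lifetimes_min(self) -> np.ndarray:
        return self.spans * self.frame_interval_s / 60.0

    @property
    def mean_observed_s(self) -> float:
        """Raw mean of observed lifetimes (k·Δt), seconds."""
        if self.total == 0:
            return math.nan
        return float((self.spans * self.counts).sum() / self.total * self.frame_interval_s)

    def normalized(self) -> np.ndarray:
        return self.counts / max(self.total, 1)

    def expand_seconds(self) -> np.ndarray:
        """One observed lifetime (seconds) per focus."""
        return np.repeat(self.spans * self.frame_interval_s, self.counts)

    def scaled(self, c: float) -> "LifetimeDistribution":
        """Same spans, all times multiplied by c."""
        return LifetimeDistribution(self.frame_interval_s * c, self.spans.copy(), self.counts.copy())


def lifetime_distribution(foci: pd.DataFrame) -> LifetimeDistribution:
    """Exact span histogram of a foci table; all records must share one Δt."""
    if len(foci) == 0:
        return LifetimeDistribution(math.nan, np.array([], dtype=np.int64), np.array([], dtype=np.int64))
    dts = foci["frame_interval_s"].unique()
    if len(dts) != 1:
        raise ValueError(f"mixed frame intervals in foci table: {sorted(dts)}; group by interval first")
    spans, counts = np.unique(foci["n_frames"].to_numpy(), return_counts=True)
    return LifetimeDistribution(float(dts[0]), spans, counts)


@dataclass(frozen=True)
class CensoredExponentialResults:
    """MLE of the repair (short-focus) lifetime under interval censoring."""

    tau_s: float
    se_s: float
    alpha: float
    n: int
    frame_interval_s: float
    mean_observed_s: float
    degenerate: bool
    tau_upper_s: float  # one-sided bound when degenerate, else Wald upper

    def conf_int(self, alpha: Optional[float] = None) -> tuple[float, float]:
        """Wald interval on log τ (keeps the bound positive)."""
        if self.degenerate:
            return (0.0, self.tau_upper_s)
        a = self.alpha if alpha is None else alpha
        z = stats.norm.ppf(1 - a / 2)
        half = z * self.se_s / self.tau_s
        return (self.tau_s * math.exp(-half), self.tau_s * math.exp(half))

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "Interval-censored exponential lifetime fit",
            f"  n foci                 {self.n}",
            f"  frame interval         {self.frame_interval_s:g} s",
            f"  tau (MLE)              {self.tau_s:.3g} s",
            f"  {100 * (1 - self.alpha):.0f}% CI                {lo:.3g} – {hi:.3g} s",
            f"  raw mean observed      {self.mean_observed_s:.3g} s",
        ]
        if self.degenerate:
            lines.append("  WARNING: all foci span a single frame; tau is only bounded above")
        return "\n".join(lines)


class CensoredExponential:
    """Exponential-lifetime model for short-lived foci under discrete frames.

    The observed span of a detected focus is geometric with ratio
    r = e^(−Δt/τ); the MLE is r̂ = 1 − 1/k̄ with k̄ the mean span.
    """

    def __init__(self, dist: LifetimeDistribution):
        if dist.total == 0:
            raise ValueError("empty lifetime distribution")
        self.dist = dist

    def loglike(self, tau_s: float) -> float:
        d = self.dist
        dt = d.frame_interval_s
        r = math.exp(-dt / tau_s)
        k = d.spans.astype(float)
        return float(np.sum(d.counts * ((k - 1) * math.log(r) + math.log1p(-r))))

    def fit(self, alpha: float = 0.05) -> CensoredExponentialResults:
        d = self.dist
        dt = d.frame_interval_s
        n = d.total
        kbar = float((d.spans * d.counts).sum() / n)
        if kbar <= 1.0:
            # all mass on single-frame foci: Δt far exceeds any plausible τ
            r_ub = 1.0 - alpha ** (1.0 / n)
            tau_ub = -dt / math.log(r_ub) if r_ub > 0 else math.nan
            return CensoredExponentialResults(
                tau_s=0.0, se_s=math.nan, alpha=alpha, n=n,
                frame_interval_s=dt, mean_observed_s=d.mean_observed_s,
                degenerate=True, tau_upper_s=tau_ub,
            )
        r = 1.0 - 1.0 / kbar
        tau = -dt / math.log(r)
        # delta method through r(k̄); Var(k) = r/(1−r)^2 for the geometric span
        se = dt * (1.0 - r) / (math.log(r) ** 2 * math.sqrt(r * n))
        z = stats.norm.ppf(1 - alpha / 2)
        return CensoredExponentialResults(
            tau_s=tau, se_s=se, alpha=alpha, n=n,
            frame_interval_s=dt, mean_observed_s=d.mean_observed_s,
            degenerate=False, tau_upper_s=tau * math.exp(z * se / tau),
        )


def estimate_tau_censored(dist: LifetimeDistribution, alpha: float = 0.05) -> CensoredExponentialResults:
    """Convenience wrapper: fit the censored exponential model to ``dist``."""
    return CensoredExponential(dist).fit(alpha=alpha)


@dataclass(frozen=True)
class CutoffResult:
    """Valley of the smoothed log-lifetime density between its two main modes."""

    cutoff_min: Optional[float]
    bimodal: bool
    modes_min: tuple
    valley_density: float
    peak_densities: tuple
    method: str = "kde-log-valley"

    def __bool__(self) -> bool:  # truthy iff a cutoff was found
        return self.bimodal


def determine_cutoff(dist: LifetimeDistribution, bw_adjust: float = 0.5, n_grid: int = 512,
                     min_foci: int = 50) -> CutoffResult:
    """Locate the short/long threshold from a bimodal lifetime distribution.

    A Gaussian KDE (Silverman bandwidth × ``bw_adjust``) is evaluated on
    log-lifetime; the cutoff is the density minimum between the two largest
    modes, reported in minutes.  Silverman's rule targets unimodal data and
    over-smooths a strongly bimodal histogram, so the default shrinks it;
    the contract is a valley between the one-frame mode and the
    doubling-time mode, robust to ±2 min, not a particular bandwidth.
    Unimodal input returns a failure state with diagnostics; fewer than
    ``min_foci`` foci are refused.
    """
    if dist.total < min_foci:
        raise ValueError(f"need at least {min_foci} foci to assess bimodality, got {dist.total}")
    x = np.log(dist.lifetimes_min)
    w = dist.counts.astype(float)
    if x.size < 2 or np.ptp(x) == 0:
        return CutoffResult(None, False, (float(np.exp(x[0])),), math.nan, (math.nan,))
    kde = stats.gaussian_kde(x, weights=w, bw_method="silverman")
    kde.set_bandwidth(kde.factor * bw_adjust)
    pad = 3.0 * float(np.sqrt(kde.covariance[0, 0]))  # 3 sd of the smoothing kernel
    grid = np.linspace(x.min() - pad, x.max() + pad, n_grid)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(interior) + 1
    if peaks.size < 2:
        modes = tuple(np.exp(grid[peaks])) if peaks.size else ()
        return CutoffResult(None, False, modes, math.nan, tuple(dens[peaks]))
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    i1, i2 = int(top2.min()), int(top2.max())
    valley = i1 + int(np.argmin(dens[i1:i2 + 1]))
    if dens[valley] >= min(dens[i1], dens[i2]):
        return CutoffResult(None, False, tuple(np.exp(grid[[i1, i2]])), float(dens[valley]),
                            (float(dens[i1]), float(dens[i2])))
    return CutoffResult(
        cutoff_min=float(np.exp(grid[valley])),
        bimodal=True,
        modes_min=(float(np.exp(grid[i1])), float(np.exp(grid[i2]))),
        valley_density=float(dens[valley]),
        peak_densities=(float(dens[i1]), float(dens[i2])),
    )


def classify_foci(foci: pd.DataFrame, cutoff_min: float = 14.0) -> pd.DataFrame:
    """Label each focus 'short' or 'long': long iff k·Δt strictly exceeds the cutoff.

    At Δt = 2 min with the 14-min threshold, the long-lived set is k ≥ 8.
    """
    dt_min = foci["frame_interval_s"] / 60.0
    if len(foci) and (cutoff_min <= dt_min).any():
        raise ValueError("cutoff must exceed the frame interval")
    out = foci.copy()
    out["label"] = np.where(foci["n_frames"] * dt_min > cutoff_min, "long", "short")
    return out


def drop_edge_foci(foci: pd.DataFrame, n_window_frames: int) -> pd.DataFrame:
    """Discard foci whose span touches the first or last frame of the window.

    Their true lifetime is right/left-truncated, so their short/long class is
    ambiguous; dropping them trades a ~1% count loss for unbiased labels.
    """
    first = foci["onset_frame"] == 0
    last = foci["onset_frame"] + foci["n_frames"] >= n_window_frames
    return foci.loc[~(first | last)].reset_index(drop=True)


def compare_bleaching(dists: Mapping[float, LifetimeDistribution], alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise two-sample KS comparison of lifetime distributions across Δt.

    Lifetimes are rescaled to seconds and re-discretized onto the coarser
    frame grid of each pair (snapping up to the next multiple of the larger
    Δt) before the test: for exponential lifetimes with uniform phase the
    snapped span law is identical across acquisition intervals, so the raw
    discretization difference does not masquerade as a lifetime change.  A
    significant divergence flags a photobleaching (or other
    acquisition-dependent) distortion.
    """
    keys = sorted(dists)
    rows = []
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            xa, xb = dists[a].expand_seconds(), dists[b].expand_seconds()
            if xa.size == 0 or xb.size == 0:
                raise ValueError("empty lifetime distribution in comparison")
            coarse = max(dists[a].frame_interval_s, dists[b].frame_interval_s)
            xa = np.ceil(xa / coarse - 1e-9) * coarse
            xb = np.ceil(xb / coarse - 1e-9) * coarse
            ks = stats.ks_2samp(xa, xb, method="asymp")
            rows.append({
                "dt_a_s": a, "dt_b_s": b, "n_a": xa.size, "n_b": xb.size,
                "ks_stat": float(ks.statistic), "pvalue": float(ks.pvalue),
                "significant": bool(ks.pvalue < alpha),
            })
    return pd.DataFrame(rows)
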