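"""Synthetic mother-machine lineages with ground-truth replication-error events.

The generator emulates the experimental system: each lineage is the mother
cell of one dead-end microchannel, followed for ~100 consecutive generations.
Replication errors arise as a homogeneous Poisson process along the lineage;
each error is independently left unrepaired with a small probability (a
Bernoulli "coin toss"), so nascent mutations form a compound Poisson process
with Bernoulli increments.  Repaired errors carry a short exponential focus
lifetime (~40 s); unrepaired errors carry a long focus lifetime of about one
doubling time, because the focus persists until the next replication cycle
fixes the error as a mutation.  An optional two-state telegraph process
modulates the failure probability to create transient hypermutable episodes
("mutation bursts") confined to single lineages.

Discrete imaging is applied separately: a focus is only recorded if at least
one acquisition frame falls inside its lifetime, and the observed lifetime is
the number of consecutive frames on which it is seen times the frame
interval.  Optional photobleaching extinguishes a visible focus permanently
after each exposure with fixed probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BurstParams",
    "SimulationParams",
    "ImagingConfig",
    "LineageTrace",
    "simulate_lineage",
    "apply_imaging",
    "simulate_experiment",
    "lineage_table",
    "emit_tables",
    "matched_burst_params",
]

#: canonical column order of the foci table
FOCI_COLUMNS = ["experiment_id", "lineage_id", "onset_frame", "n_frames", "frame_interval_s"]
#: extra ground-truth columns present for simulated data only
TRUTH_COLUMNS = ["true_onset_min", "true_lifetime_min", "outcome", "q_state"]
LINEAGE_COLUMNS = ["experiment_id", "lineage_id", "n_generations", "window_min", "doubling_time_min"]


@dataclass(frozen=True)
class BurstParams:
    """Two-state telegraph modulation of the repair-failure probability.

    While the hidden state is "on" the failure probability is ``q_high``
    instead of the baseline ``q``.  Dwell times in both states are
    exponential.  Defaults give episodes of mean 40 min (~1.5 generations at
    a 26.6-min doubling time) occupying ~5% of the time, which together with
    a baseline q of 0.005 yields a time-averaged failure probability of 1%.
    """

    q_high: float = 0.1
    switch_on_per_min: float = 0.025 * (0.0526316 / (1 - 0.0526316))
    switch_off_per_min: float = 1.0 / 40.0

    @property
    def on_fraction(self) -> float:
        return self.switch_on_per_min / (self.switch_on_per_min + self.switch_off_per_min)


def matched_burst_params(
    mean_failure: float = 0.01,
    q_low: float = 0.005,
    q_high: float = 0.1,
    dwell_on_min: float = 40.0,
) -> tuple[float, BurstParams]:
    """Baseline q and telegraph rates whose time-average equals ``mean_failure``.

    Returns ``(q_low, BurstParams)`` suitable for SimulationParams, with the
    "on" dwell fixed at ``dwell_on_min`` and the on-fraction solved from
    ``mean_failure = q_low (1-f) + q_high f``.
    """
    if not (q_low <= mean_failure <= q_high):
        raise ValueError("mean_failure must lie between q_low and q_high")
    f_on = (mean_failure - q_low) / (q_high - q_low)
    k_off = 1.0 / dwell_on_min
    k_on = k_off * f_on / (1.0 - f_on)
    return q_low, BurstParams(q_high=q_high, switch_on_per_min=k_on, switch_off_per_min=k_off)


@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth parameters of the lineage simulation.

    error_rate_per_min
        λ, replication errors per minute per lineage.  Default 0.14/26.6:
        ~0.14 errors per generation, matching the long-term mother-cell
        accounting in which 1% failures give ~0.0014 mutations/generation.
    failure_prob
        q, probability that repair of an error fails (Bernoulli).
    tau_short_s
        τ, mean of the exponential lifetime of repaired-error foci, seconds.
    doubling_time_min
        T_d, deterministic division interval, minutes.
    long_lifetime_cv
        relative spread of the unrepaired-focus lifetime about T_d.
    burst_params
        optional telegraph modulation of q; ``None`` keeps q constant.
    window_generations
        observation window expressed in generations (window = g·T_d minutes).
    """

    error_rate_per_min: float = 0.14 / 26.6
    failure_prob: float = 0.01
    tau_short_s: float = 40.0
    doubling_time_min: float = 26.6
    long_lifetime_cv: float = 0.2
    burst_params: Optional[BurstParams] = None
    n_lineages: int = 400
    window_generations: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("error_rate_per_min", "tau_short_s", "doubling_time_min", "window_generations"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if not (np.isfinite(self.failure_prob) and 0.0 <= self.failure_prob <= 1.0):
            raise ValueError(f"failure_prob must be in [0, 1], got {self.failure_prob!r}")
        if self.long_lifetime_cv < 0 or not np.isfinite(self.long_lifetime_cv):
            raise ValueError("long_lifetime_cv must be finite and >= 0")
        if self.n_lineages < 1:
            raise ValueError("n_lineages must be >= 1")
        if self.burst_params is not None and self.burst_params.q_high < self.failure_prob:
            raise ValueError("burst q_high must be >= baseline failure_prob")

    @property
    def window_min(self) -> float:
        return self.window_generations * self.doubling_time_min


@dataclass(frozen=True)
class ImagingConfig:
    """Discrete acquisition grid: frames at phase_offset_s + j·frame_interval_s.

    window_duration_min of ``None`` means "image the whole lineage window".
    bleach_per_exposure is the probability that a visible focus permanently
    drops below detection after each exposure (0 disables bleaching).
    """

    frame_interval_s: float
    window_duration_min: Optional[float] = None
    phase_offset_s: float = 0.0
    bleach_per_exposure: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.frame_interval_s) and self.frame_interval_s > 0):
            raise ValueError("frame_interval_s must be finite and > 0")
        if not (0.0 <= self.bleach_per_exposure < 1.0):
            raise ValueError("bleach_per_exposure must be in [0, 1)")
        if not (0.0 <= self.phase_offset_s < self.frame_interval_s):
            raise ValueError("phase_offset_s must lie in [0, frame_interval_s)")

    def n_frames(self, window_min: float) -> int:
        """Number of frames whose acquisition time falls inside the window."""
        return int(math.floor((window_min * 60.0 - self.phase_offset_s) / self.frame_interval_s)) + 1


@dataclass
class LineageTrace:
    """Ground truth for one simulated mother-cell lineage."""

    lineage_id: int
    window_min: float
    doubling_time_min: float
    onset_times_min: np.ndarray  # increasing, within [0, window)
    unrepaired: np.ndarray       # bool per event
    lifetimes_min: np.ndarray    # true focus lifetime per event
    q_state: np.ndarray          # telegraph state at onset (0/1)

    @property
    def division_times(self) -> np.ndarray:
        """Deterministic division times: multiples of T_d inside the window."""
        n = int(math.floor(self.window_min / self.doubling_time_min + 1e-9))
        return self.doubling_time_min * np.arange(1, n + 1)

    @property
    def n_events(self) -> int:
        return int(self.onset_times_min.size)


def _lineage_rng(seed: int, lineage_index: int, stream: int = 0) -> np.random.Generator:
    # per-lineage substream: lineage i is reproducible independent of n_lineages
    return np.random.default_rng([int(seed), int(lineage_index), int(stream)])


def _telegraph_states(rng: np.random.Generator, times: np.ndarray, window: float, bp: BurstParams) -> np.ndarray:
    """Hidden telegraph state (0=baseline, 1=high-q) at each event time."""
    state0 = int(rng.random() < bp.on_fraction)  # stationary start
    switches = []
    t, s = 0.0, state0
    while t < window:
        rate = bp.switch_off_per_min if s == 1 else bp.switch_on_per_min
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        if t < window:
            switches.append(t)
        s ^= 1
    switches = np.asarray(switches)
    n_before = np.searchsorted(switches, times, side="right")
    return ((state0 + n_before) % 2).astype(np.int8)


def simulate_lineage(params: SimulationParams, lineage_index: int, seed: Optional[int] = None) -> LineageTrace:
    """Simulate ground truth for one lineage.

    Error onsets are a homogeneous Poisson process at rate λ over the window;
    each is unrepaired with probability q (or q_high while the telegraph
    state is on).  Repaired lifetimes ~ Exp(τ); unrepaired lifetimes
    ~ T_d·(1+ε) with ε Gaussian, truncated away from zero.
    """
    rng = _lineage_rng(params.seed if seed is None else seed, lineage_index)
    window = params.window_min
    n = rng.poisson(params.error_rate_per_min * window)
    onsets = np.sort(rng.uniform(0.0, window, size=n))

    if params.burst_params is not None:
        states = _telegraph_states(rng, onsets, window, params.burst_params)
        q = np.where(states == 1, params.burst_params.q_high, params.failure_prob)
    else:
        states = np.zeros(n, dtype=np.int8)
        q = np.full(n, params.failure_prob)

    unrepaired = rng.random(n) < q
    lifetimes = np.empty(n)
    n_rep = int(n - unrepaired.sum())
    lifetimes[~unrepaired] = rng.exponential(params.tau_short_s / 60.0, size=n_rep)
    n_long = int(unrepaired.sum())
    eps = rng.normal(0.0, params.long_lifetime_cv, size=n_long)
    # truncate: a long-lived focus always outlives half a minute
    floor_min = 0.5
    bad = params.doubling_time_min * (1.0 + eps) <= floor_min
    while bad.any():
        eps[bad] = rng.normal(0.0, params.long_lifetime_cv, size=int(bad.sum()))
        bad = params.doubling_time_min * (1.0 + eps) <= floor_min
    lifetimes[unrepaired] = params.doubling_time_min * (1.0 + eps)

    return LineageTrace(
        lineage_id=int(lineage_index),
        window_min=window,
        doubling_time_min=params.doubling_time_min,
        onset_times_min=onsets,
        unrepaired=unrepaired,
        lifetimes_min=lifetimes,
        q_state=states,
    )


def apply_imaging(
    trace: LineageTrace,
    imaging: ImagingConfig,
    rng: Optional[np.random.Generator] = None,
    experiment_id: str = "sim",
) -> pd.DataFrame:
    """Observed foci table that discrete imaging would record for one lineage.

    A focus alive on [onset, onset+L) is detected iff at least one frame time
    falls in that interval (and it has not bleached before its first frame).
    The observed span is the number of consecutive frames on which it is
    visible; bleaching truncates the span with per-exposure probability.
    Returns a DataFrame in the foci-table schema plus ground-truth columns;
    empty traces yield an empty frame.
    """
    dt = imaging.frame_interval_s
    phase = imaging.phase_offset_s
    window_min = imaging.window_duration_min if imaging.window_duration_min is not None else trace.window_min
    m = imaging.n_frames(window_min)

    onset_s = trace.onset_times_min * 60.0
    end_s = onset_s + trace.lifetimes_min * 60.0
    j0 = np.ceil((onset_s - phase) / dt).astype(np.int64)
    np.maximum(j0, 0, out=j0)
    j1 = np.ceil((end_s - phase) / dt).astype(np.int64) - 1
    np.minimum(j1, m - 1, out=j1)
    detected = (j1 >= j0) & (onset_s < window_min * 60.0)

    span = (j1 - j0 + 1)[detected]
    if imaging.bleach_per_exposure > 0 and span.size:
        if rng is None:
            rng = np.random.default_rng()
        # focus survives until the exposure that bleaches it (seen on that frame)
        survive = rng.geometric(imaging.bleach_per_exposure, size=span.size)
        span = np.minimum(span, survive)

    df = pd.DataFrame(
        {
            "experiment_id": experiment_id,
            "lineage_id": trace.lineage_id,
            "onset_frame": j0[detected],
            "n_frames": span.astype(np.int64),
            "frame_interval_s": dt,
            "true_onset_min": trace.onset_times_min[detected],
            "true_lifetime_min": trace.lifetimes_min[detected],
            "outcome": np.where(trace.unrepaired[detected], "unrepaired", "repaired"),
            "q_state": trace.q_state[detected],
        }
    )
    return df


def simulate_experiment(
    params: SimulationParams,
    imaging: ImagingConfig,
    experiment_id: str = "sim",
) -> tuple[list[LineageTrace], pd.DataFrame]:
    """Simulate all lineages and the foci table their imaging would produce."""
    traces = []
    frames = []
    for i in range(params.n_lineages):
        trace = simulate_lineage(params, i)
        traces.append(trace)
        rng = _lineage_rng(params.seed, i, stream=1)
        frames.append(apply_imaging(trace, imaging, rng=rng, experiment_id=experiment_id))
    if frames:
        foci = pd.concat(frames, ignore_index=True)
    else:
        foci = pd.DataFrame(columns=FOCI_COLUMNS + TRUTH_COLUMNS)
    return traces, foci


def lineage_table(traces: Sequence[LineageTrace], experiment_id: str = "sim") -> pd.DataFrame:
    """Lineage metadata table (one row per microchannel mother cell)."""
    return pd.DataFrame(
        {
            "experiment_id": experiment_id,
            "lineage_id": [t.lineage_id for t in traces],
            "n_generations": [t.window_min / t.doubling_time_min for t in traces],
            "window_min": [t.window_min for t in traces],
            "doubling_time_min": [t.doubling_time_min for t in traces],
        }
    )


def emit_tables(foci: pd.DataFrame, traces: Sequence[LineageTrace], out_dir, experiment_id: str = "sim"):
    """Write the foci and lineage CSV tables; returns the two paths.

    Ground-truth columns are kept in the foci table when present, so a
    simulated batch round-trips losslessly through the io readers.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    foci_path = out / "foci.csv"
    lin_path = out / "lineages.csv"
    cols = FOCI_COLUMNS + [c for c in TRUTH_COLUMNS if c in foci.columns]
    foci.loc[:, cols].to_csv(foci_path, index=False)
    lineage_table(traces, experiment_id).to_csv(lin_path, index=False)
    return foci_path, lin_path
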