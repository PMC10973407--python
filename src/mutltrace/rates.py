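"""Detection-corrected focus rates, mutation-rate estimates and the
cross-condition / replicative-age comparisons.

Discrete imaging misses short foci whose whole lifetime falls between two
frames.  For an exponential lifetime with mean τ and uniform phase relative
to the frame grid, the detection probability is

    p(τ, Δt) = (τ/Δt) · (1 − e^(−Δt/τ)),

so the corrected total error-production rate divides the short-focus count
by p while long-lived foci (lifetime ≈ one doubling time ≫ Δt) are taken as
fully detected.  The mutation rate per generation is the rate of long-lived
foci; the repair-failure fraction is the ratio of long-lived to all
(corrected) foci.  Poisson confidence intervals use the exact Garwood
(chi-square) construction; the replicative-age endpoint comparison uses an
unconditional exact 2×2 test (score statistic maximized over a nuisance
grid, the score variant of Barnard's test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "detection_probability",
    "poisson_ci",
    "proportion_ci",
    "RateEstimate",
    "corrected_total_rate",
    "mutation_rate_from_long_foci",
    "MAWGSInput",
    "generations_per_cycle",
    "ma_wgs_rate",
    "compare_rate_estimates",
    "repair_failure_fraction",
    "BarnardResult",
    "barnard_exact_score",
    "age_binned_analysis",
    "AgeBinResult",
    "fold_change",
]


def detection_probability(tau_s: float, dt_s: float) -> float:
    """Probability that an Exp(τ)-lifetime focus with uniform phase covers ≥1 frame."""
    if not (tau_s > 0 and dt_s > 0) or not (np.isfinite(tau_s) and np.isfinite(dt_s)):
        raise ValueError("tau_s and dt_s must be finite and positive")
    x = dt_s / tau_s
    return float(-math.expm1(-x) / x)


def poisson_ci(n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Garwood) two-sided CI for a Poisson count."""
    if n < 0:
        raise ValueError("count must be nonnegative")
    lo = 0.0 if n == 0 else stats.chi2.ppf(alpha / 2, 2 * n) / 2.0
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * n + 2) / 2.0
    return (float(lo), float(hi))


def proportion_ci(x: float, n: float, alpha: float = 0.05) -> tuple[float, float]:
    """Clopper–Pearson interval via beta quantiles (accepts non-integer n)."""
    if n <= 0 or x < 0 or x > n:
        raise ValueError("need 0 <= x <= n and n > 0")
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x >= n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return (lo, hi)


@dataclass(frozen=True)
class RateEstimate:
    """Raw and detection-corrected event rates with exact Poisson CIs."""

    n_events: int
    exposure_min: float
    exposure_generations: float
    detection_probability: float
    raw_rate_per_min: float
    corrected_rate_per_min: float
    ci_per_min: tuple
    alpha: float = 0.05

    @property
    def raw_rate_per_generation(self) -> float:
        return self.raw_rate_per_min * self.exposure_min / self.exposure_generations

    @property
    def corrected_rate_per_generation(self) -> float:
        return self.corrected_rate_per_min * self.exposure_min / self.exposure_generations

    @property
    def ci_per_generation(self) -> tuple:
        f = self.exposure_min / self.exposure_generations
        return (self.ci_per_min[0] * f, self.ci_per_min[1] * f)

    def summary(self) -> str:
        lo, hi = self.ci_per_min
        glo, ghi = self.ci_per_generation
        return "\n".join([
            "Rate estimate",
            f"  events                   {self.n_events}",
            f"  exposure                 {self.exposure_min:g} min "
            f"({self.exposure_generations:g} generations)",
            f"  detection probability    {self.detection_probability:.4f}",
            f"  raw rate                 {self.raw_rate_per_min:.4g} /min "
            f"({self.raw_rate_per_generation:.4g} /generation)",
            f"  corrected rate           {self.corrected_rate_per_min:.4g} /min "
            f"({self.corrected_rate_per_generation:.4g} /generation)",
            f"  {100*(1-self.alpha):.0f}% CI                   {lo:.4g} – {hi:.4g} /min "
            f"({glo:.4g} – {ghi:.4g} /generation)",
        ])


def corrected_total_rate(
    n_short: int,
    n_long: int,
    exposure_min: float,
    p_short: float,
    doubling_min: float = 26.6,
    alpha: float = 0.05,
) -> RateEstimate:
    """Total error-production rate with the discrete-observation correction.

    corrected = (n_short / p_short + n_long) / exposure.  Long-lived foci are
    assumed fully detected.  The CI scales the exact Poisson CI of the
    observed count by the correction factor; the leading variance term of the
    corrected count matches this scaling.
    """
    if not (0.0 < p_short <= 1.0):
        raise ValueError("p_short must lie in (0, 1]")
    if exposure_min <= 0:
        raise ValueError("exposure must be positive")
    n_obs = n_short + n_long
    n_eff = n_short / p_short + n_long
    raw = n_obs / exposure_min
    corrected = n_eff / exposure_min
    lo, hi = poisson_ci(n_obs, alpha)
    scale = (n_eff / n_obs) if n_obs > 0 else 1.0 / p_short
    return RateEstimate(
        n_events=n_obs,
        exposure_min=exposure_min,
        exposure_generations=exposure_min / doubling_min,
        detection_probability=p_short,
        raw_rate_per_min=raw,
        corrected_rate_per_min=corrected,
        ci_per_min=(lo * scale / exposure_min, hi * scale / exposure_min),
        alpha=alpha,
    )


def mutation_rate_from_long_foci(
    n_long: int,
    generations: float,
    doubling_min: float = 26.6,
    alpha: float = 0.05,
) -> RateEstimate:
    """Mutation rate per generation from long-lived foci, with exact Poisson CI."""
    if generations <= 0:
        raise ValueError("generations must be positive")
    exposure_min = generations * doubling_min
    lo, hi = poisson_ci(n_long, alpha)
    return RateEstimate(
        n_events=n_long,
        exposure_min=exposure_min,
        exposure_generations=generations,
        detection_probability=1.0,
        raw_rate_per_min=n_long / exposure_min,
        corrected_rate_per_min=n_long / exposure_min,
        ci_per_min=(lo / exposure_min, hi / exposure_min),
        alpha=alpha,
    )


def experiment_rates(
    foci: pd.DataFrame,
    windows_min: Sequence[float],
    n_window_frames: int,
    cutoff_min: float = 14.0,
    tau_s: float = 40.0,
    doubling_min: float = 26.6,
    alpha: float = 0.05,
) -> dict:
    """Canonical per-experiment rate accounting: total, mutation, failure fraction.

    Foci whose spans touch the window edges are discarded (their class is
    ambiguous), and each class gets the effective exposure inside which a
    focus of its typical lifetime fits entirely: W − τ − 2Δt for short foci,
    W − T_d − Δt for long ones.  The corrected total is
    n_short/(p·E_short) + n_long/E_long with p the detection probability of
    an Exp(τ) lifetime at this frame interval.
    """
    from .lifetimes import classify_foci, drop_edge_foci

    if len(foci) == 0:
        raise ValueError("empty foci table")
    dt_s = float(foci["frame_interval_s"].iloc[0])
    dt_min = dt_s / 60.0
    w = np.asarray(windows_min, dtype=float)
    clf = classify_foci(drop_edge_foci(foci, n_window_frames), cutoff_min)
    short = clf["label"] == "short"
    n_short = int(short.sum())
    n_long = int((~short).sum())
    p = detection_probability(tau_s, dt_s)
    e_short = float(np.clip(w - tau_s / 60.0 - 2 * dt_min, 0.0, None).sum())
    e_long = float(np.clip(w - doubling_min - dt_min, 0.0, None).sum())
    exposure = float(w.sum())
    # the 1/p correction compensates sampling loss of Exp(τ) lifetimes; spans
    # beyond ~6.9τ (< 0.1% exponential tail mass) are not plausibly such foci
    # (they are truncated long-lifetime spans) and enter at unit weight
    k_tau = max(1, math.ceil(6.9 * tau_s / dt_s))
    n_short_exp = int((short & (clf["n_frames"] <= k_tau)).sum())
    n_short_other = n_short - n_short_exp
    corrected = (n_short_exp / p + n_short_other) / e_short + n_long / e_long
    n_obs = n_short + n_long
    glo, ghi = poisson_ci(n_obs, alpha)
    scale = corrected / n_obs if n_obs > 0 else 1.0
    total = RateEstimate(
        n_events=n_obs,
        exposure_min=exposure,
        exposure_generations=exposure / doubling_min,
        detection_probability=p,
        raw_rate_per_min=n_obs / exposure,
        corrected_rate_per_min=corrected,
        ci_per_min=(glo * scale, ghi * scale),
        alpha=alpha,
    )
    mutation = mutation_rate_from_long_foci(
        n_long, e_long / doubling_min, doubling_min=doubling_min, alpha=alpha
    )
    n_all_corrected = n_short_exp / p + n_short_other + n_long
    frac, frac_ci = repair_failure_fraction(n_long, n_all_corrected, alpha) if n_obs else (math.nan, (math.nan, math.nan))
    return {
        "n_short": n_short,
        "n_long": n_long,
        "classified": clf,
        "total": total,
        "mutation": mutation,
        "failure_fraction": frac,
        "failure_fraction_ci": frac_ci,
    }


def long_exposure_generations(
    windows_min: Sequence[float], doubling_min: float = 26.6, dt_min: float = 2.0
) -> float:
    """Effective exposure (generations) for counting classifiable long-lived foci.

    A long-lived focus (mean lifetime one doubling time) is only classifiable
    when its whole span lies inside the observation window, so each lineage
    contributes its window minus one doubling time and one frame.  Pairs with
    `drop_edge_foci`, which discards the window-touching spans.
    """
    w = np.asarray(windows_min, dtype=float)
    eff = np.clip(w - doubling_min - dt_min, 0.0, None)
    return float(eff.sum() / doubling_min)


@dataclass(frozen=True)
class MAWGSInput:
    """Mutation-accumulation + whole-genome-sequencing design summary."""

    n_mutations: int
    n_lines: int
    dilution_factor: float
    n_cycles: int

    def __post_init__(self) -> None:
        if self.n_mutations < 0 or self.n_lines < 1 or self.n_cycles < 1:
            raise ValueError("counts must be positive (mutations nonnegative)")
        if not self.dilution_factor > 1:
            raise ValueError("dilution_factor must exceed 1")


def generations_per_cycle(dilution_factor: float) -> float:
    """Generations per growth cycle implied by the daily bottleneck dilution."""
    if not dilution_factor > 1:
        raise ValueError("dilution_factor must exceed 1")
    return math.log2(dilution_factor)


def ma_wgs_rate(inp: MAWGSInput, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Mutations per genome per generation from an MA+WGS experiment.

    rate = n_mutations / (n_lines × generations_per_cycle × n_cycles),
    with an exact Poisson CI on the mutation count.
    """
    g = generations_per_cycle(inp.dilution_factor)
    denom = inp.n_lines * g * inp.n_cycles
    lo, hi = poisson_ci(inp.n_mutations, alpha)
    return inp.n_mutations / denom, (lo / denom, hi / denom)


def compare_rate_estimates(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance two-sided t-test on per-group rate samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two samples per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (math.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def repair_failure_fraction(
    n_long: int, n_all_corrected: float, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Fraction of (corrected) foci that are long-lived, with binomial CI.

    This ratio of the long-lived focus rate to the total focus rate is the
    per-error repair *failure* probability; its complement is what the study
    system calls repair efficiency.
    """
    if n_all_corrected <= 0:
        raise ValueError("n_all_corrected must be positive")
    if n_long > n_all_corrected:
        raise ValueError("n_long cannot exceed the corrected total")
    ratio = n_long / n_all_corrected
    return ratio, proportion_ci(n_long, n_all_corrected, alpha)


# ---------------------------------------------------------------------------
# unconditional exact 2x2 test (score variant)

def _score_z(x1: np.ndarray, x2: np.ndarray, n1: int, n2: int) -> np.ndarray:
    p1 = x1 / n1
    p2 = x2 / n2
    pp = (x1 + x2) / (n1 + n2)
    denom = np.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (p1 - p2) / denom
    return np.where(denom > 0, z, 0.0)


@dataclass(frozen=True)
class BarnardResult:
    statistic: float
    pvalue: float
    grid_step: float
    table: tuple


def barnard_exact_score(table, grid_step: float = 0.001) -> BarnardResult:
    """Unconditional exact two-sided test for a 2×2 table with fixed row totals.

    Rows are the two groups (sizes fixed by design), column 0 the successes.
    The pooled score statistic orders the sample space; the p-value maximizes
    the exceedance probability over the common nuisance success probability
    on a grid of the given step.  Identical rows give p = 1 by construction.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a nonnegative 2x2 array")
    n1 = int(t[0].sum())
    n2 = int(t[1].sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both rows must contain observations")
    x1o, x2o = int(t[0, 0]), int(t[1, 0])
    z_obs = float(_score_z(np.array(x1o, float), np.array(x2o, float), n1, n2))

    k1 = np.arange(n1 + 1)
    k2 = np.arange(n2 + 1)
    z = _score_z(k1[:, None].astype(float), k2[None, :].astype(float), n1, n2)
    extreme = np.abs(z) >= abs(z_obs) - 1e-12

    grid = np.arange(grid_step, 1.0, grid_step)
    pmf1 = stats.binom.pmf(k1[:, None], n1, grid[None, :])  # (n1+1, G)
    pmf2 = stats.binom.pmf(k2[:, None], n2, grid[None, :])  # (n2+1, G)
    m = extreme.astype(float) @ pmf2                        # (n1+1, G)
    pvals = np.einsum("kg,kg->g", pmf1, m)
    return BarnardResult(statistic=z_obs, pvalue=float(min(pvals.max(), 1.0)),
                         grid_step=grid_step, table=tuple(map(tuple, t.tolist())))


@dataclass(frozen=True)
class AgeBinResult:
    """Repair-failure fraction per replicative-age bin plus the endpoint test."""

    bins: pd.DataFrame
    endpoint_table: tuple
    endpoint_pvalue: float
    bin_generations: float


def age_binned_analysis(
    foci: pd.DataFrame,
    doubling_min: float = 26.6,
    bin_generations: float = 10.0,
    alpha: float = 0.05,
) -> AgeBinResult:
    """Long-lived fraction vs replicative age, and a first-vs-last-bin test.

    Foci must carry a 'label' column.  Replicative age of each focus is its
    onset time in generations (deterministic divisions every T_d); cells are
    binned by ``bin_generations``.  The endpoint comparison applies the
    unconditional exact test to the 2×2 table of long/short counts in the
    first and last bins.
    """
    if "label" not in foci.columns:
        raise ValueError("foci must be classified first (missing 'label' column)")
    if len(foci) == 0:
        raise ValueError("empty foci table")
    gen = foci["onset_frame"] * foci["frame_interval_s"] / 60.0 / doubling_min
    b = np.floor(gen / bin_generations).astype(int)
    long = (foci["label"] == "long").to_numpy()
    rows = []
    for bi in np.unique(b):
        sel = b == bi
        n_all = int(sel.sum())
        n_long = int(long[sel].sum())
        lo, hi = proportion_ci(n_long, n_all, alpha)
        rows.append({
            "bin": int(bi),
            "age_generations": (bi + 0.5) * bin_generations,
            "n_long": n_long,
            "n_total": n_all,
            "fraction_long": n_long / n_all,
            "ci_low": lo,
            "ci_high": hi,
        })
    bins = pd.DataFrame(rows)
    first, last = bins.iloc[0], bins.iloc[-1]
    if first["n_total"] == 0 or last["n_total"] == 0 or len(bins) < 2:
        raise ValueError("need nonempty first and last age bins")
    table = (
        (int(first["n_long"]), int(first["n_total"] - first["n_long"])),
        (int(last["n_long"]), int(last["n_total"] - last["n_long"])),
    )
    res = barnard_exact_score(table)
    return AgeBinResult(bins=bins, endpoint_table=table,
                        endpoint_pvalue=res.pvalue, bin_generations=bin_generations)


def fold_change(
    n_a: int, exposure_a: float, n_b: int, exposure_b: float, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Ratio of two Poisson rates with the conditional-binomial exact CI.

    Conditional on the total count, n_a is binomial; the Clopper–Pearson
    interval on that proportion transforms to an interval on the rate ratio.
    A zero numerator yields ratio 0 with an informative upper bound only.
    """
    if exposure_a <= 0 or exposure_b <= 0:
        raise ValueError("exposures must be positive")
    n = n_a + n_b
    if n == 0:
        raise ValueError("no events in either condition")
    ratio = (n_a / exposure_a) / (n_b / exposure_b) if n_b > 0 else math.inf
    lo_p, hi_p = proportion_ci(n_a, n, alpha)
    f = exposure_b / exposure_a
    lo = (lo_p / (1 - lo_p)) * f if lo_p < 1 else math.inf
    hi = (hi_p / (1 - hi_p)) * f if hi_p < 1 else math.inf
    return ratio, (lo, hi)
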