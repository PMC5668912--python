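"""Sampling-efficiency measurement: populations, folding times, kinetics.

Given per-simulation native-state flags (from the CαβRMSD classifier)
this module computes

* aggregated native-state populations across N replicate simulations,
  with the sample SD (N−1 denominator) and SE = SD/√N;
* first-passage folding records (event time of the first saved frame at
  or below the cutoff, right-censored at the full run length otherwise);
* folding times τ_f = 1/k_f by survival analysis — the nonparametric
  Kaplan–Meier product-limit estimator and the exponential
  maximum-likelihood fit, combined by the two-step procedure of
  :func:`estimate_folding_time`;
* two-state kinetics diagnostics: under D ⇌ N with folding rate k_f the
  nonnative fraction decays as exp(−k_f·t), so ln(nonnative) is linear
  in time (:func:`ln_nonnative_regression`);
* pooled-variance unpaired t-tests between population-vs-time curves.

Times are in ns of effective (standard-mass) time throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats

from .errors import (
    AlignmentError,
    DegenerateInputError,
    FoldingTimeDiscardedError,
    InsufficientReplicatesError,
    NoEventError,
)


@dataclass(frozen=True)
class FoldingRecord:
    """One simulation's folding outcome.

    ``time`` (ns, effective standard-mass time) is the first-passage
    time when ``event`` is True, or the full simulated duration when the
    run ended without folding (right-censored).
    """

    time: float
    event: bool

    def __post_init__(self):
        if self.time <= 0:
            raise DegenerateInputError("folding-record time must be > 0")


@dataclass(frozen=True)
class TwoStateModel:
    """First-order two-state scheme D ⇌ N with rates in ns⁻¹."""

    k_f: float
    k_u: float = 0.0

    def __post_init__(self):
        if self.k_f < 0 or self.k_u < 0:
            raise DegenerateInputError("rates must be >= 0")

    @property
    def tau_f(self) -> float:
        return math.inf if self.k_f == 0 else 1.0 / self.k_f


@dataclass
class PopulationSeries:
    """Aggregated native-state population at a grid of step-count checkpoints.

    Mirrors the layout of the benchmark tables: one row per checkpoint
    with the aggregated simulation time (μs, summed over the N runs),
    the mean population (%), its SD and SE (%), plus the per-simulation
    populations the aggregate was formed from.
    """

    checkpoints: np.ndarray       # step counts
    aggregated_time: np.ndarray   # μs, N × checkpoint × effective_dt
    mean: np.ndarray              # %
    sd: np.ndarray                # %
    se: np.ndarray                # %
    n_sims: int
    per_sim: np.ndarray           # (n_checkpoints, n_sims), fractions

    def to_frame(self):
        """Table-style DataFrame (percentages at full precision)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "checkpoint_steps": self.checkpoints,
                "aggregated_time_us": self.aggregated_time,
                "mean_pct": self.mean,
                "sd_pct": self.sd,
                "se_pct": self.se,
            }
        )


@dataclass
class SurvivalFit:
    """Folding time τ_f (ns) with 95% confidence limits.

    ``estimator`` names the producing method (``"kaplan_meier"`` or
    ``"exponential"``); ``km_agrees`` records, for the two-step
    procedure, whether the product-limit and parametric means agreed.
    """

    tau_f: float
    lcl: float
    ucl: float
    estimator: str
    n_events: int
    km_agrees: bool | None = None

    def __post_init__(self):
        if not (self.lcl <= self.tau_f <= self.ucl):
            raise DegenerateInputError("confidence limits must bracket tau_f")


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

def individual_population(native_flags: np.ndarray) -> float:
    """Fraction of saved frames classified native, in [0, 1]."""
    flags = np.asarray(native_flags, dtype=bool)
    if flags.size == 0:
        raise DegenerateInputError("empty native-flag series")
    return float(np.count_nonzero(flags)) / flags.size


def aggregate_population(per_sim: np.ndarray) -> tuple[float, float, float]:
    """(mean %, SD %, SE %) across N replicate simulations.

    SD is the sample standard deviation (N−1 denominator); SE = SD/√N.
    """
    p = np.asarray(per_sim, dtype=float)
    n = p.size
    if n < 2:
        raise InsufficientReplicatesError(
            "aggregated population requires >= 2 simulations"
        )
    mean = float(np.mean(p)) * 100.0
    sd = float(np.std(p, ddof=1)) * 100.0
    se = sd / math.sqrt(n)
    return mean, sd, se


def population_time_series(
    native_flag_matrix: np.ndarray,
    checkpoints: np.ndarray,
    save_interval: int,
    effective_dt: float,
) -> PopulationSeries:
    """Aggregated population at each step-count checkpoint.

    ``native_flag_matrix`` is (n_sims, n_frames) with frames saved every
    ``save_interval`` steps; at each checkpoint every per-simulation
    population uses only the frames up to that step count.
    ``aggregated_time`` is N × checkpoint × ``effective_dt`` (fs),
    reported in μs.
    """
    m = np.asarray(native_flag_matrix, dtype=bool)
    if m.ndim != 2:
        raise AlignmentError("native_flag_matrix must be 2-D (ragged input?)")
    checkpoints = np.asarray(checkpoints, dtype=np.int64)
    n_sims, n_frames = m.shape
    if np.any(checkpoints // save_interval > n_frames):
        raise AlignmentError("checkpoint beyond the simulated length")
    rows = []
    per_sim = np.empty((len(checkpoints), n_sims))
    for c, ck in enumerate(checkpoints):
        k = int(ck // save_interval)
        if k == 0:
            raise AlignmentError("checkpoint smaller than the save interval")
        per_sim[c] = np.count_nonzero(m[:, :k], axis=1) / k
        rows.append(aggregate_population(per_sim[c]))
    mean, sd, se = map(np.array, zip(*rows))
    return PopulationSeries(
        checkpoints=checkpoints,
        aggregated_time=n_sims * checkpoints * effective_dt * 1e-9,
        mean=mean,
        sd=sd,
        se=se,
        n_sims=n_sims,
        per_sim=per_sim,
    )


# ---------------------------------------------------------------------------
# First passage and survival estimation
# ---------------------------------------------------------------------------

def first_passage(
    rmsd_series: np.ndarray,
    cutoff: float,
    save_interval: int,
    effective_dt: float,
    n_steps: int,
) -> FoldingRecord:
    """Folding record from a per-frame RMSD series.

    The event time is the (1-based) index of the first frame at or
    below the cutoff, times ``save_interval × effective_dt``; a series
    that never crosses is right-censored at ``n_steps × effective_dt``.
    Times are returned in ns (1 ns = 10⁶ fs).
    """
    series = np.asarray(rmsd_series, dtype=float)
    below = np.nonzero(series <= cutoff)[0]
    if below.size:
        t_fs = (below[0] + 1) * save_interval * effective_dt
        return FoldingRecord(time=t_fs * 1e-6, event=True)
    return FoldingRecord(time=n_steps * effective_dt * 1e-6, event=False)


def _split(records) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    if times.size == 0:
        raise DegenerateInputError("no folding records")
    return times, events


def km_fit(records) -> SurvivalFit:
    """Kaplan–Meier product-limit fit; mean = restricted area under S(t).

    The mean is the area under the survival curve restricted to the
    largest observed time; its 95% CI comes from the Greenwood variance
    of that restricted mean.
    """
    times, events = _split(records)
    if not events.any():
        raise NoEventError("Kaplan-Meier fit requires at least one event")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    # restricted mean: integrate the step function S(t) from 0 to t_max
    t_max = float(times.max())
    sf = kmf.survival_function_.iloc[:, 0]
    grid = np.asarray(sf.index, dtype=float)
    surv = np.asarray(sf.values, dtype=float)
    mean = 0.0
    var = 0.0
    # area and Greenwood variance of the restricted mean
    knots = np.append(grid, t_max)
    for k in range(len(grid)):
        left, right = knots[k], min(knots[k + 1], t_max)
        if right > left:
            mean += surv[k] * (right - left)
    ev = kmf.event_table
    at_risk = ev["at_risk"].to_numpy(dtype=float)
    d = ev["observed"].to_numpy(dtype=float)
    ts = np.asarray(ev.index, dtype=float)
    for k in range(len(ts)):
        if d[k] > 0 and at_risk[k] > d[k]:
            # A(t_k): area under S from t_k to t_max
            a = 0.0
            for m in range(len(grid)):
                left = max(grid[m], ts[k])
                right = min(knots[m + 1], t_max)
                if right > left:
                    a += surv[m] * (right - left)
            var += a**2 * d[k] / (at_risk[k] * (at_risk[k] - d[k]))
        elif d[k] > 0 and at_risk[k] == d[k]:
            pass  # last event takes the curve to 0: no variance contribution
    se = math.sqrt(var)
    return SurvivalFit(
        tau_f=mean,
        lcl=max(mean - 1.959963984540054 * se, 0.0),
        ucl=mean + 1.959963984540054 * se,
        estimator="kaplan_meier",
        n_events=int(events.sum()),
    )


def exponential_fit(records) -> SurvivalFit:
    """Exponential maximum-likelihood fit for censored folding times.

    τ̂ = (total observed + censored exposure) / (number of events); the
    95% CI is the log-normal approximation exp(ln τ̂ ± 1.96/√events).
    With no censoring τ̂ is exactly the sample mean.
    """
    times, events = _split(records)
    d = int(events.sum())
    if d == 0:
        raise NoEventError("exponential fit requires at least one event")
    tau = float(times.sum()) / d
    z = 1.959963984540054
    half = z / math.sqrt(d)
    return SurvivalFit(
        tau_f=tau,
        lcl=tau * math.exp(-half),
        ucl=tau * math.exp(half),
        estimator="exponential",
        n_events=d,
    )


def estimate_folding_time(
    records,
    full_length: bool = True,
    agreement_rtol: float = 0.01,
) -> SurvivalFit:
    """Two-step folding-time estimate from N replicate simulations.

    For a full-length set in which every run folded, the Kaplan–Meier
    mean is compared with the exponential MLE; if they agree within
    ``agreement_rtol`` relative, the parametric (exponential) fit is
    returned as the selected model, otherwise the Kaplan–Meier fit with
    ``km_agrees=False``.  Sets with censored runs fall back to the
    exponential fit.  A *shortened* set (``full_length=False``) in which
    half or more of the runs did not fold is refused outright: its
    confidence interval would be uninformatively wide.
    """
    times, events = _split(records)
    n = len(times)
    n_censored = int(n - events.sum())
    if not full_length and 2 * n_censored >= n:
        raise FoldingTimeDiscardedError(
            f"{n_censored}/{n} shortened simulations censored: "
            "folding-time estimate discarded (overly wide 95% CI)"
        )
    if n_censored > 0:
        return exponential_fit(records)
    km = km_fit(records)
    exp = exponential_fit(records)
    agrees = abs(km.tau_f - exp.tau_f) <= agreement_rtol * km.tau_f
    if agrees:
        exp.km_agrees = True
        return exp
    km.km_agrees = False
    return km


# ---------------------------------------------------------------------------
# Two-state kinetics and curve comparison
# ---------------------------------------------------------------------------

def ln_nonnative_regression(
    records, time_grid: np.ndarray
) -> tuple[float, float, float]:
    """OLS of ln(nonnative fraction) against time.

    The nonnative fraction at t is the fraction of simulations that had
    not folded by t.  Under two-state kinetics ln([D]/[D]₀) = −k_f·t, so
    the slope estimates −k_f = −1/τ_f.  Returns (slope ns⁻¹, intercept,
    r²).  Requires ≥3 grid points with a positive nonnative fraction.
    """
    times, events = _split(records)
    grid = np.asarray(time_grid, dtype=float)
    frac = np.array(
        [np.mean(~((times <= t) & events)) for t in grid]
    )
    keep = frac > 0
    if keep.sum() < 3:
        raise DegenerateInputError(
            "ln-nonnative regression needs >= 3 grid points with "
            "nonnative fraction > 0"
        )
    res = stats.linregress(grid[keep], np.log(frac[keep]))
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def curve_ttest(
    means_a: np.ndarray, means_b: np.ndarray
) -> tuple[float, int, float]:
    """Pooled-variance unpaired two-sample t-test between two curves.

    The inputs are aggregated-population means (%) at matched
    step-count checkpoints.  Returns (t, df, two-tailed P) with
    df = n_a + n_b − 2 (Student, not Welch).
    """
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateInputError("each curve needs >= 2 checkpoints")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), len(a) + len(b) - 2, float(p)
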