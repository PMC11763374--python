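"""Minimal-triplet divergence-point analysis.

Aggregates repetitions of a trajectory (optionally time-normalized per
interval), estimates where two mean trajectories begin to diverge with a
threshold/run-length detector on the standardized difference, and tests
synchrony of consonant and vowel onsets by contrasting the divergence times
of the two minimal pairs sharing a control condition.

The detector flags the earliest time at which ``|mean_a - mean_b|`` exceeds
``k`` pooled per-time standard deviations for ``r`` consecutive samples, and
reports the start of that run.  Confidence intervals come from a bootstrap
over repetitions (not time points), which preserves within-trajectory
autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .sequencing import Channel, Trajectory

__all__ = [
    "RepetitionSet",
    "Aggregate",
    "DivergenceConfig",
    "DivergenceResult",
    "SynchronyResult",
    "aggregate",
    "estimate_divergence_point",
    "synchrony_test",
]


@dataclass(frozen=True)
class RepetitionSet:
    """Repeated productions of one condition on a common channel."""

    repetitions: tuple[Trajectory, ...]
    label: str = ""
    time_normalize: bool = True

    def __post_init__(self):
        object.__setattr__(self, "repetitions", tuple(self.repetitions))
        if len(self.repetitions) < 2:
            raise InvalidInputError("need >= 2 repetitions for variance estimates")
        channels = {r.channel.name for r in self.repetitions}
        if len(channels) > 1:
            raise InvalidInputError(f"mismatched channels: {sorted(channels)}")

    @property
    def channel(self) -> Channel:
        return self.repetitions[0].channel


@dataclass(frozen=True)
class Aggregate:
    """Pointwise mean and SD across repetitions, with the rep matrix kept
    for bootstrap resampling."""

    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: int
    matrix: np.ndarray = field(repr=False, default=None)  # (n, T)
    label: str = ""


@dataclass(frozen=True)
class DivergenceConfig:
    """Detector and bootstrap settings."""

    threshold_k: float = 2.0
    run_length_r: int = 5
    n_bootstrap: int = 200
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self):
        if self.threshold_k <= 0:
            raise InvalidInputError("threshold_k must be > 0")
        if self.run_length_r < 1:
            raise InvalidInputError("run_length_r must be >= 1")
        if self.n_bootstrap < 100:
            raise InvalidInputError("n_bootstrap must be >= 100")


@dataclass(frozen=True)
class DivergenceResult:
    t_div: float | None
    ci_low: float | None
    ci_high: float | None
    trace: np.ndarray = field(repr=False, default=None)
    times: np.ndarray = field(repr=False, default=None)
    bootstrap_detected: float = 0.0  # fraction of bootstrap draws with a detection


@dataclass(frozen=True)
class SynchronyResult:
    delta_t: float | None
    ci_low: float | None
    ci_high: float | None
    t_div_c: float | None
    t_div_v: float | None
    determined: bool = True

    @property
    def synchrony_supported(self) -> bool | None:
        if not self.determined or self.ci_low is None:
            return None
        return self.ci_low <= 0.0 <= self.ci_high


def _normalize_repetitions(reps: RepetitionSet, rate: float | None) -> tuple[np.ndarray, np.ndarray]:
    """Map each repetition's interval k linearly onto the condition-mean
    interval durations and resample onto a common uniform grid."""
    trajs = reps.repetitions
    n_bounds = {len(t.boundary_times) for t in trajs}
    if len(n_bounds) > 1:
        raise InvalidInputError("repetitions disagree on interval structure")
    if rate is None:
        rate = trajs[0].rate
    # per-repetition edges including both ends
    edges = np.array(
        [
            np.concatenate(([t.times[0]], t.boundary_times, [t.times[-1]]))
            for t in trajs
        ]
    )
    mean_edges = edges.mean(axis=0)
    n = int(np.floor((mean_edges[-1] - mean_edges[0]) * rate + 1e-9))
    grid = mean_edges[0] + np.arange(n + 1) / rate
    matrix = np.empty((len(trajs), len(grid)))
    for i, t in enumerate(trajs):
        # warp the common grid back into this repetition's own clock
        own_time = np.interp(grid, mean_edges, edges[i])
        matrix[i] = np.interp(own_time, t.times, t.values)
    return grid, matrix


def _common_grid(reps: RepetitionSet, rate: float | None) -> tuple[np.ndarray, np.ndarray]:
    trajs = reps.repetitions
    lengths = {len(t.times) for t in trajs}
    if len(lengths) > 1:
        raise InvalidInputError(
            "repetitions have different lengths; enable time normalization"
        )
    times = trajs[0].times
    for t in trajs[1:]:
        if not np.allclose(t.times, times, atol=1e-9):
            raise InvalidInputError(
                "repetition clocks differ; enable time normalization"
            )
    return times, np.array([t.values for t in trajs])


def aggregate(reps: RepetitionSet, rate: float | None = None) -> Aggregate:
    """Pointwise mean and SD (ddof=1) across repetitions.

    When ``reps.time_normalize`` is set and the repetitions carry interval
    boundaries, each repetition is first warped linearly per interval onto
    the condition's mean interval durations.
    """
    if reps.time_normalize and len(reps.repetitions[0].boundary_times):
        times, matrix = _normalize_repetitions(reps, rate)
    else:
        times, matrix = _common_grid(reps, rate)
    return Aggregate(
        times=times,
        mean=matrix.mean(axis=0),
        sd=matrix.std(axis=0, ddof=1),
        n=matrix.shape[0],
        matrix=matrix,
        label=reps.label,
    )


def _pooled_sd(a_sd, a_n, b_sd, b_n) -> np.ndarray:
    return np.sqrt(((a_n - 1) * a_sd**2 + (b_n - 1) * b_sd**2) / (a_n + b_n - 2))


def _trace(mean_a, mean_b, sd_pool) -> np.ndarray:
    diff = np.abs(mean_a - mean_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = diff / sd_pool
    # zero pooled SD: zero difference is "no evidence", nonzero difference
    # is infinitely strong evidence
    zero_sd = sd_pool <= 0
    z[zero_sd & (diff <= 1e-12)] = 0.0
    z[zero_sd & (diff > 1e-12)] = np.inf
    return z


def _first_run_start(exceed: np.ndarray, r: int) -> int | None:
    """Index of the first sample opening a run of >= r consecutive True."""
    if r == 1:
        hits = np.flatnonzero(exceed)
        return int(hits[0]) if hits.size else None
    ok = exceed.astype(int)
    window = np.convolve(ok, np.ones(r, dtype=int), mode="valid")
    hits = np.flatnonzero(window == r)
    return int(hits[0]) if hits.size else None


def _detect(times, mean_a, sd_a, n_a, mean_b, sd_b, n_b, cfg) -> tuple[float | None, np.ndarray]:
    z = _trace(mean_a, mean_b, _pooled_sd(sd_a, n_a, sd_b, n_b))
    idx = _first_run_start(z >= cfg.threshold_k, cfg.run_length_r)
    return (float(times[idx]) if idx is not None else None), z


def _boot_stats(matrix: np.ndarray, idx: np.ndarray):
    """Mean and SD over rows selected (with replacement) by ``idx``: (B, n) draws."""
    draws = matrix[idx]  # (B, n, T)
    return draws.mean(axis=1), draws.std(axis=1, ddof=1)


def estimate_divergence_point(
    a: Aggregate,
    b: Aggregate,
    cfg: DivergenceConfig = DivergenceConfig(),
    compute_ci: bool = True,
) -> DivergenceResult:
    """Earliest time the two mean trajectories separate beyond noise.

    Returns ``t_div = None`` when no qualifying run exists.  The bootstrap
    resamples repetitions within each condition; the CI is the percentile
    interval of the detected bootstrap divergence times.  ``compute_ci=False``
    skips the bootstrap (useful in large simulation loops).
    """
    if len(a.times) != len(b.times) or not np.allclose(a.times, b.times, atol=1e-9):
        raise InvalidInputError("aggregates must share a common time base")
    t_div, z = _detect(a.times, a.mean, a.sd, a.n, b.mean, b.sd, b.n, cfg)
    ci_low = ci_high = None
    frac = 0.0
    if compute_ci and t_div is not None and a.matrix is not None and b.matrix is not None:
        rng = np.random.default_rng(cfg.seed)
        B = cfg.n_bootstrap
        ma, sa = _boot_stats(a.matrix, rng.integers(0, a.n, size=(B, a.n)))
        mb, sb = _boot_stats(b.matrix, rng.integers(0, b.n, size=(B, b.n)))
        boots = []
        for i in range(B):
            t_i, _ = _detect(a.times, ma[i], sa[i], a.n, mb[i], sb[i], b.n, cfg)
            if t_i is not None:
                boots.append(t_i)
        frac = len(boots) / B
        if boots:
            alpha = 100.0 * (1.0 - cfg.ci_level) / 2.0
            ci_low, ci_high = np.percentile(boots, [alpha, 100.0 - alpha])
            ci_low, ci_high = float(ci_low), float(ci_high)
    return DivergenceResult(
        t_div=t_div, ci_low=ci_low, ci_high=ci_high, trace=z, times=a.times,
        bootstrap_detected=frac,
    )


def synchrony_test(
    control: RepetitionSet,
    c_contrast: RepetitionSet,
    v_contrast: RepetitionSet,
    cfg: DivergenceConfig = DivergenceConfig(),
    rate: float | None = None,
) -> SynchronyResult:
    """Contrast the divergence times of the two minimal pairs.

    The C-pair is control vs ``c_contrast`` and the V-pair is control vs
    ``v_contrast``; ``delta_t = t_div(C-pair) - t_div(V-pair)``.  Synchrony
    of the consonant and vowel onsets is supported when the bootstrap CI of
    ``delta_t`` covers 0.  If either pair yields no detection the result is
    flagged undetermined.
    """
    agg_ctl = aggregate(control, rate)
    agg_c = aggregate(c_contrast, rate)
    agg_v = aggregate(v_contrast, rate)
    n_common = min(len(agg_ctl.times), len(agg_c.times), len(agg_v.times))

    def clip(agg: Aggregate) -> Aggregate:
        return Aggregate(
            times=agg.times[:n_common],
            mean=agg.mean[:n_common],
            sd=agg.sd[:n_common],
            n=agg.n,
            matrix=agg.matrix[:, :n_common],
            label=agg.label,
        )

    agg_ctl, agg_c, agg_v = clip(agg_ctl), clip(agg_c), clip(agg_v)
    times = agg_ctl.times
    t_c, _ = _detect(times, agg_ctl.mean, agg_ctl.sd, agg_ctl.n, agg_c.mean, agg_c.sd, agg_c.n, cfg)
    t_v, _ = _detect(times, agg_ctl.mean, agg_ctl.sd, agg_ctl.n, agg_v.mean, agg_v.sd, agg_v.n, cfg)
    if t_c is None or t_v is None:
        return SynchronyResult(None, None, None, t_c, t_v, determined=False)

    rng = np.random.default_rng(cfg.seed)
    B = cfg.n_bootstrap
    m_ctl, s_ctl = _boot_stats(agg_ctl.matrix, rng.integers(0, agg_ctl.n, size=(B, agg_ctl.n)))
    m_c, s_c = _boot_stats(agg_c.matrix, rng.integers(0, agg_c.n, size=(B, agg_c.n)))
    m_v, s_v = _boot_stats(agg_v.matrix, rng.integers(0, agg_v.n, size=(B, agg_v.n)))
    deltas = []
    for i in range(B):
        tc_i, _ = _detect(times, m_ctl[i], s_ctl[i], agg_ctl.n, m_c[i], s_c[i], agg_c.n, cfg)
        tv_i, _ = _detect(times, m_ctl[i], s_ctl[i], agg_ctl.n, m_v[i], s_v[i], agg_v.n, cfg)
        if tc_i is not None and tv_i is not None:
            deltas.append(tc_i - tv_i)
    ci_low = ci_high = None
    if deltas:
        alpha = 100.0 * (1.0 - cfg.ci_level) / 2.0
        lo, hi = np.percentile(deltas, [alpha, 100.0 - alpha])
        ci_low, ci_high = float(lo), float(hi)
    return SynchronyResult(
        delta_t=t_c - t_v, ci_low=ci_low, ci_high=ci_high, t_div_c=t_c, t_div_v=t_v,
    )
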