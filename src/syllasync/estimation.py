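"""Analysis-by-synthesis target estimation.

Recovers underlying (slope, height, strength) targets from an observed
trajectory by repeatedly synthesizing candidate trajectories (sequential
intervals with analytic state transfer) and minimizing the squared error
with bounded nonlinear least squares, multi-started over the strength
parameter — the only source of serious non-convexity.

The initial dynamic state of the first interval is not observable from a
"previous interval", so it is seeded from a short quadratic regression on
the first 25 ms of data and then refined jointly with the targets.

``alignment_mode="free"`` additionally fits one boundary offset per internal
boundary (within a search window), adding one degree of freedom per
boundary; ``"fixed"`` keeps the given boundaries, operationalizing
onset-synchronized learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError, InvalidInputError
from .qta import DynamicState, TargetSpec, evaluate_positions, evaluate_state, solve_coefficients
from .sequencing import Trajectory

__all__ = [
    "FitConfig",
    "FitResult",
    "fit_interval_targets",
    "fit_alignment",
    "alignment_learning_experiment",
    "synthesize_piecewise",
]

_INIT_WINDOW = 0.025  # s of data used to seed the first interval's state


@dataclass(frozen=True)
class FitConfig:
    """Bounds, multi-start and alignment settings for target fitting."""

    slope_bounds: tuple[float, float] = (-500.0, 500.0)
    height_bounds: tuple[float, float] = (-1e4, 1e4)
    strength_bounds: tuple[float, float] = (1.0, 200.0)
    n_starts: int = 3
    max_nfev: int | None = None
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-12
    seed: int = 0
    alignment_mode: str = "fixed"  # fixed | free
    boundary_window: float = 0.05  # s, free mode only

    def __post_init__(self):
        if self.strength_bounds[0] <= 0:
            raise InvalidInputError("strength lower bound must be > 0")
        for lo, hi in (self.slope_bounds, self.height_bounds, self.strength_bounds):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise InvalidInputError("bounds must be finite with lo < hi")
        if self.alignment_mode not in {"fixed", "free"}:
            raise InvalidInputError(f"unknown alignment mode {self.alignment_mode!r}")

    def lambda_starts(self) -> np.ndarray:
        lo = max(5.0, self.strength_bounds[0])
        hi = min(80.0, self.strength_bounds[1])
        return np.geomspace(lo, hi, self.n_starts)


@dataclass(frozen=True)
class FitResult:
    targets: tuple[TargetSpec, ...]
    init_state: DynamicState
    boundary_offsets: tuple[float, ...]
    rmse: float
    n_evaluations: int
    converged: bool
    strength_identifiable: tuple[bool, ...] = ()
    boundaries: tuple[float, ...] = ()

    def __post_init__(self):
        if self.rmse < 0:
            raise InvalidInputError("rmse must be >= 0")


def synthesize_piecewise(
    times: np.ndarray,
    boundaries: np.ndarray,
    params: np.ndarray,  # (n_intervals, 3): slope, height, strength
    init: DynamicState,
) -> np.ndarray:
    """Evaluate the sequential model at arbitrary sample times.

    ``boundaries`` includes both utterance edges; boundary samples belong to
    the following interval.
    """
    values = np.empty_like(times)
    state = init
    n = len(boundaries) - 1
    for k in range(n):
        lo, hi = boundaries[k], boundaries[k + 1]
        dur = hi - lo
        target = TargetSpec(params[k, 0], params[k, 1], params[k, 2], dur)
        coeffs = solve_coefficients(target, state)
        if k < n - 1:
            sel = (times >= lo - 1e-12) & (times < hi - 1e-12)
        else:
            sel = (times >= lo - 1e-12) & (times <= hi + 1e-12)
        if sel.any():
            values[sel] = evaluate_positions(target, coeffs, np.clip(times[sel] - lo, 0.0, None))
        state = evaluate_state(target, coeffs, dur)
    return values


def _seed_initial_state(times: np.ndarray, values: np.ndarray) -> DynamicState:
    t0 = times[0]
    sel = times <= t0 + _INIT_WINDOW
    if sel.sum() < 3:
        sel = np.zeros_like(sel)
        sel[: min(3, len(times))] = True
    coef = np.polyfit(times[sel] - t0, values[sel], min(2, sel.sum() - 1))
    poly = np.poly1d(coef)
    return DynamicState(float(poly(0.0)), float(poly.deriv(1)(0.0)) if len(coef) > 1 else 0.0,
                        2.0 * float(coef[0]) if len(coef) == 3 else 0.0)


def _line_seeds(times, values, bounds_list):
    """Per-interval (slope, height) seeds from straight-line fits."""
    seeds = []
    for lo, hi in zip(bounds_list[:-1], bounds_list[1:]):
        sel = (times >= lo - 1e-12) & (times <= hi + 1e-12)
        tt, vv = times[sel], values[sel]
        if len(tt) >= 2:
            m, b = np.polyfit(tt - lo, vv, 1)
        else:
            m, b = 0.0, float(vv[0]) if len(vv) else 0.0
        seeds.append((float(m), float(b)))
    return seeds


def fit_interval_targets(
    traj: Trajectory, boundaries, cfg: FitConfig = FitConfig()
) -> FitResult:
    """Fit (slope, height, strength) per interval by analysis-by-synthesis.

    ``boundaries`` are the global times of all interval edges, including the
    utterance start and end.  Samples with NaN values are treated as masked:
    synthesis is continuous but the error is computed on unmasked samples
    only.  Raises :class:`FitError` if every start fails.
    """
    boundaries = np.asarray(boundaries, dtype=float)
    if len(boundaries) < 2 or not np.all(np.diff(boundaries) > 0):
        raise InvalidInputError("boundaries must be increasing with >= 2 edges")
    times, values = traj.times, traj.values
    if boundaries[0] < times[0] - 1e-9 or boundaries[-1] > times[-1] + 1e-9:
        raise InvalidInputError("boundaries outside the trajectory")
    mask = np.isfinite(values)
    n_int = len(boundaries) - 1
    for k in range(n_int):
        sel = mask & (times >= boundaries[k] - 1e-12) & (times <= boundaries[k + 1] + 1e-12)
        if sel.sum() < 3:
            raise InvalidInputError(f"interval {k} has fewer than 3 usable samples")

    free = cfg.alignment_mode == "free"
    if free:
        durs = np.diff(boundaries)
        if n_int > 1 and cfg.boundary_window >= min(durs) / 2:
            raise InvalidInputError(
                f"boundary window {cfg.boundary_window} exceeds half the shortest interval"
            )

    init_seed = _seed_initial_state(times, values)
    filled = np.where(mask, values, np.interp(times, times[mask], values[mask]))
    line_seeds = _line_seeds(times, filled, boundaries)

    m_lo, m_hi = cfg.slope_bounds
    b_lo, b_hi = cfg.height_bounds
    l_lo, l_hi = cfg.strength_bounds
    n_off = n_int - 1 if free else 0

    def unpack(x):
        state = DynamicState(x[0], x[1], x[2])
        p = x[3 : 3 + 3 * n_int].reshape(n_int, 3)
        offsets = x[3 + 3 * n_int :]
        edges = boundaries.copy()
        if n_off:
            edges[1:-1] = boundaries[1:-1] + offsets
        return state, p, edges

    def residuals(x):
        state, p, edges = unpack(x)
        model = synthesize_piecewise(times, edges, p, state)
        return (model - values)[mask]

    lower = [-np.inf, -np.inf, -np.inf] + [m_lo, b_lo, l_lo] * n_int + [-cfg.boundary_window] * n_off
    upper = [np.inf, np.inf, np.inf] + [m_hi, b_hi, l_hi] * n_int + [cfg.boundary_window] * n_off

    best = None
    total_nfev = 0
    any_success = False
    for lam0 in cfg.lambda_starts():
        lam0 = float(np.clip(lam0, l_lo, l_hi))
        x0 = [init_seed.position, init_seed.velocity, init_seed.acceleration]
        for m, b in line_seeds:
            x0 += [float(np.clip(m, m_lo, m_hi)), float(np.clip(b, b_lo, b_hi)), lam0]
        x0 += [0.0] * n_off
        try:
            sol = least_squares(
                residuals, x0, bounds=(lower, upper),
                xtol=cfg.xtol, ftol=cfg.ftol, gtol=cfg.gtol,
                max_nfev=cfg.max_nfev,
            )
        except Exception:
            continue
        total_nfev += sol.nfev
        any_success = True
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-20:
            break
    if not any_success or best is None:
        raise FitError("all optimizer starts failed")

    state, p, edges = unpack(best.x)
    rmse = float(np.sqrt(np.mean(best.fun**2)))
    targets = tuple(
        TargetSpec(p[k, 0], p[k, 1], p[k, 2], edges[k + 1] - edges[k]) for k in range(n_int)
    )
    identifiable = _strength_identifiability(times, values, mask, edges, p, state, best.cost)
    offsets = tuple(float(o) for o in (edges[1:-1] - boundaries[1:-1])) if n_off else ()
    return FitResult(
        targets=targets,
        init_state=state,
        boundary_offsets=offsets,
        rmse=rmse,
        n_evaluations=total_nfev,
        converged=bool(best.success),
        strength_identifiable=identifiable,
        boundaries=tuple(float(e) for e in edges),
    )


def _strength_identifiability(times, values, mask, edges, p, state, best_cost):
    """Flag strength as unidentifiable in intervals where perturbing it barely
    changes the fit (flat profile, e.g. data already on the target line)."""
    flags = []
    denom = max(best_cost, 1e-12) + np.sum(values[mask] ** 2) * 1e-12 + 1e-12
    for k in range(p.shape[0]):
        worst = 0.0
        for factor in (0.5, 2.0):
            q = p.copy()
            q[k, 2] = np.clip(p[k, 2] * factor, 1e-3, 1e4)
            model = synthesize_piecewise(times, edges, q, state)
            cost = 0.5 * np.sum((model - values)[mask] ** 2)
            worst = max(worst, cost - best_cost)
        flags.append(bool(worst > 1e-6 * denom + 1e-12))
    return tuple(flags)


def fit_alignment(
    traj: Trajectory, nominal_boundaries, cfg: FitConfig = FitConfig()
) -> FitResult:
    """Fit targets with fixed or free boundary alignment per ``cfg``."""
    return fit_interval_targets(traj, nominal_boundaries, cfg)


def _parameter_error(fit: FitResult, truth: list[TargetSpec]) -> float:
    """RMS error between fitted and true target lines, measured at both ends
    of each interval (strength-free, so the metric is always identifiable)."""
    errs = []
    for est, tru in zip(fit.targets, truth):
        errs.append(est.height - tru.height)
        errs.append((est.height + est.slope * tru.duration) - (tru.height + tru.slope * tru.duration))
    return float(np.sqrt(np.mean(np.square(errs))))


def alignment_learning_experiment(
    n_corpora: int = 50,
    n_syllables: int = 3,
    syllable_duration: float = 0.25,
    sigma: float = 0.1,
    rate: float = 200.0,
    budget: int = 400,
    boundary_window: float = 0.04,
    seed: int = 0,
    tones: dict[str, tuple[float, float, float]] | None = None,
    tone_pattern: tuple[str, ...] | None = ("H", "R", "L"),
) -> pd.DataFrame:
    """Synchronized-vs-flexible alignment learning at matched optimizer budgets.

    Generates tone corpora with targets synchronized to syllable boundaries,
    fits each contour in ``fixed`` and ``free`` alignment mode with the same
    evaluation budget, and reports per-mode residual RMSE, target-parameter
    recovery error, and evaluations used, as a tidy table.
    """
    from .syndata import NoiseConfig, generate_tone_corpus

    rows = []
    for c in range(n_corpora):
        pattern = list(tone_pattern)[:n_syllables] if tone_pattern else None
        if pattern is not None and len(pattern) < n_syllables:
            pattern = (pattern * n_syllables)[:n_syllables]
        corpus = generate_tone_corpus(
            n_sentences=1,
            n_syllables=n_syllables,
            syllable_duration=syllable_duration,
            noise=NoiseConfig(sigma=sigma, seed=seed + 1000 + c),
            rate=rate,
            tones=tones,
            tone_pattern=pattern,
        )
        traj, truth = corpus[0]
        boundaries = np.concatenate(([traj.times[0]], traj.boundary_times, [traj.times[-1]]))
        for mode in ("fixed", "free"):
            cfg = FitConfig(
                alignment_mode=mode,
                boundary_window=boundary_window,
                max_nfev=budget,
                n_starts=3,
                seed=seed,
            )
            fit = fit_interval_targets(traj, boundaries, cfg)
            rows.append(
                {
                    "corpus": c,
                    "mode": mode,
                    "rmse": fit.rmse,
                    "param_error": _parameter_error(fit, truth["targets"]),
                    "n_evaluations": fit.n_evaluations,
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)
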