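"""Nonlinear least-squares fitting of mortality trajectories and model selection.

Each strain's mortality trajectory (%dead at days 0, 1, 7, 14, 21, 28 after
nitrogen removal) is fitted with every applicable model from
:mod:`quiescreen.models` by trust-region least squares with a deterministic
multi-start grid.  The optimal model is then chosen by two criteria:

1. highest goodness-of-fit z score (r² standardized across the converged
   candidate fits — a monotone transform of r², recorded per fit), among
2. models whose fitted curve reaches 99% mortality within the extrapolation
   horizon (so that T_99 is a finite prediction).

If no candidate reaches 99% within the horizon, the best-r² fit is returned
with all threshold times censored at the horizon.  Ties in r² (which occur
exactly when one model family nests another, e.g. exp2p inside exp3p) are
broken by parsimony (fewer parameters) and then by the registry order of
:data:`quiescreen.models.MODEL_ORDER`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .models import MODELS, MODEL_ORDER, ThresholdTime, evaluate_model, threshold_time

#: r² difference below which two fits are considered tied for selection.
R2_TIE_TOL = 1e-9

#: Mortality levels (in %) whose threshold times are attached to every fit.
THRESHOLD_LEVELS = (25.0, 50.0, 99.0)


class UnfittableStrainError(RuntimeError):
    """No kinetic model converged on a strain's trajectory."""


@dataclass
class ModelFit:
    """Result of fitting one kinetic model to one mortality trajectory."""

    model_id: str
    params: Tuple[float, ...]
    rss: float
    r2: float
    converged: bool
    n_obs: int
    t25: Optional[ThresholdTime] = None
    t50: Optional[ThresholdTime] = None
    t99: Optional[ThresholdTime] = None
    fit_zscore: float = float("nan")
    message: str = ""

    @property
    def arity(self) -> int:
        return MODELS[self.model_id].arity


def _log_slope(t: np.ndarray, y: np.ndarray) -> float:
    pos = y > 0
    if pos.sum() >= 2:
        return float(np.polyfit(t[pos], np.log(y[pos]), 1)[0])
    return 0.1


def _t_half_guess(t: np.ndarray, y: np.ndarray) -> float:
    ymax = max(float(y.max()), 1e-6)
    return float(t[np.argmin(np.abs(y - ymax / 2.0))])


def _starts(model_id: str, t: np.ndarray, y: np.ndarray) -> List[Tuple[float, ...]]:
    """Eight deterministic starting points derived from the data range."""
    y0 = float(y[0])
    ymin, ymax, ymean = float(y.min()), float(y.max()), float(y.mean())
    r = abs(_log_slope(t, y))
    r = min(max(r, 1e-3), 4.0)
    thalf = _t_half_guess(t, y)
    tmid = float((t[0] + t[-1]) / 2.0)
    amax = min(max(ymax * 1.05, 1.0), 105.0)

    if model_id == "exp2p":
        return [(a, b) for a in (max(y0, 0.5), max(ymean, 0.5))
                for b in (r, r / 2.0, 0.05, 0.2)]
    if model_id == "exp3p":
        grow = [(max(y0 * 0.5, 0.1), max(y0 * 0.5, 0.5), rr)
                for rr in (0.05, 0.15, 0.3)]
        sat = [(amax, -max(ymax - y0, 0.5), -rr) for rr in (0.05, 0.15, 0.3)]
        flat = [(max(ymean, 0.1), 0.1, 0.01), (max(y0, 0.1), 0.1, -0.01)]
        return grow + sat + flat
    if model_id == "logistic3p":
        return [(a, b, c) for a in (amax, 100.0) for b in (0.15, 0.5)
                for c in (thalf, tmid)]
    if model_id == "gompertz3p":
        return [(a, b, c) for a in (amax, 100.0) for b in (0.1, 0.4)
                for c in (thalf, tmid)]
    if model_id == "mech_growth":
        b0 = min(max(1.0 - y0 / amax, 0.05), 1.0)
        return [(a, b, c) for a in (amax, 100.0) for b in (b0, 0.9)
                for c in (0.05, 0.3)]
    if model_id == "probit4p":
        d0 = max(ymin, 0.0)
        return [(a, b, c, d0) for a in (amax, 100.0) for b in (0.1, 0.3)
                for c in (thalf, tmid)]
    if model_id == "logistic5p":
        d0 = max(ymin, 0.0)
        return [(a, b, thalf, d0, e) for a in (amax, 100.0) for b in (0.2, 0.5)
                for e in (1.0, 2.0)]
    raise ValueError(f"unknown model_id {model_id!r}")


def _clip_to_bounds(x0, lower, upper):
    return tuple(min(max(v, lo + 1e-12), up - 1e-12)
                 for v, lo, up in zip(x0, lower, upper))


def _r2(rss: float, y: np.ndarray) -> float:
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        return 1.0 if rss <= 1e-10 else 0.0
    return 1.0 - rss / tss


def fit_model(model_id: str, days: Sequence[float], mortality: Sequence[float],
              horizon: float = 1000.0, n_starts: int = 8,
              x0: Optional[Sequence[float]] = None) -> ModelFit:
    """Fit one kinetic model by multi-start trust-region least squares.

    A model of arity p needs at least p+1 usable observations (3 for the
    two-parameter exponential, 4 for the 3P models, 5 for 4P, 6 for 5P);
    with fewer the fit is returned non-converged with a reason and never
    raises.  ``x0``, when given, is used as an extra (first) start — the
    bootstrap refits warm-start from the original parameters this way.
    """
    t = np.asarray(days, dtype=float)
    y = np.asarray(mortality, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("days and mortality must be 1-D and equally long")
    if np.any(np.diff(t) <= 0):
        raise ValueError("days must be strictly increasing")
    model = MODELS[model_id]
    if len(t) < model.arity + 1:
        return ModelFit(model_id, (), np.inf, -np.inf, False, len(t),
                        message=f"needs >= {model.arity + 1} observations, "
                                f"got {len(t)}")

    def resid(p):
        return model.func(t, *p) - y

    starts = _starts(model_id, t, y)[:n_starts]
    if x0 is not None:
        starts = [tuple(x0)] + starts
    best = None
    for s in starts:
        try:
            res = least_squares(
                resid, _clip_to_bounds(s, model.lower, model.upper),
                bounds=(model.lower, model.upper), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=4000)
        except (ValueError, FloatingPointError):  # ill-conditioned start
            continue
        rss = float(np.sum(res.fun ** 2))
        if np.isfinite(rss) and (best is None or rss < best[0]):
            best = (rss, tuple(float(p) for p in res.x))
    if best is None:
        return ModelFit(model_id, (), np.inf, -np.inf, False, len(t),
                        message="no start converged")
    rss, params = best
    fit = ModelFit(model_id, params, rss, _r2(rss, y), True, len(t))
    fit.t25, fit.t50, fit.t99 = (
        threshold_time(model_id, params, lev, horizon) for lev in THRESHOLD_LEVELS)
    return fit


def fit_all_models(days, mortality, horizon: float = 1000.0,
                   n_starts: int = 8,
                   model_ids: Sequence[str] = MODEL_ORDER) -> List[ModelFit]:
    """Fit every candidate model to one trajectory."""
    return [fit_model(m, days, mortality, horizon=horizon, n_starts=n_starts)
            for m in model_ids]


def select_model(fits: Sequence[ModelFit], horizon: float = 1000.0) -> ModelFit:
    """Pick the optimal model by the two-criterion rule.

    Among converged fits, r² is standardized to a z score across candidates;
    the fit with the highest z score *and* a finite T_99 within the horizon
    wins.  When no fit reaches 99% within the horizon, the best-r² fit is
    returned with t25/t50/t99 censored at the horizon.  Raises
    :class:`UnfittableStrainError` when nothing converged.
    """
    conv = [f for f in fits if f.converged]
    if not conv:
        raise UnfittableStrainError(
            "no converged fit among candidates: "
            + "; ".join(f"{f.model_id}: {f.message}" for f in fits))
    r2s = np.array([f.r2 for f in conv])
    sd = float(r2s.std())
    zs = np.zeros(len(conv)) if sd < 1e-15 else (r2s - r2s.mean()) / sd
    conv = [dataclasses.replace(f, fit_zscore=float(z)) for f, z in zip(conv, zs)]

    order = {m: i for i, m in enumerate(MODEL_ORDER)}

    def tie_key(f: ModelFit):
        return (f.arity, order[f.model_id])

    eligible = [f for f in conv if f.t99 is not None and not f.t99.censored]
    if eligible:
        best_r2 = max(f.r2 for f in eligible)
        ties = [f for f in eligible if f.r2 >= best_r2 - R2_TIE_TOL]
        return min(ties, key=tie_key)

    best_r2 = max(f.r2 for f in conv)
    ties = [f for f in conv if f.r2 >= best_r2 - R2_TIE_TOL]
    best = min(ties, key=tie_key)
    censored = ThresholdTime(horizon, True, horizon)
    return dataclasses.replace(best, t25=censored, t50=censored, t99=censored)


@dataclass
class ConfidenceInterval:
    """Percentile bootstrap interval for a threshold time."""

    low: float
    high: float
    reliable: bool
    n_converged: int
    n_boot: int


def halflife_confidence_interval(fit: ModelFit, days, mortality,
                                 level: float = 50.0, n_boot: int = 200,
                                 seed: int = 0,
                                 horizon: float = 1000.0) -> ConfidenceInterval:
    """95% CI for the time to ``level``% mortality by residual resampling.

    Residuals of the selected fit are resampled with replacement onto the
    fitted curve; each pseudo-trajectory is refitted (warm-started from the
    original parameters) and the threshold time recomputed.  The interval is
    the 2.5–97.5 percentile of the uncensored refit times and is flagged
    unreliable when fewer than half the refits converge.
    """
    if not fit.converged:
        raise ValueError("confidence interval requires a converged fit")
    t = np.asarray(days, dtype=float)
    y = np.asarray(mortality, dtype=float)
    pred = np.asarray(evaluate_model(fit.model_id, fit.params, t), dtype=float)
    resid = y - pred
    rng = np.random.default_rng(seed)
    times: List[float] = []
    n_conv = 0
    for _ in range(n_boot):
        yb = pred + rng.choice(resid, size=resid.size, replace=True)
        refit = fit_model(fit.model_id, t, yb, horizon=horizon, n_starts=2,
                          x0=fit.params)
        if refit.converged:
            n_conv += 1
            tt = threshold_time(refit.model_id, refit.params, level, horizon)
            if not tt.censored:
                times.append(tt.value)
    if times:
        low, high = (float(v) for v in np.percentile(times, [2.5, 97.5]))
    else:
        low = high = float("nan")
    return ConfidenceInterval(low, high, n_conv >= 0.5 * n_boot, n_conv, n_boot)
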