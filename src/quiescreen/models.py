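"""Functional forms of the seven mortality-kinetics models.

Mortality of a gene-deletion strain during nitrogen-starvation quiescence is
summarized as %dead cells at a handful of sampling days. Seven candidate
nonlinear models describe how that percentage evolves with time ``t`` (days):

======================  =============================================  ======
model_id                f(t)                                           params
======================  =============================================  ======
``logistic3p``          a / (1 + exp(-b (t - c)))                      a,b,c
``mech_growth``         a (1 - b exp(-c t))                            a,b,c
``gompertz3p``          a exp(-exp(-b (t - c)))                        a,b,c
``logistic5p``          d + (a - d) / (1 + exp(-b (t - c)))**e         a,b,c,d,e
``exp3p``               a + b exp(c t)                                 a,b,c
``exp2p``               a exp(b t)                                     a,b
``probit4p``            d + (a - d) Phi(b (t - c))                     a,b,c,d
======================  =============================================  ======

``Phi`` is the standard normal CDF.  ``a`` (and ``d``) are percentage
asymptotes/offsets, ``b``/``c`` rate and location parameters in 1/day and
day.  The probit model uses a linear time argument so that day 0 (always
observed) is in its domain.

Threshold times ``T_1/4``, ``T_1/2`` and ``T_99`` are the earliest days at
which a fitted curve reaches 25%, 50% and 99% mortality; curves that never
reach a level within the extrapolation horizon are censored at the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr


@dataclass(frozen=True)
class ModelDef:
    """One kinetic model: identifier, arity, parameter names and callable."""

    model_id: str
    arity: int
    param_names: Tuple[str, ...]
    func: Callable[..., np.ndarray]
    #: box constraints used by the fitter, (lower, upper) per parameter
    lower: Tuple[float, ...]
    upper: Tuple[float, ...]


def _logistic3p(t, a, b, c):
    return a / (1.0 + np.exp(-b * (t - c)))


def _mech_growth(t, a, b, c):
    return a * (1.0 - b * np.exp(-c * t))


def _gompertz3p(t, a, b, c):
    return a * np.exp(-np.exp(-b * (t - c)))


def _logistic5p(t, a, b, c, d, e):
    return d + (a - d) / (1.0 + np.exp(-b * (t - c))) ** e


def _exp3p(t, a, b, c):
    return a + b * np.exp(c * t)


def _exp2p(t, a, b):
    return a * np.exp(b * t)


def _probit4p(t, a, b, c, d):
    return d + (a - d) * ndtr(b * (t - c))


#: Registry in the canonical listing order; this order is also the final
#: tie-break in model selection (see :func:`quiescreen.fitting.select_model`).
MODELS: Dict[str, ModelDef] = {
    m.model_id: m
    for m in (
        ModelDef("logistic3p", 3, ("a", "b", "c"), _logistic3p,
                 (1e-8, -5.0, -1000.0), (105.0, 5.0, 2000.0)),
        ModelDef("mech_growth", 3, ("a", "b", "c"), _mech_growth,
                 (1e-8, -2.0, -5.0), (105.0, 2.0, 5.0)),
        ModelDef("gompertz3p", 3, ("a", "b", "c"), _gompertz3p,
                 (1e-8, -5.0, -1000.0), (105.0, 5.0, 2000.0)),
        ModelDef("logistic5p", 5, ("a", "b", "c", "d", "e"), _logistic5p,
                 (0.0, -5.0, -1000.0, 0.0, 0.05), (105.0, 5.0, 2000.0, 105.0, 20.0)),
        ModelDef("exp3p", 3, ("a", "b", "c"), _exp3p,
                 (0.0, -210.0, -5.0), (105.0, 210.0, 5.0)),
        ModelDef("exp2p", 2, ("a", "b"), _exp2p,
                 (1e-8, -5.0), (105.0, 5.0)),
        ModelDef("probit4p", 4, ("a", "b", "c", "d"), _probit4p,
                 (0.0, -5.0, -1000.0, 0.0), (105.0, 5.0, 2000.0, 105.0)),
    )
}

MODEL_ORDER: Tuple[str, ...] = tuple(MODELS)


def evaluate_model(model_id: str, params, t):
    """Evaluate a kinetic model at time(s) ``t`` (days).

    Parameters
    ----------
    model_id : str
        One of :data:`MODEL_ORDER`.
    params : sequence of float
        Ordered parameters; length must equal the model arity.
    t : float or array-like
        Days, ``t >= 0`` for scientific use (the function itself is defined
        for any real ``t``).

    Returns
    -------
    float or ndarray
        Predicted mortality in percent (not clamped).
    """
    if model_id not in MODELS:
        raise ValueError(f"unknown model_id {model_id!r}; known: {MODEL_ORDER}")
    model = MODELS[model_id]
    params = tuple(float(p) for p in params)
    if len(params) != model.arity:
        raise ValueError(
            f"{model_id} takes {model.arity} parameters, got {len(params)}"
        )
    t = np.asarray(t, dtype=float)
    out = model.func(t, *params)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ThresholdTime:
    """Earliest day a curve reaches a mortality level, or censored at horizon."""

    value: float
    censored: bool
    horizon: float

    def __float__(self) -> float:  # convenience for arithmetic on results
        return self.value


def _exp2p_threshold(a: float, b: float, level: float,
                     horizon: float) -> ThresholdTime:
    # closed form: a e^{bt} = level  =>  t = ln(level/a)/b
    if a >= level:
        return ThresholdTime(0.0, False, horizon)
    if b <= 0 or a <= 0:
        return ThresholdTime(horizon, True, horizon)
    t = np.log(level / a) / b
    if t > horizon:
        return ThresholdTime(horizon, True, horizon)
    return ThresholdTime(float(t), False, horizon)


def threshold_time(model_id: str, params, level: float,
                   horizon: float = 1000.0) -> ThresholdTime:
    """Smallest ``t`` in [0, horizon] with model prediction >= ``level``.

    Uses the closed form for ``exp2p``; otherwise a dense grid bracket
    followed by bisection (``brentq``) to 1e-6 day.  Returns a censored
    marker carrying the horizon when the curve never reaches the level.
    """
    if not 0.0 < level < 100.0:
        raise ValueError(f"level must be in (0, 100), got {level}")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if model_id == "exp2p":
        a, b = (float(p) for p in params)
        return _exp2p_threshold(a, b, level, horizon)

    grid = np.linspace(0.0, horizon, 4097)
    with np.errstate(over="ignore", invalid="ignore"):
        vals = np.asarray(evaluate_model(model_id, params, grid), dtype=float)
    vals = np.nan_to_num(vals, nan=-np.inf, posinf=np.inf, neginf=-np.inf)
    above = vals >= level
    if above[0]:
        return ThresholdTime(0.0, False, horizon)
    if not above.any():
        return ThresholdTime(horizon, True, horizon)
    i = int(np.argmax(above))
    f = lambda t: evaluate_model(model_id, params, t) - level
    with np.errstate(over="ignore", invalid="ignore"):
        t = brentq(f, grid[i - 1], grid[i], xtol=1e-6)
    return ThresholdTime(float(t), False, horizon)
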