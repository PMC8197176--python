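"""RMSE calibration of the ODE model by differential evolution.

The objective pools every calibration point — volumetric growth rates,
intravital per-capita process rates and E:T ratios — into one unweighted
root-mean-square error.  Rates all carry day^-1 units; the dimensionless E:T
points enter the same pool unweighted (an optional per-kind weight exists).
A treatment group's day-3 and day-7 transfer conditions are fitted jointly
with one shared parameter vector: each objective evaluation runs one
simulation per transfer day.

Minimisation uses differential evolution with the current-to-best ("local to
best") mutation strategy, repeated from independent seeded starting
populations; the tumour growth rate g (pre-set from untreated tumours) and
the resistance decay d_r (fixed at 0) are not searched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution
from scipy.stats import qmc

from .model import IntegrationError, ModelParameters, simulate
from .observation import CalibrationPoint, GROWTH, model_predictions

__all__ = ["FitConfig", "FitResult", "rmse_objective", "fit_group", "local_sensitivity"]

logger = logging.getLogger(__name__)

#: parameters searched by default, in vector order
FREE_PARAMS = ("s", "k_e", "k_i", "d_i", "k_r", "k_q", "d_q")

#: RMSE returned when the integrator fails inside the search box
FAILURE_PENALTY = 1.0e6

DEFAULT_BOUNDS = {
    "s": (0.0, 5.0),
    "k_e": (0.0, 50.0),
    "k_i": (0.0, 50.0),
    "d_i": (0.0, 50.0),
    "k_r": (0.0, 50.0),
    "k_q": (0.0, 50.0),
    "d_q": (0.0, 50.0),
    "d_r": (0.0, 50.0),
}


@dataclass(frozen=True)
class FitConfig:
    """Differential-evolution settings.

    Defaults follow the full calibration protocol (population 200 for 500
    generations, 5 repeats, current-to-best strategy); recovery experiments
    use reduced budgets.  F/CR are conventional values for this strategy.
    """

    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    population_size: int = 200
    generations: int = 500
    repeats: int = 5
    strategy: str = "currenttobest1bin"
    mutation: float = 0.8
    recombination: float = 0.9
    seed: int = 0
    fixed: dict = field(default_factory=lambda: {"g": 0.5, "d_r": 0.0})
    free: tuple = FREE_PARAMS
    weights: dict = field(default_factory=dict)   # per-kind residual weights
    seed_points: tuple = ()   # ModelParameters to inject into the start population


def _model_values(
    params: ModelParameters,
    points: list[CalibrationPoint],
) -> np.ndarray:
    """Model-side values matching each point, one simulation per condition.

    Growth points carrying a measurement interval are matched by the model's
    interval log-slope ln(T(t2)/T(t1))/(t2-t1) over the same interval — like
    for like with the data-side finite difference; all other kinds use the
    trajectory values at the point's day.
    """
    out = np.empty(len(points))
    by_td: dict[float, list[int]] = {}
    for i, pt in enumerate(points):
        td = pt.condition[1] if pt.condition[1] is not None else np.inf
        by_td.setdefault(td, []).append(i)

    for td, idx in by_td.items():
        p = params.with_(transfer_day=td) if np.isfinite(td) else params.with_(s=0.0)
        days = {0.0}
        for i in idx:
            pt = points[i]
            if pt.interval is not None:
                days.update(pt.interval)
            days.add(pt.day)
        grid = np.array(sorted(days))
        traj = simulate(p, grid)
        T = {t: v for t, v in zip(traj.times, traj.T)}
        pred_cache: dict[float, dict] = {}
        for i in idx:
            pt = points[i]
            if pt.kind == GROWTH and pt.interval is not None:
                t1, t2 = pt.interval
                v1, v2 = T[t1], T[t2]
                out[i] = np.log(v2 / v1) / (t2 - t1) if v1 > 0 and v2 > 0 else FAILURE_PENALTY
            else:
                if pt.day not in pred_cache:
                    pred_cache[pt.day] = {
                        q.kind: q.value for q in model_predictions(traj, [pt.day])
                    }
                out[i] = pred_cache[pt.day][pt.kind]
    return out


def rmse_objective(
    params: ModelParameters,
    points: list[CalibrationPoint],
    weights: dict | None = None,
) -> float:
    """Unweighted RMSE between data points and matched model predictions.

    One simulation is run per transfer-day condition present among the
    points, all sharing ``params``.  A failed integration returns a large
    finite penalty so a global optimiser can continue past it.
    """
    if not points:
        raise ValueError("no calibration points")
    try:
        pred = _model_values(params, points)
    except IntegrationError as exc:
        logger.info("integration failure at %s: %s", params.to_dict(), exc)
        return FAILURE_PENALTY
    data = np.array([pt.value for pt in points])
    res = pred - data
    if weights:
        w = np.array([weights.get(pt.kind, 1.0) for pt in points])
        res = res * w
    if not np.all(np.isfinite(res)):
        return FAILURE_PENALTY
    return float(np.sqrt(np.mean(res**2)))


@dataclass(frozen=True)
class FitResult:
    """Best parameter set over repeats, plus every repeat's outcome."""

    best_params: ModelParameters
    rmse: float
    per_repeat: tuple        # ((ModelParameters, rmse, seed), ...)
    n_points: int


def _make_params(x: np.ndarray, config: FitConfig) -> ModelParameters:
    d = dict(config.fixed)
    d.update(zip(config.free, x))
    return ModelParameters(**d)


def fit_group(
    points: list[CalibrationPoint],
    config: FitConfig,
    callback=None,
) -> FitResult:
    """Fit one treatment group's free parameters to its calibration points.

    Runs ``config.repeats`` independent differential-evolution searches from
    different seeded Latin-hypercube starting populations and returns the
    best.  The result is deterministic given ``config.seed``.  ``config.seed_points``
    are injected into each starting population (warm start); elitist greedy
    replacement then guarantees the returned objective value never exceeds
    the objective at an injected point.  ``callback(best_x, convergence)``
    is invoked once per generation.
    """
    if not points:
        raise ValueError("empty point set")
    bounds = [config.bounds[name] for name in config.free]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def objective(x: np.ndarray) -> float:
        return rmse_objective(_make_params(x, config), points, config.weights)

    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
             np.random.SeedSequence(config.seed).spawn(config.repeats)]
    per_repeat = []
    for rep_seed in seeds:
        sampler = qmc.LatinHypercube(d=len(bounds), seed=rep_seed)
        init = lo + (hi - lo) * sampler.random(config.population_size)
        for i, sp in enumerate(config.seed_points[: len(init)]):
            init[i] = [getattr(sp, name) for name in config.free]
        result = differential_evolution(
            objective,
            bounds,
            strategy=config.strategy,
            init=init,
            maxiter=config.generations,
            mutation=config.mutation,
            recombination=config.recombination,
            tol=0.0,
            seed=rep_seed,
            polish=False,
            updating="immediate",
            callback=callback,
        )
        per_repeat.append((_make_params(result.x, config), float(result.fun), rep_seed))
        logger.info("repeat seed %d: rmse %.6g", rep_seed, result.fun)

    best_params, best_rmse, _ = min(per_repeat, key=lambda t: t[1])
    return FitResult(
        best_params=best_params,
        rmse=best_rmse,
        per_repeat=tuple(per_repeat),
        n_points=len(points),
    )


def local_sensitivity(
    params: ModelParameters,
    points: list[CalibrationPoint],
    delta: float = 0.2,
    fixed: tuple = ("g", "d_r"),
) -> pd.DataFrame:
    """RMSE change when each parameter is perturbed by +/- ``delta`` (fraction).

    Parameters held fixed during fitting are perturbed too but flagged, so
    the table separates fit sensitivity from pre-set constants.
    """
    base = rmse_objective(params, points)
    rows = []
    for name in ("g", "s", "k_e", "k_i", "d_i", "k_r", "d_r", "k_q", "d_q"):
        value = getattr(params, name)
        rmses = {}
        for sign, label in ((-1.0, "minus"), (+1.0, "plus")):
            perturbed = max(value * (1.0 + sign * delta), 0.0)
            rmses[label] = rmse_objective(params.with_(**{name: perturbed}), points)
        rows.append({
            "parameter": name,
            "value": value,
            "fixed": name in fixed,
            "rmse_base": base,
            "rmse_minus": rmses["minus"],
            "rmse_plus": rmses["plus"],
            "delta_rmse_minus": rmses["minus"] - base,
            "delta_rmse_plus": rmses["plus"] - base,
        })
    return pd.DataFrame(rows)
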