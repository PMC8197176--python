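"""Poisson models for tumour-cell apoptosis counts per imaged position.

The number of tumour-cell apoptosis events counted in one position over its
imaging window is modelled as Poisson.  Two intensity forms are compared:

* linear      — intensity proportional to the number of CTLs in the field,
                mean = lambda * n_ctl * tau       (lambda in CTL^-1 day^-1)
* mass-action — intensity proportional to CTLs x tumour cells,
                mean = lambda * n_ctl * n_tc * tau (lambda in CTL^-1 TC^-1 day^-1)

with tau the imaging duration in days.  Each form is fitted either pooled
(one rate for all positions) or per treatment group (one rate per group),
and the fits are ranked by AIC and BIC.  The Poisson MLE has the closed form
lambda = sum(counts) / sum(exposures).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import poisson

from .observation import HOURS_PER_DAY, IntravitalPosition

__all__ = [
    "PoissonKillFit",
    "fit_poisson_linear",
    "fit_poisson_massaction",
    "compare_models",
    "poisson_band",
]

_POOLED = "__pooled__"


@dataclass(frozen=True)
class PoissonKillFit:
    """A fitted Poisson intensity model for TC apoptosis counts."""

    model: str                    # "linear" | "mass-action"
    grouping: str                 # "pooled" | "per-treatment"
    rates: dict                   # group label (or "pooled") -> MLE rate
    log_likelihood: float
    n_params: int
    n_obs: int
    aic: float
    bic: float
    total_kills: float            # observation-set signature for comparisons

    @property
    def rate(self) -> float:
        """The single fitted rate (pooled fits only)."""
        if len(self.rates) != 1:
            raise ValueError("fit has one rate per treatment; use .rates")
        return next(iter(self.rates.values()))


def _exposures(positions: Sequence[IntravitalPosition], model: str) -> np.ndarray:
    tau = np.array([p.duration for p in positions]) / HOURS_PER_DAY
    e = np.array([p.n_ctl for p in positions], dtype=float) * tau
    if model == "mass-action":
        e *= np.array([p.n_tc for p in positions], dtype=float)
    return e


def _fit(positions: Sequence[IntravitalPosition], model: str, grouping: str) -> PoissonKillFit:
    positions = list(positions)
    if not positions:
        raise ValueError("no positions to fit")
    kills = np.array([p.tc_apoptosis for p in positions], dtype=float)
    expo = _exposures(positions, model)
    if np.any((expo == 0) & (kills > 0)):
        raise ValueError("position with zero exposure but non-zero apoptosis count")

    if grouping == "pooled":
        labels = np.array([_POOLED] * len(positions))
    elif grouping == "per-treatment":
        labels = np.array([p.group if p.group is not None else _POOLED for p in positions])
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    rates: dict[str, float] = {}
    loglik = 0.0
    for lab in dict.fromkeys(labels):          # preserve order
        m = labels == lab
        total_expo = expo[m].sum()
        if total_expo == 0:
            raise ValueError(f"all exposures zero in group {lab!r}")
        lam = kills[m].sum() / total_expo
        rates[lab if lab != _POOLED else "pooled"] = float(lam)
        mu = lam * expo[m]
        # Poisson log-pmf with 0*log(0) = 0 for zero-mean, zero-count cells
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(kills[m] > 0, kills[m] * np.log(mu), 0.0)
        loglik += float(np.sum(term - mu - gammaln(kills[m] + 1.0)))

    k = len(rates)
    n = len(positions)
    return PoissonKillFit(
        model=model,
        grouping=grouping,
        rates=rates,
        log_likelihood=loglik,
        n_params=k,
        n_obs=n,
        aic=2.0 * k - 2.0 * loglik,
        bic=k * np.log(n) - 2.0 * loglik,
        total_kills=float(kills.sum()),
    )


def fit_poisson_linear(
    positions: Sequence[IntravitalPosition], grouping: str = "pooled"
) -> PoissonKillFit:
    """MLE of the linear model: apoptosis mean = lambda * n_ctl * tau.

    The rate is reported in CTL^-1 day^-1.
    """
    return _fit(positions, "linear", grouping)


def fit_poisson_massaction(
    positions: Sequence[IntravitalPosition], grouping: str = "pooled"
) -> PoissonKillFit:
    """MLE of the mass-action model: mean = lambda * n_ctl * n_tc * tau.

    The rate is reported in CTL^-1 TC^-1 day^-1.
    """
    return _fit(positions, "mass-action", grouping)


def compare_models(fits: Iterable[PoissonKillFit]) -> pd.DataFrame:
    """Rank fits of the same observations by AIC (with BIC alongside).

    Raises if the fits were not computed on the same observation set.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    sig = {(f.n_obs, f.total_kills) for f in fits}
    if len(sig) > 1:
        raise ValueError("fits were computed on different observation sets")
    rows = [
        {
            "model": f.model,
            "grouping": f.grouping,
            "n_params": f.n_params,
            "rates": "; ".join(f"{k}={v:.4g}" for k, v in f.rates.items()),
            "log_likelihood": f.log_likelihood,
            "aic": f.aic,
            "bic": f.bic,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].min()
    df["delta_bic"] = df["bic"] - df["bic"].min()
    return df


def poisson_band(
    E_grid: Sequence[float],
    rate: float,
    duration: float = 1.0,
    q: tuple = (0.05, 0.95),
) -> pd.DataFrame:
    """Expected kill counts and exact Poisson quantile band along a CTL grid.

    ``rate`` is the per-CTL kill rate in day^-1 and ``duration`` the imaging
    window in hours, so the expected count at E CTLs is rate*E*duration/24.
    Quantiles are exact Poisson inverse-CDF values (smallest k with
    CDF(k) >= q) — counts are small, so no normal approximation.
    """
    E = np.asarray(E_grid, dtype=float)
    mean = rate * E * (duration / HOURS_PER_DAY)
    lo = poisson.ppf(q[0], mean)
    hi = poisson.ppf(q[1], mean)
    # ppf returns -1 (lo) / 0 for mean == 0; a zero-intensity process is [0, 0]
    lo = np.where(mean > 0, lo, 0.0)
    hi = np.where(mean > 0, hi, 0.0)
    return pd.DataFrame({"n_ctl": E, "expected": mean, "lower": lo, "upper": hi})
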