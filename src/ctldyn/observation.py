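"""Observation model: from raw records to calibration points.

Experimental readouts come in two currencies — serial tumour-volume
measurements per mouse, and intravital two-photon statistics per imaged
position (cell counts plus mitosis/apoptosis event counts over a 1-3 h
window).  Both are reduced to scalar *calibration points* in common units
(day^-1 for rates, dimensionless for the effector:target ratio), the unit of
the RMSE fitting objective.  The same point kinds are extracted from model
trajectories, so data and model meet in one currency:

    CTL killing rate     (TC apoptosis)/(time * CTLs)        | model: k_e
    TC mitosis rate      (TC mitosis)/(time * TCs)           | model: g*T_p/T
    CTL mitosis rate     (CTL mitosis)/(time * CTLs)         | model: I
    CTL apoptosis rate   (CTL apoptosis)/(time * CTLs)       | model: R
    E:T ratio            n_ctl/n_tc                          | model: E/T
    volumetric growth    ln(V2/V1)/(t2-t1) at the midpoint   | model: (1/T)dT/dt
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import Trajectory

__all__ = [
    "GROWTH", "KILLING", "TC_MITOSIS", "CTL_MITOSIS", "CTL_APOPTOSIS", "ET_RATIO",
    "RATE_KINDS", "POINT_KINDS",
    "IntravitalPosition", "MouseRecord", "CalibrationPoint",
    "growth_rate_series", "intravital_rates", "model_predictions",
    "assemble_points", "write_cohort", "read_cohort",
]

GROWTH = "growth_rate"
KILLING = "killing"
TC_MITOSIS = "tc_mitosis"
CTL_MITOSIS = "ctl_mitosis"
CTL_APOPTOSIS = "ctl_apoptosis"
ET_RATIO = "et_ratio"

#: point kinds carrying day^-1 units
RATE_KINDS = (GROWTH, KILLING, TC_MITOSIS, CTL_MITOSIS, CTL_APOPTOSIS)
POINT_KINDS = RATE_KINDS + (ET_RATIO,)

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class IntravitalPosition:
    """One imaged field: counts and event tallies over ``duration`` hours.

    Counts may be non-integral when they are noise-free expected values from
    the synthetic generator; observed data are integers.
    """

    mouse_id: str
    day: float
    duration: float          # hours, 1-3 by design
    n_ctl: float
    n_tc: float
    tc_apoptosis: float = 0.0
    tc_mitosis: float = 0.0
    ctl_apoptosis: float = 0.0
    ctl_mitosis: float = 0.0
    group: str | None = None

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0 h, got {self.duration}")
        for name in ("n_ctl", "n_tc", "tc_apoptosis", "tc_mitosis",
                     "ctl_apoptosis", "ctl_mitosis"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class MouseRecord:
    """One animal: treatment assignment, volume series, imaged positions."""

    mouse_id: str
    group: str                       # e.g. "no-ACT", "ACT-only", "ACT+mAb"
    transfer_day: float | None       # 3, 7 or None (untreated controls)
    volumes: tuple = ()              # ((day, mm3), ...) strictly increasing days
    positions: tuple = ()            # IntravitalPosition, days >= transfer_day

    def __post_init__(self) -> None:
        days = [d for d, _ in self.volumes]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("volume measurement days must be strictly increasing")
        if self.transfer_day is not None:
            for pos in self.positions:
                if pos.day < self.transfer_day:
                    raise ValueError(
                        f"position on day {pos.day} precedes transfer day {self.transfer_day}"
                    )
        object.__setattr__(self, "volumes", tuple((float(d), float(v)) for d, v in self.volumes))
        object.__setattr__(self, "positions", tuple(self.positions))


@dataclass(frozen=True)
class CalibrationPoint:
    """One scalar observation entering the fit.

    ``condition`` tags the treatment condition as (group, transfer_day).
    Volumetric growth points carry the measurement ``interval`` (t1, t2) that
    produced them, so the calibration can compare like for like.
    """

    kind: str
    day: float
    value: float
    condition: tuple = (None, None)
    interval: tuple | None = None
    source: str | None = None        # mouse or position label, bookkeeping only

    def __post_init__(self) -> None:
        if self.kind not in POINT_KINDS:
            raise ValueError(f"unknown point kind {self.kind!r}")
        if not np.isfinite(self.value):
            raise ValueError(f"point value must be finite, got {self.value}")


def growth_rate_series(
    volumes: Sequence[tuple],
    condition: tuple = (None, None),
    source: str | None = None,
) -> list[CalibrationPoint]:
    """Per-interval volumetric growth rates from a (day, mm3) series.

    For each successive pair the estimate is ln(V2/V1)/(t2-t1), displayed at
    the interval midpoint.  Requires at least two strictly positive volumes.
    """
    if len(volumes) < 2:
        raise ValueError("need at least two volume measurements")
    points = []
    for (t1, v1), (t2, v2) in zip(volumes, volumes[1:]):
        if v1 <= 0 or v2 <= 0:
            raise ValueError(f"volumes must be strictly positive, got {v1}, {v2}")
        if t2 <= t1:
            raise ValueError("volume days must be strictly increasing")
        points.append(CalibrationPoint(
            kind=GROWTH,
            day=0.5 * (t1 + t2),
            value=float(np.log(v2 / v1) / (t2 - t1)),
            condition=condition,
            interval=(float(t1), float(t2)),
            source=source,
        ))
    return points


def intravital_rates(
    pos: IntravitalPosition,
    condition: tuple = (None, None),
) -> list[CalibrationPoint]:
    """Per-capita process rates and E:T ratio from one imaged position.

    Rates are events per cell per day (hour^-1 counts scaled by 24).  Rates
    whose denominator count is zero are omitted entirely rather than reported
    as zero: a 0/0 estimate carries no information.  With ``n_ctl = 0`` the
    E:T ratio is still emitted (it is genuinely zero).
    """
    tau_days = pos.duration / HOURS_PER_DAY
    src = f"{pos.mouse_id}" if pos.mouse_id else None

    def pt(kind, value):
        return CalibrationPoint(kind=kind, day=pos.day, value=float(value),
                                condition=condition, source=src)

    points = []
    if pos.n_ctl > 0:
        points.append(pt(KILLING, pos.tc_apoptosis / (tau_days * pos.n_ctl)))
        points.append(pt(CTL_MITOSIS, pos.ctl_mitosis / (tau_days * pos.n_ctl)))
        points.append(pt(CTL_APOPTOSIS, pos.ctl_apoptosis / (tau_days * pos.n_ctl)))
    if pos.n_tc > 0:
        points.append(pt(TC_MITOSIS, pos.tc_mitosis / (tau_days * pos.n_tc)))
        points.append(pt(ET_RATIO, pos.n_ctl / pos.n_tc))
    return points


def model_predictions(
    traj: Trajectory,
    days: Sequence[float],
    condition: tuple = (None, None),
) -> list[CalibrationPoint]:
    """Model-side calibration points at the requested days.

    Emits per day: killing = k_e, TC mitosis = g*T_p/T, CTL mitosis = I,
    CTL apoptosis = R, E:T = E/T, and the instantaneous volumetric growth
    rate (1/T)dT/dt = g*T_p/T - k_e*E/T.  Days must lie inside the
    trajectory span.
    """
    p = traj.params
    points = []
    for day in days:
        st = traj.state_at(day)   # raises outside span
        T = st.T
        frac_p = st.T_p / T if T > 0 else 0.0
        per_capita = st.E / T if T > 0 else 0.0

        def pt(kind, value):
            return CalibrationPoint(kind=kind, day=float(day), value=float(value),
                                    condition=condition)

        points.extend([
            pt(KILLING, p.k_e),
            pt(TC_MITOSIS, p.g * frac_p),
            pt(CTL_MITOSIS, st.I),
            pt(CTL_APOPTOSIS, st.R),
            pt(ET_RATIO, per_capita),
            pt(GROWTH, p.g * frac_p - p.k_e * per_capita),
        ])
    return points


def assemble_points(
    mice: Iterable[MouseRecord],
    aggregate_et: bool = False,
) -> list[CalibrationPoint]:
    """All calibration points of a cohort, tagged with their condition.

    With ``aggregate_et`` the per-position E:T ratios are replaced by their
    per-mouse, per-day means (mirroring per-mouse aggregation of field
    measurements); all other points stay per-position.
    """
    points: list[CalibrationPoint] = []
    for mouse in mice:
        condition = (mouse.group, mouse.transfer_day)
        if len(mouse.volumes) >= 2:
            points.extend(growth_rate_series(mouse.volumes, condition, mouse.mouse_id))
        et_acc: dict[float, list[float]] = {}
        for pos in mouse.positions:
            for pt in intravital_rates(pos, condition):
                if aggregate_et and pt.kind == ET_RATIO:
                    et_acc.setdefault(pt.day, []).append(pt.value)
                else:
                    points.append(pt)
        for day, values in sorted(et_acc.items()):
            points.append(CalibrationPoint(
                kind=ET_RATIO, day=day, value=float(np.mean(values)),
                condition=condition, source=mouse.mouse_id,
            ))
    return points


# ---------------------------------------------------------------------------
# cohort table IO: one row per volume measurement, one row per position

_VOLUME_COLS = ["mouse_id", "group", "transfer_day", "day", "volume_mm3"]
_POSITION_COLS = [
    "mouse_id", "group", "transfer_day", "day", "duration_h",
    "n_ctl", "n_tc", "tc_apoptosis", "tc_mitosis", "ctl_apoptosis", "ctl_mitosis",
]


def write_cohort(mice: Iterable[MouseRecord], volumes_path, positions_path) -> None:
    """Write a cohort to two delimited-text tables (CSV)."""
    vrows, prows = [], []
    for m in mice:
        td = m.transfer_day if m.transfer_day is not None else np.nan
        for day, vol in m.volumes:
            vrows.append([m.mouse_id, m.group, td, day, vol])
        for p in m.positions:
            prows.append([m.mouse_id, m.group, td, p.day, p.duration, p.n_ctl, p.n_tc,
                          p.tc_apoptosis, p.tc_mitosis, p.ctl_apoptosis, p.ctl_mitosis])
    pd.DataFrame(vrows, columns=_VOLUME_COLS).to_csv(volumes_path, index=False)
    pd.DataFrame(prows, columns=_POSITION_COLS).to_csv(positions_path, index=False)


def read_cohort(volumes_path, positions_path=None) -> list[MouseRecord]:
    """Read a cohort from the tables written by :func:`write_cohort`."""
    vdf = pd.read_csv(volumes_path)
    pdf = pd.read_csv(positions_path) if positions_path is not None else pd.DataFrame(columns=_POSITION_COLS)
    mice = []
    for (mouse_id, group), sub in vdf.groupby(["mouse_id", "group"], sort=False):
        td = sub["transfer_day"].iloc[0]
        td = None if pd.isna(td) else float(td)
        sub = sub.sort_values("day")
        psub = pdf[pdf["mouse_id"] == mouse_id]
        positions = tuple(
            IntravitalPosition(
                mouse_id=str(mouse_id), day=float(r.day), duration=float(r.duration_h),
                n_ctl=float(r.n_ctl), n_tc=float(r.n_tc),
                tc_apoptosis=float(r.tc_apoptosis), tc_mitosis=float(r.tc_mitosis),
                ctl_apoptosis=float(r.ctl_apoptosis), ctl_mitosis=float(r.ctl_mitosis),
                group=str(group),
            )
            for r in psub.itertuples()
        )
        mice.append(MouseRecord(
            mouse_id=str(mouse_id), group=str(group), transfer_day=td,
            volumes=tuple(zip(sub["day"], sub["volume_mm3"])), positions=positions,
        ))
    return mice
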