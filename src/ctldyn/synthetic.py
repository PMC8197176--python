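"""Synthetic intravital-imaging cohorts with the study's statistical design.

The generator emulates the structure of the melanoma ACT experiments:
tumour volumes measured on days 1, 3, 6, 9, 13 and 15 in every mouse;
adoptive transfer on day 3 or day 7; about four intravital positions per
mouse imaged for 1-3 h on days 6 and 9 (only after transfer).  Per-mouse
trajectories come from the ODE model; measurement noise is layered on top:

* volumes:   V(day) = T(day)/cells_per_mm3 times lognormal noise (mean 1,
             CV ``volume_cv``);
* field counts: expected tumour cells per field scale with total tumour
             size, with a lognormal field-to-field factor reflecting how
             strongly counts depended on window placement; CTL counts have
             expectation n_tc * (E/T);
* event counts: Poisson given counts and per-capita rates, with means
             tc_apoptosis = k_e*n_ctl*tau, tc_mitosis = g*(T_p/T)*n_tc*tau,
             ctl_mitosis = I*n_ctl*tau, ctl_apoptosis = R*n_ctl*tau
             (tau in days).

With ``noise=False`` every draw is replaced by its expectation (fixed 2 h
duration, counts kept as floats), giving an exact round trip through the
observation model.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml

from .model import ModelParameters, Trajectory, simulate
from .observation import IntravitalPosition, MouseRecord

__all__ = ["CohortDesign", "generate_cohort", "generate_condition",
           "expected_counts", "event_count_means", "write_manifest"]


@dataclass(frozen=True)
class CohortDesign:
    """Study design and noise settings for one generated condition."""

    n_mice: int = 5
    volume_days: tuple = (1.0, 3.0, 6.0, 9.0, 13.0, 15.0)
    imaging_days: tuple = (6.0, 9.0)
    positions_per_mouse_per_day: int = 4
    duration_range: tuple = (1.0, 3.0)        # hours
    field_cell_scale: float = 300.0           # expected TCs per field at T = field_ref_cells
    field_ref_cells: float = 1.0e5
    field_sigma: float = 0.5                  # lognormal sd of the field-placement factor
    volume_cv: float = 0.2
    cells_per_mm3: float = 1.3e5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice <= 0 or self.positions_per_mouse_per_day <= 0:
            raise ValueError("counts must be positive")
        if self.volume_cv < 0:
            raise ValueError("volume_cv must be >= 0")
        if not (0 < self.duration_range[0] <= self.duration_range[1]):
            raise ValueError("duration_range must be positive and ordered")


def event_count_means(
    killing: float, tc_mitosis: float, ctl_mitosis: float, ctl_apoptosis: float,
    n_ctl: float, n_tc: float, duration: float,
) -> dict:
    """Expected event counts in one field from per-capita rates (day^-1).

    ``duration`` is in hours; killing and the CTL rates are per CTL, the TC
    mitosis rate per tumour cell.
    """
    tau = duration / 24.0
    return {
        "tc_apoptosis": killing * n_ctl * tau,
        "tc_mitosis": tc_mitosis * n_tc * tau,
        "ctl_mitosis": ctl_mitosis * n_ctl * tau,
        "ctl_apoptosis": ctl_apoptosis * n_ctl * tau,
    }


def _rates_at(traj: Trajectory, day: float) -> tuple:
    """(killing, tc_mitosis, ctl_mitosis, ctl_apoptosis, T, T_p, E) at day."""
    st = traj.state_at(day)
    p = traj.params
    frac_p = st.T_p / st.T if st.T > 0 else 0.0
    return p.k_e, p.g * frac_p, st.I, st.R, st.T, st.T_p, st.E


def expected_counts(
    params: ModelParameters,
    design: CohortDesign,
    day: float,
    duration: float | None = None,
) -> dict:
    """Closed-form per-position expected counts on ``day``.

    Uses the design's expected field size (no field-placement noise) and the
    midpoint of the duration range unless ``duration`` (hours) is given.
    Exposed so tests can compare Monte-Carlo means against these values.
    """
    if duration is None:
        duration = 0.5 * sum(design.duration_range)
    grid = np.unique([0.0, day])
    traj = simulate(params, grid)
    k_e, tcm, ctlm, ctla, T, _, E = _rates_at(traj, day)
    n_tc = design.field_cell_scale * T / design.field_ref_cells
    n_ctl = n_tc * (E / T if T > 0 else 0.0)
    means = event_count_means(k_e, tcm, ctlm, ctla, n_ctl, n_tc, duration)
    means.update({"n_tc": n_tc, "n_ctl": n_ctl, "duration": duration})
    return means


def generate_condition(
    params: ModelParameters,
    design: CohortDesign,
    group: str,
    transfer_day: float | None,
    rng: np.random.Generator,
    noise: bool = True,
) -> list[MouseRecord]:
    """Generate ``design.n_mice`` mice for one treatment condition."""
    if transfer_day is None:
        p = params.with_(s=0.0)      # CTLs never infiltrate
    else:
        p = params.with_(transfer_day=float(transfer_day))
    days = sorted(set(design.volume_days) | set(design.imaging_days) | {0.0})
    traj = simulate(p, np.array(days))

    if design.volume_cv > 0:
        sigma_v = np.sqrt(np.log1p(design.volume_cv**2))
    else:
        sigma_v = 0.0

    mice = []
    for m in range(design.n_mice):
        mouse_id = f"{group}-d{transfer_day if transfer_day is not None else 'none'}-m{m:02d}"
        volumes = []
        for day in design.volume_days:
            v = traj.state_at(day).T / design.cells_per_mm3
            if noise and sigma_v > 0:
                v *= rng.lognormal(mean=-0.5 * sigma_v**2, sigma=sigma_v)
            volumes.append((day, v))
        positions = []
        for day in design.imaging_days:
            if transfer_day is not None and day < transfer_day:
                continue   # positions are only recorded after transfer
            k_e, tcm, ctlm, ctla, T, _, E = _rates_at(traj, day)
            for _pos in range(design.positions_per_mouse_per_day):
                if noise:
                    duration = rng.uniform(*design.duration_range)
                    factor = rng.lognormal(mean=-0.5 * design.field_sigma**2,
                                           sigma=design.field_sigma)
                    mu_tc = design.field_cell_scale * (T / design.field_ref_cells) * factor
                    n_tc = float(rng.poisson(mu_tc))
                    n_ctl = float(rng.poisson(n_tc * (E / T if T > 0 else 0.0)))
                    means = event_count_means(k_e, tcm, ctlm, ctla, n_ctl, n_tc, duration)
                    counts = {k: float(rng.poisson(v)) for k, v in means.items()}
                else:
                    duration = 2.0
                    n_tc = design.field_cell_scale * (T / design.field_ref_cells)
                    n_ctl = n_tc * (E / T if T > 0 else 0.0)
                    counts = event_count_means(k_e, tcm, ctlm, ctla, n_ctl, n_tc, duration)
                positions.append(IntravitalPosition(
                    mouse_id=mouse_id, day=day, duration=duration,
                    n_ctl=n_ctl, n_tc=n_tc, group=group, **counts,
                ))
        mice.append(MouseRecord(
            mouse_id=mouse_id, group=group, transfer_day=transfer_day,
            volumes=tuple(volumes), positions=tuple(positions),
        ))
    return mice


def generate_cohort(
    params_by_group: dict,
    design: CohortDesign,
    transfer_days: tuple = (3.0, 7.0),
    noise: bool = True,
) -> list[MouseRecord]:
    """Generate a full multi-condition cohort.

    ``params_by_group`` maps a group label to its ModelParameters; each group
    is generated at every transfer day in ``transfer_days`` (``None`` for an
    untreated condition).  Identical seeds give identical cohorts.
    """
    rng = np.random.default_rng(design.seed)
    mice: list[MouseRecord] = []
    for group, params in params_by_group.items():
        for td in transfer_days:
            mice.extend(generate_condition(params, design, group, td, rng, noise=noise))
    return mice


def write_manifest(design: CohortDesign, path, extra: dict | None = None) -> None:
    """Record the generating design (and seed) alongside the cohort tables."""
    payload = {"design": {k: (list(v) if isinstance(v, tuple) else v)
                          for k, v in asdict(design).items()}}
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
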