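"""Conversion of simulated compartment concentrations to organ deltaR1.

The change in longitudinal relaxation rate deltaR1 (1/s) is linear in
contrast-agent concentration through the field-strength-dependent
relaxivity r1 (L mmol^-1 s^-1).  Liver deltaR1 is a volume-fraction-
weighted mean over the extracellular and hepatocellular compartments, which
carry different relaxivities; spleen uses the blood relaxivity over its
whole-organ volume.  DCE-MRI observations are acquired over finite frames
(57 s here), so model predictions are time-averages of the simulated
deltaR1 over each frame interval.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ParameterError, PhysiologyParams, RelaxivityTable
from .pbpk import PBPKTrajectory

ORGANS = ("blood", "spleen", "liver")
SECONDS_PER_HOUR = 3600.0
#: umol/L -> mmol/L (relaxivities are per mmol)
UM_TO_MM = 1e-3


@dataclass
class DeltaR1Profile:
    """Frame-interval deltaR1 observations for one animal/organ/arm.

    frames: t_start/t_end in seconds, deltaR1 in 1/s; non-overlapping and
    ordered.
    """

    animal: str
    organ: str
    field_strength: float
    arm: str
    t_start: np.ndarray
    t_end: np.ndarray
    deltaR1: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.organ not in ORGANS:
            raise ParameterError(f"unknown organ {self.organ!r}")
        self.t_start = np.asarray(self.t_start, dtype=float)
        self.t_end = np.asarray(self.t_end, dtype=float)
        self.deltaR1 = np.asarray(self.deltaR1, dtype=float)
        if not (self.t_start.shape == self.t_end.shape == self.deltaR1.shape):
            raise ParameterError("frame arrays must share a shape")
        if np.any(self.t_end <= self.t_start):
            raise ParameterError("frames must have t_end > t_start")
        if np.any(self.t_start[1:] < self.t_end[:-1] - 1e-9):
            raise ParameterError("frames must be ordered and non-overlapping")

    @property
    def n_frames(self) -> int:
        return self.deltaR1.size


def conc_to_deltaR1(c_mM, r1: float):
    """deltaR1 (1/s) from concentration (mmol/L) and relaxivity r1."""
    c = np.asarray(c_mM, dtype=float)
    if np.any(c < 0):
        raise ParameterError("concentration must be >= 0")
    return r1 * c


def organ_deltaR1(traj: PBPKTrajectory, phys: PhysiologyParams,
                  r1: RelaxivityTable, organ: str,
                  field_strength: float) -> np.ndarray:
    """Simulated deltaR1 time course (1/s) for blood, spleen or liver."""
    r1b = r1.blood(field_strength)
    if organ == "blood":
        return r1b * traj.c_b * UM_TO_MM
    if organ == "spleen":
        return r1b * traj.c_spl_extr * UM_TO_MM * phys.V_spl_extr / phys.V_spl
    if organ == "liver":
        r1h = r1.hepatocytes(field_strength)
        amount_extr = traj.c_liv_extr * phys.V_liv_extr
        amount_cell = traj.c_liv_cell * phys.V_liv_cell
        return (r1b * amount_extr + r1h * amount_cell) * UM_TO_MM / phys.V_liv
    raise ParameterError(f"unknown organ {organ!r}")


def frame_average(t_dense, y_dense, t_start, t_end) -> np.ndarray:
    """Time-average of a densely sampled signal over frame intervals.

    t_dense and frame times share one unit; trapezoidal quadrature on the
    dense grid with interpolated frame endpoints.
    """
    t = np.asarray(t_dense, dtype=float)
    y = np.asarray(y_dense, dtype=float)
    t_start = np.atleast_1d(np.asarray(t_start, dtype=float))
    t_end = np.atleast_1d(np.asarray(t_end, dtype=float))
    if t_start.min() < t[0] - 1e-9 or t_end.max() > t[-1] + 1e-9:
        raise ValueError("frames extend outside the simulated span")
    out = np.empty(t_start.size)
    for i, (a, b) in enumerate(zip(t_start, t_end)):
        mask = (t > a) & (t < b)
        tt = np.concatenate([[a], t[mask], [b]])
        yy = np.concatenate([[np.interp(a, t, y)], y[mask],
                             [np.interp(b, t, y)]])
        out[i] = np.trapezoid(yy, tt) / (b - a)
    return out


def frame_time_grid(t_start_s, t_end_s, points_per_frame: int = 21
                    ) -> np.ndarray:
    """Dense hour-scale grid covering every frame with >= 20 interior
    points per frame, for quadrature-accurate frame means."""
    pieces = [np.linspace(a, b, points_per_frame)
              for a, b in zip(np.asarray(t_start_s, float),
                              np.asarray(t_end_s, float))]
    grid = np.unique(np.concatenate([[0.0]] + pieces)) / SECONDS_PER_HOUR
    return grid


def predict_frame_means(traj: PBPKTrajectory, phys: PhysiologyParams,
                        r1: RelaxivityTable, profile: DeltaR1Profile
                        ) -> np.ndarray:
    """Model-predicted frame-mean deltaR1 for one observed profile."""
    signal = organ_deltaR1(traj, phys, r1, profile.organ,
                           profile.field_strength)
    t_s = traj.t * SECONDS_PER_HOUR
    return frame_average(t_s, signal, profile.t_start, profile.t_end)
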