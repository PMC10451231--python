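"""Discrete-time dosing simulation, open-loop dose sizing and trajectory metrics.

The simulation convention is sample-then-dose: at time kT the concentration
y(k) = c^T x(k) is read, then the dose u(k) is administered, so

    x(k+1) = F x(k) + g u(k),   x(0) = 0 by default,

and the first dose acts on the first sampled concentration one period later.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .discretization import DiscreteModel

__all__ = [
    "DoseSchedule",
    "DosingTrajectory",
    "TherapeuticRange",
    "RangeReport",
    "simulate_lti",
    "openloop_dose",
    "auc_trapezoid",
    "range_report",
]


@dataclass(frozen=True)
class DoseSchedule:
    """Sequence of doses u(0..N-1) in mg, administered every ``T`` hours.

    Negative doses are allowed (they arise as an infeasibility diagnostic in
    closed-loop designs) but are flagged via :attr:`has_negative`.
    """

    doses: np.ndarray
    T: float

    def __post_init__(self) -> None:
        doses = np.atleast_1d(np.asarray(self.doses, float))
        if doses.size < 1 or not np.all(np.isfinite(doses)):
            raise ValueError("schedule must contain at least one finite dose")
        if not self.T > 0:
            raise ValueError("dosing period must be positive")
        object.__setattr__(self, "doses", doses)

    @classmethod
    def constant(cls, dose: float, n: int, T: float) -> "DoseSchedule":
        return cls(np.full(n, float(dose)), T)

    @property
    def has_negative(self) -> bool:
        return bool(np.any(self.doses < 0.0))

    def __len__(self) -> int:
        return self.doses.size


@dataclass(frozen=True)
class DosingTrajectory:
    """Aligned dosing history: times kT, doses, states, outputs.

    All arrays have length N+1; the dose sequence is padded with a trailing
    NaN marker (no dose is given at the final sample).  ``fs`` carries the
    state-feedback signal and ``v`` the integrator output when the
    trajectory comes from a cascade controller.
    """

    times: np.ndarray
    doses: np.ndarray
    states: np.ndarray
    outputs: np.ndarray
    fs: np.ndarray | None = None
    v: np.ndarray | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, float)
        doses = np.asarray(self.doses, float)
        states = np.asarray(self.states, float)
        outputs = np.asarray(self.outputs, float)
        n = times.size
        if not (doses.size == n and states.shape[0] == n and outputs.size == n):
            raise ValueError("trajectory sequences must share one length")
        for name, arr in (("fs", self.fs), ("v", self.v)):
            if arr is not None and np.asarray(arr).size != n:
                raise ValueError(f"{name} must share the trajectory length")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "outputs", outputs)

    @property
    def n_steps(self) -> int:
        return self.times.size - 1

    @property
    def has_negative_dose(self) -> bool:
        return bool(np.any(self.doses[:-1] < 0.0))

    def to_frame(self) -> pd.DataFrame:
        data = {
            "k": np.arange(self.times.size),
            "t_h": self.times,
            "dose_mg": self.doses,
            "x1": self.states[:, 0],
            "x2": self.states[:, 1],
            "x3": self.states[:, 2],
            "y": self.outputs,
        }
        if self.fs is not None:
            data["fs"] = self.fs
        if self.v is not None:
            data["v"] = self.v
        return pd.DataFrame(data)


@dataclass(frozen=True)
class TherapeuticRange:
    """Concentration band [lower, upper] in mg/mL within which the drug is
    effective and non-toxic."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("therapeutic range requires lower < upper")

    @classmethod
    def around(cls, target: float, rel_width: float = 0.1) -> "TherapeuticRange":
        """Band target*(1 -/+ rel_width); the default +/-10% mirrors the
        uncertainty magnitude the dosing designs are built against."""
        return cls(target * (1.0 - rel_width), target * (1.0 + rel_width))


@dataclass(frozen=True)
class RangeReport:
    below: np.ndarray
    above: np.ndarray
    settle_after: int
    status: str  # "ok" | "ineffective" | "toxic" | "mixed"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def simulate_lti(
    model: DiscreteModel,
    schedule: DoseSchedule,
    x0: Sequence[float] | None = None,
) -> DosingTrajectory:
    """Run x(k+1) = F x(k) + g u(k) over the given dose schedule."""
    n = model.n
    x = np.zeros(n) if x0 is None else np.asarray(x0, float).reshape(-1)
    if x.size != n:
        raise ValueError(f"x0 must have length {n}, got {x.size}")
    N = len(schedule)
    states = np.empty((N + 1, n))
    outputs = np.empty(N + 1)
    states[0] = x
    outputs[0] = model.c @ x
    for k in range(N):
        x = model.F @ x + model.g * schedule.doses[k]
        states[k + 1] = x
        outputs[k + 1] = model.c @ x
    times = np.arange(N + 1) * model.T
    doses = np.append(schedule.doses, np.nan)
    return DosingTrajectory(times=times, doses=doses, states=states, outputs=outputs)


def openloop_dose(gain: float, r: float) -> float:
    """Constant dose r / gain that steers the steady state to the target r."""
    if not gain > 0:
        raise ValueError(f"steady-state gain must be positive, got {gain}")
    return r / gain


def auc_trapezoid(trajectory: DosingTrajectory) -> float:
    """Area under the concentration curve by the trapezoidal rule (h x mg/mL),
    over the trajectory's sampled grid."""
    if trajectory.times.size < 2:
        raise ValueError("AUC needs at least two samples")
    return float(np.trapezoid(trajectory.outputs, trajectory.times))


def range_report(
    trajectory: DosingTrajectory,
    therapeutic_range: TherapeuticRange,
    settle_after: int = 0,
) -> RangeReport:
    """Flag samples outside the therapeutic range once transients have settled.

    Only samples with k >= settle_after are judged; sub-range levels mean an
    ineffective regimen, supra-range levels a toxic one.
    """
    y = trajectory.outputs
    k = np.arange(y.size)
    judged = k >= settle_after
    below = k[judged & (y < therapeutic_range.lower)]
    above = k[judged & (y > therapeutic_range.upper)]
    if below.size and above.size:
        status = "mixed"
    elif below.size:
        status = "ineffective"
    elif above.size:
        status = "toxic"
    else:
        status = "ok"
    return RangeReport(below=below, above=above, settle_after=settle_after, status=status)
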