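"""Least-squares identification of the rate constants from sampled
concentrations.

Given concentrations sampled after a single known oral dose, the four rate
constants are estimated by minimizing the unweighted sum of squared errors
between the data and the model's impulse response,

    y(t; theta) = dose * c^T exp(A(theta) t) b,

i.e. the dose is treated as an impulse into the absorption compartment at
time zero.  The estimation is exposed statsmodels-style: construct a
:class:`PKIdentification` model from the data, call :meth:`~PKIdentification.fit`,
inspect the returned :class:`PKFitResults` (estimates, SSE, convergence
diagnostics, ``summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import least_squares

from .core_model import RateConstants, build_continuous_model

__all__ = [
    "ConcentrationSeries",
    "PKIdentification",
    "PKFitResults",
    "fit_rate_constants",
    "simulate_concentrations",
]

_RATE_NAMES = ("ka", "ke1", "k23", "ke3")
_LOWER_BOUND = 1e-6  # keeps every rate strictly positive during the search


@dataclass(frozen=True)
class ConcentrationSeries:
    """Sampled drug concentrations after a single known dose.

    times in hours (strictly increasing), concentrations in mg/mL
    (non-negative), dose in mg administered at ``dose_time`` (hours).
    """

    times: np.ndarray
    concentrations: np.ndarray
    dose: float
    dose_time: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        c = np.asarray(self.concentrations, float)
        if t.size != c.size:
            raise ValueError("times and concentrations must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, dose: float, dose_time: float = 0.0
    ) -> "ConcentrationSeries":
        return cls(
            times=df["t_h"].to_numpy(float),
            concentrations=df["conc_mg_per_ml"].to_numpy(float),
            dose=dose,
            dose_time=dose_time,
        )

    def __len__(self) -> int:
        return self.times.size


def simulate_concentrations(
    rates: RateConstants,
    times: np.ndarray,
    dose: float,
    dose_time: float = 0.0,
    observed_compartment: int = 2,
) -> np.ndarray:
    """Model concentrations at ``times`` for an impulse dose at ``dose_time``."""
    model = build_continuous_model(rates)
    x0 = model.b * dose
    out = np.zeros(np.asarray(times, float).size)
    for i, t in enumerate(np.asarray(times, float)):
        dt = t - dose_time
        if dt >= 0:
            out[i] = expm(model.A * dt)[observed_compartment] @ x0
    return out


class PKIdentification:
    """Nonlinear least-squares model for the four rate constants.

    Parameters
    ----------
    data : ConcentrationSeries
        Sampled concentrations and the dose that produced them.
    observed_compartment : int
        Zero-based index of the sampled compartment; default 2, the tissue
        compartment the observation vector c = (0, 0, 1) points at.
    """

    def __init__(self, data: ConcentrationSeries, observed_compartment: int = 2):
        if len(data) < 4:
            raise ValueError(
                f"need at least 4 samples to identify 4 rate constants, got {len(data)}"
            )
        if not 0 <= observed_compartment <= 2:
            raise ValueError("observed_compartment must be 0, 1 or 2")
        self.data = data
        self.observed_compartment = observed_compartment

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        dose: float,
        dose_time: float = 0.0,
        observed_compartment: int = 2,
    ) -> "PKIdentification":
        return cls(
            ConcentrationSeries.from_dataframe(df, dose=dose, dose_time=dose_time),
            observed_compartment=observed_compartment,
        )

    def predict(self, rates: RateConstants) -> np.ndarray:
        return simulate_concentrations(
            rates,
            self.data.times,
            self.data.dose,
            self.data.dose_time,
            self.observed_compartment,
        )

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        rates = RateConstants(*np.maximum(theta, _LOWER_BOUND))
        return self.predict(rates) - self.data.concentrations

    def fit(self, start: RateConstants | None = None) -> "PKFitResults":
        """Minimize the SSE from ``start`` (trust-region reflective, with a
        positivity lower bound on every rate).  Deterministic: no random
        restarts; the same data and start always give the same estimate."""
        if start is None:
            start = RateConstants(0.1, 0.1, 1.0, 0.2)
        theta0 = start.as_array()
        sse_path: list[float] = []

        def tracked(theta: np.ndarray) -> np.ndarray:
            res = self._residuals(theta)
            sse = float(res @ res)
            sse_path.append(min(sse, sse_path[-1]) if sse_path else sse)
            return res

        sol = least_squares(
            tracked,
            theta0,
            bounds=(_LOWER_BOUND, np.inf),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        rates = RateConstants(*np.maximum(sol.x, _LOWER_BOUND))
        return PKFitResults(
            model=self,
            params=rates,
            sse=float(2 * sol.cost),
            success=bool(sol.success),
            status=int(sol.status),
            message=str(sol.message),
            n_evaluations=int(sol.nfev),
            start=start,
            sse_path=np.asarray(sse_path),
        )


@dataclass(frozen=True)
class PKFitResults:
    """Estimates and diagnostics of a rate-constant fit."""

    model: PKIdentification
    params: RateConstants
    sse: float
    success: bool
    status: int
    message: str
    n_evaluations: int
    start: RateConstants
    sse_path: np.ndarray = field(repr=False)

    def fittedvalues(self) -> np.ndarray:
        return self.model.predict(self.params)

    def resid(self) -> np.ndarray:
        return self.fittedvalues() - self.model.data.concentrations

    def summary(self) -> str:
        lines = [
            "Rate-constant identification (nonlinear least squares)",
            "=" * 56,
            f"observations: {len(self.model.data)}   "
            f"dose: {self.model.data.dose} mg   "
            f"compartment: {self.model.observed_compartment + 1}",
            f"converged: {self.success}   evaluations: {self.n_evaluations}",
            f"SSE: {self.sse:.6g}",
            "-" * 56,
            f"{'parameter':>10} {'estimate (1/h)':>16} {'start':>12}",
        ]
        for name in _RATE_NAMES:
            lines.append(
                f"{name:>10} {getattr(self.params, name):>16.6f} "
                f"{getattr(self.start, name):>12.4f}"
            )
        return "\n".join(lines)


def fit_rate_constants(
    data: ConcentrationSeries,
    initial_guess: RateConstants,
    observed_compartment: int = 2,
) -> PKFitResults:
    """Functional wrapper around :class:`PKIdentification`."""
    return PKIdentification(data, observed_compartment).fit(start=initial_guess)
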