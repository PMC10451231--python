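"""Reference fixtures: the in-vivo series, nominal parameters and published
reference matrices used throughout the tests and examples."""

from __future__ import annotations

import numpy as np

from .core_model import NOMINAL_RATES_H, RateConstants, build_continuous_model
from .discretization import DiscreteModel
from .identification import ConcentrationSeries

__all__ = [
    "nominal_rates",
    "nominal_continuous_model",
    "invivo_series",
    "reference_discrete_model",
    "reference_feedback_gain",
]


def nominal_rates() -> RateConstants:
    """Nominal rate constants identified for sulfathiazole in the rat (1/h)."""
    return RateConstants.from_mapping(NOMINAL_RATES_H)


def nominal_continuous_model():
    return build_continuous_model(nominal_rates())


def invivo_series() -> ConcentrationSeries:
    """Mean in-vivo sulfathiazole concentrations (mg/mL) in rat blood samples,
    hourly from 6 h after a single oral suspension dose.

    Dose bookkeeping: 0.5 mL of a 5% (50 mg/mL) suspension per 100 g body
    weight, rats of 200 g, hence 50 mg per animal.  The exact normalization
    used in the original identification is not recorded here, so this series
    is a smoke-test input, not a parameter oracle.
    """
    return ConcentrationSeries(
        times=np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
        concentrations=np.array(
            [0.0, 0.0715, 0.0855, 0.0780, 0.0735, 0.0490, 0.0535]
        ),
        dose=50.0,
    )


def reference_discrete_model() -> DiscreteModel:
    """Published 4-decimal discrete-time model at T = 6 h.

    These are the rounded printed values; exact ZOH discretization of the
    nominal continuous model reproduces them entry-wise to 4 dp.
    """
    F = np.array(
        [
            [0.3866, 0.0, 0.0],
            [0.0128, 0.0005, 0.0],
            [0.0718, 0.3272, 0.2718],
        ]
    )
    g = np.array([3.8726, 0.1025, 0.2704])
    return DiscreteModel(F=F, g=g, c=np.array([0.0, 0.0, 1.0]), T=6.0)


def reference_feedback_gain() -> np.ndarray:
    """Published robustly stabilizing state-feedback gain row vector."""
    return np.array([-0.2371, 0.0754, 0.0754])
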