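"""Closed-loop dosing with a discrete integral controller.

Each dosing period the measured concentration is fed back and the next dose
is the previous administered dose plus ki times the tracking error:

    u(0) = ki * r,      u(k) = u(k-1) + ki * (r - y(k)),   k >= 1,

where r is the target steady-state concentration and ki the integral gain.
Integral action drives the steady-state error to zero whenever the loop is
Schur-stable, regardless of (bounded) parametric uncertainty — the dose
converges to r divided by the true steady-state gain without the clinician
knowing that gain.

The update uses the most recent sample y(k).  Scenario knobs cover a
loading dose (override of u(0) only) and mis-dosing experiments where the
first few administered doses are a scaled version of the computed ones; the
loop always observes the concentrations the *administered* doses produced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_model import TransferFunction
from .discretization import DiscreteModel, discrete_transfer_function, steady_state_gain
from .simulation import DosingTrajectory

__all__ = [
    "IntegralControllerConfig",
    "ClosedLoopAnalysis",
    "simulate_integral_control",
    "closed_loop_char_poly",
    "settled_dose",
]


@dataclass(frozen=True)
class IntegralControllerConfig:
    """Integral-controller dosing scenario.

    ki: integral gain (dimensionless); r: target concentration (mg/mL);
    horizon: number of dosing intervals N; u0_override: optional loading
    dose replacing u(0) only; dose_scale: optional (factor, first_n) pair —
    the first ``first_n`` administered doses are ``factor`` times the
    computed ones (under-/over-dosing experiments); integrator: whether the
    recursion continues from the administered or the computed dose.
    """

    ki: float
    r: float
    horizon: int = 24
    u0_override: float | None = None
    dose_scale: tuple[float, int] | None = None
    integrator: str = "administered"  # or "computed"

    def __post_init__(self) -> None:
        if not self.ki > 0:
            raise ValueError("integral gain ki must be positive")
        if self.r < 0:
            raise ValueError("target concentration must be non-negative")
        if self.horizon < 1:
            raise ValueError("horizon must be at least one dosing interval")
        if self.dose_scale is not None:
            factor, first_n = self.dose_scale
            if not factor > 0 or first_n < 0:
                raise ValueError("dose_scale must be (factor > 0, first_n >= 0)")
        if self.integrator not in ("administered", "computed"):
            raise ValueError("integrator must be 'administered' or 'computed'")


def simulate_integral_control(
    model: DiscreteModel, cfg: IntegralControllerConfig
) -> DosingTrajectory:
    """Simulate the integral-controller dosing loop from a drug-free state.

    Records the administered doses; negative computed doses are simulated
    as-is (they flag an infeasible protocol, not a numerical problem).
    """
    n = model.n
    N = cfg.horizon
    x = np.zeros(n)
    states = np.empty((N + 1, n))
    outputs = np.empty(N + 1)
    doses = np.full(N + 1, np.nan)
    states[0] = x
    outputs[0] = model.c @ x

    u_computed = cfg.ki * cfg.r if cfg.u0_override is None else cfg.u0_override
    u_prev_for_integrator = 0.0
    for k in range(N):
        u_adm = u_computed
        if cfg.dose_scale is not None and k < cfg.dose_scale[1]:
            u_adm = cfg.dose_scale[0] * u_computed
        doses[k] = u_adm
        x = model.F @ x + model.g * u_adm
        states[k + 1] = x
        y = model.c @ x
        outputs[k + 1] = y
        u_prev_for_integrator = u_adm if cfg.integrator == "administered" else u_computed
        u_computed = u_prev_for_integrator + cfg.ki * (cfg.r - y)

    times = np.arange(N + 1) * model.T
    return DosingTrajectory(times=times, doses=doses, states=states, outputs=outputs)


@dataclass(frozen=True)
class ClosedLoopAnalysis:
    """z-domain stability analysis of the integral loop."""

    char_poly: np.ndarray  # monic, highest power of z first, degree n+1
    roots: np.ndarray      # sorted descending by modulus
    stable: bool
    plant: TransferFunction


def closed_loop_char_poly(model: DiscreteModel, ki: float) -> ClosedLoopAnalysis:
    """Characteristic polynomial and roots of the integral-control loop.

    With plant pulse transfer function G(z) = num(z)/det(zI - F) (num
    strictly proper) and the integral law accumulating the current sample,
    the loop characteristic polynomial is

        p(z) = (z - 1) det(zI - F) + ki * z * num(z),

    of degree n+1; the loop is Schur-stable iff all roots lie strictly
    inside the unit circle.
    """
    if not ki > 0:
        raise ValueError("integral gain ki must be positive")
    tf = discrete_transfer_function(model)
    den = tf.den
    p = np.polymul(den, np.array([1.0, -1.0]))
    shifted_num = ki * np.polymul(tf.num, np.array([1.0, 0.0]))
    p = np.polyadd(p, np.concatenate([np.zeros(p.size - shifted_num.size), shifted_num]))
    roots = np.roots(p)
    order = np.argsort(-np.abs(roots))
    roots = roots[order]
    if np.allclose(roots.imag, 0.0, atol=1e-12):
        roots = roots.real
    stable = bool(np.all(np.abs(roots) < 1.0))
    return ClosedLoopAnalysis(char_poly=p, roots=roots, stable=stable, plant=tf)


def settled_dose(
    trajectory: DosingTrajectory, rel_tol: float = 1e-3
) -> float:
    """Final administered dose of a (presumed converged) closed-loop run.

    For a stable loop this converges to r / steady-state-gain, i.e. to the
    dose the open-loop design would prescribe if the gain were known.  A
    relative step change above ``rel_tol`` at the horizon raises a
    non-convergence warning.
    """
    doses = trajectory.doses[:-1]
    if doses.size < 2:
        raise ValueError("need at least two doses to judge convergence")
    last, prev = doses[-1], doses[-2]
    scale = max(abs(last), 1e-12)
    if abs(last - prev) / scale > rel_tol:
        warnings.warn(
            f"dose not settled at horizon: relative step "
            f"{abs(last - prev) / scale:.3e} > {rel_tol:.1e}",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(last)
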