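"""Zero-order-hold discretization and interval-uncertainty models.

Repeated oral dosing is a sampled process: a dose u(k) is given every T
hours and the concentration is sampled at the same cadence, so the natural
model is the exact ZOH discretization

    x(k+1) = F x(k) + g u(k),   F = exp(A T),  g = A^{-1} (F - I) b.

Parametric uncertainty is carried as an element-wise interval around the
nominal (F, g): every entry is known only to within a relative factor
(1 +/- delta).  Because F is non-negative for compartmental models, the
spectral radius is monotone in the entries, which turns robust Schur
stability into a single check at the upper interval corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.linalg import expm

from .core_model import ContinuousModel, TransferFunction

__all__ = [
    "DiscreteModel",
    "IntervalModel",
    "zoh_discretize",
    "steady_state_gain",
    "make_interval",
    "make_interval_continuous",
    "interval_is_stable",
    "discrete_transfer_function",
]

#: strict Schur margin: "stable" means spectral radius < 1 - SCHUR_TOL
SCHUR_TOL = 1e-9


@dataclass(frozen=True)
class DiscreteModel:
    """Discrete-time state-space model (F, g, c) at dosing period T hours."""

    F: np.ndarray
    g: np.ndarray
    c: np.ndarray
    T: float
    discretization_method: str = field(default="direct", compare=False)

    def __post_init__(self) -> None:
        F = np.asarray(self.F, float)
        g = np.asarray(self.g, float).reshape(-1)
        c = np.asarray(self.c, float).reshape(-1)
        if F.shape[0] != F.shape[1] or F.shape[0] != g.size or g.size != c.size:
            raise ValueError(f"inconsistent shapes: F{F.shape}, g{g.shape}, c{c.shape}")
        if not self.T > 0:
            raise ValueError(f"dosing period must be positive, got T={self.T}")
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "c", c)

    @property
    def n(self) -> int:
        return self.F.shape[0]

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.F))))

    def is_schur(self) -> bool:
        return self.spectral_radius() < 1.0 - SCHUR_TOL

    def scaled(self, factor: float) -> "DiscreteModel":
        """Model with F and g scaled element-wise (interval-corner model)."""
        return DiscreteModel(
            factor * self.F, factor * self.g, self.c, self.T,
            discretization_method=self.discretization_method,
        )


@dataclass(frozen=True)
class IntervalModel:
    """Element-wise interval family F_lo <= F <= F_hi, g_lo <= g <= g_hi."""

    F_lo: np.ndarray
    F_hi: np.ndarray
    g_lo: np.ndarray
    g_hi: np.ndarray
    delta: float
    base: DiscreteModel

    def __post_init__(self) -> None:
        for name in ("F_lo", "F_hi", "g_lo", "g_hi"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if np.any(self.F_lo > self.F_hi + 1e-15) or np.any(self.g_lo > self.g_hi + 1e-15):
            raise ValueError("interval bounds must satisfy lo <= hi element-wise")

    def corners(self):
        """The four (F, g) corner pairs {F_lo,F_hi} x {g_lo,g_hi}."""
        return [
            (F, g)
            for F in (self.F_lo, self.F_hi)
            for g in (self.g_lo, self.g_hi)
        ]


def zoh_discretize(model: ContinuousModel, T: float) -> DiscreteModel:
    """Exact zero-order-hold discretization at dosing period T (hours).

    When A is invertible (always the case for positive rates: A is
    triangular with a negative diagonal) g = A^{-1}(exp(AT) - I) b.  A
    singular A — possible with permissively built matrices — falls back to
    the augmented-matrix exponential exp([[A, b], [0, 0]] T), whose top-right
    block is g; the path taken is recorded in ``discretization_method``.
    """
    if not T > 0:
        raise ValueError(f"dosing period must be positive, got T={T}")
    A, b = model.A, model.b
    n = model.n
    F = expm(A * T)
    try:
        # solve A g = (F - I) b; raises for singular A
        g = np.linalg.solve(A, (F - np.eye(n)) @ b)
        method = "direct"
    except np.linalg.LinAlgError:
        aug = np.zeros((n + 1, n + 1))
        aug[:n, :n] = A
        aug[:n, n] = b
        M = expm(aug * T)
        F = M[:n, :n]
        g = M[:n, n]
        method = "augmented"
    return DiscreteModel(F=F, g=g, c=model.c.copy(), T=T, discretization_method=method)


def steady_state_gain(model: DiscreteModel) -> float:
    """Steady-state gain c^T (I - F)^{-1} g.

    This is the ratio y_ss / u_ss under a constant dose; it only exists for
    Schur-stable F.
    """
    if not model.is_schur():
        raise ValueError(
            "no finite steady state: spectral radius "
            f"{model.spectral_radius():.6f} >= 1"
        )
    return float(model.c @ np.linalg.solve(np.eye(model.n) - model.F, model.g))


def make_interval(model: DiscreteModel, delta: float) -> IntervalModel:
    """Relative element-wise interval (1 - delta) * nominal .. (1 + delta) * nominal.

    ``delta`` is the maximum acceptable relative parametric uncertainty
    (e.g. 0.1 for +/-10%).  delta >= 1 is rejected: it would permit negative
    parameters, which is biologically impossible for this model class.
    """
    if not 0.0 <= delta < 1.0:
        raise ValueError(
            f"delta must lie in [0, 1), got {delta}: delta >= 1 would permit "
            "negative parameters"
        )
    return IntervalModel(
        F_lo=(1.0 - delta) * model.F,
        F_hi=(1.0 + delta) * model.F,
        g_lo=(1.0 - delta) * model.g,
        g_hi=(1.0 + delta) * model.g,
        delta=delta,
        base=model,
    )


def make_interval_continuous(model: ContinuousModel, T: float, delta: float) -> IntervalModel:
    """Secondary uncertainty mode: perturb the continuous rates, then discretize.

    The rates are scaled by (1 - delta) and (1 + delta), each perturbed model
    is ZOH-discretized, and the element-wise envelope of the two corners is
    taken.  This parameterization does NOT coincide with the element-wise
    scaling of (F, g) done by :func:`make_interval` (discretization is a
    nonlinear map of the rates); the discrete-domain scaling is the default
    throughout the package.
    """
    if not 0.0 <= delta < 1.0:
        raise ValueError(
            f"delta must lie in [0, 1), got {delta}: delta >= 1 would permit "
            "negative parameters"
        )
    if model.rates is None:
        raise ValueError("continuous-delta mode needs a model built from rates")
    base = zoh_discretize(model, T)
    from .core_model import build_continuous_model

    lo = zoh_discretize(build_continuous_model(model.rates.scaled(1.0 - delta)), T)
    hi = zoh_discretize(build_continuous_model(model.rates.scaled(1.0 + delta)), T)
    return IntervalModel(
        F_lo=np.minimum(lo.F, hi.F),
        F_hi=np.maximum(lo.F, hi.F),
        g_lo=np.minimum(lo.g, hi.g),
        g_hi=np.maximum(lo.g, hi.g),
        delta=delta,
        base=base,
    )


def _vertex_matrices(F_lo: np.ndarray, F_hi: np.ndarray, cap: int = 4096):
    """All per-entry corner matrices of [F_lo, F_hi] (entries that differ)."""
    diff = np.argwhere(F_lo != F_hi)
    if 2 ** len(diff) > cap:
        raise ValueError(
            f"vertex enumeration over {len(diff)} free entries exceeds cap {cap}"
        )
    for choice in product((0, 1), repeat=len(diff)):
        F = F_lo.copy()
        for (i, j), pick in zip(diff, choice):
            if pick:
                F[i, j] = F_hi[i, j]
        yield F


def interval_is_stable(interval: IntervalModel) -> tuple[bool, str]:
    """Robust Schur stability of the whole interval family.

    For a non-negative interval (F_lo >= 0) the spectral radius of a
    non-negative matrix is monotone in its entries, so the family is Schur
    iff the upper corner F_hi is; the certificate records rho(F_hi) and this
    argument, plus an explicit check of all four (F, g) corner pairs.  If
    F_lo has negative entries the monotonicity argument fails and the
    routine falls back to exhaustive per-entry vertex enumeration (capped).
    """
    rho = lambda F: float(np.max(np.abs(np.linalg.eigvals(F))))
    if np.all(interval.F_lo >= 0.0):
        rho_hi = rho(interval.F_hi)
        stable = rho_hi < 1.0 - SCHUR_TOL
        corner_rhos = [rho(F) for F, _ in interval.corners()]
        stable = stable and all(r < 1.0 - SCHUR_TOL for r in corner_rhos)
        certificate = (
            f"non-negative interval family: spectral radius is monotone in the "
            f"entries, hence maximal at the upper corner; rho(F_hi)={rho_hi:.6f} "
            f"{'<' if stable else '>='} 1; corner radii "
            + ", ".join(f"{r:.6f}" for r in sorted(set(corner_rhos)))
        )
        return stable, certificate
    radii = [rho(F) for F in _vertex_matrices(interval.F_lo, interval.F_hi)]
    worst = max(radii)
    stable = worst < 1.0 - SCHUR_TOL
    certificate = (
        f"F_lo has negative entries: exhaustive vertex check over "
        f"{len(radii)} corner matrices; max spectral radius {worst:.6f}"
    )
    return stable, certificate


def discrete_transfer_function(model: DiscreteModel) -> TransferFunction:
    """Pulse transfer function G(z) = c^T (zI - F)^{-1} g.

    Returned with monomial coefficients in z (monic denominator
    det(zI - F)); the numerator is strictly proper, so the impulse response
    starts with c^T g one step after the dose.
    """
    from scipy.signal import ss2tf

    num, den = ss2tf(
        model.F, model.g.reshape(-1, 1), model.c.reshape(1, -1), np.zeros((1, 1))
    )
    num = np.atleast_1d(np.squeeze(num))
    nz = np.flatnonzero(np.abs(num) > 0)
    num = num[nz[0]:] if nz.size else np.array([0.0])
    return TransferFunction(num=num, den=den, var="z")
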