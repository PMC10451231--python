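"""Robust state-feedback stabilization of an unstable interval plant.

A compartmental plant discretized with ZOH is always Schur-stable, but
related bioprocess models (tumour growth being the motivating example) need
not be.  To study that regime the lower interval corner is deliberately
destabilized by an additive entry perturbation, and a state-feedback dose
term u = K x is synthesized by linear programming so that every corner of
the interval family is simultaneously non-negative and Schur-stable.

Synthesis exploits positivity.  Split K = K+ + K- with K+ >= 0, K- <= 0.
For any F in the (element-wise) interval hull and g in [g_lo, g_hi] >= 0,

    F_min + g_lo K+ + g_hi K-  <=  F + g K  <=  F_max + g_hi K+ + g_lo K-,

so it suffices to make the right bound Schur (via a chosen positive
left Lyapunov vector v: v^T M < v^T) and the left bound non-negative.  Both
conditions are linear in (K+, K-), giving a small LP; a-posteriori
verification over the four (F, g) corner pairs is the contract, since LP
vertex solutions are solver-dependent.

Because one component of a stabilizing K is typically negative, pure state
feedback can prescribe negative (infeasible) doses; the cascade loop adds
an outer integral controller, u(k) = v(k) + K x(k), which restores
positive dosing and zero steady-state tracking error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .discretization import SCHUR_TOL, DiscreteModel, IntervalModel
from .integral_control import IntegralControllerConfig
from .simulation import DosingTrajectory

__all__ = [
    "DestabilizedPlant",
    "FeedbackGain",
    "SynthesisInfeasibleError",
    "destabilize",
    "synthesize_state_feedback",
    "verify_corner_stability",
    "closed_loop_eigs",
    "simulate_cascade",
    "detect_infeasible_dosing",
]


class SynthesisInfeasibleError(RuntimeError):
    """Raised when the stabilization LP has no feasible point."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class DestabilizedPlant:
    """Interval plant whose lower transition-matrix corner has been
    perturbed by an additive matrix D (the instability injection)."""

    interval: IntervalModel
    D: np.ndarray
    F_lo: np.ndarray  # perturbed lower corner

    def corners(self):
        """(F, g) vertex pairs with the perturbed lower corner in place."""
        return [
            (F, g)
            for F in (self.F_lo, self.interval.F_hi)
            for g in (self.interval.g_lo, self.interval.g_hi)
        ]

    def eigenvalues(self) -> np.ndarray:
        eig = np.linalg.eigvals(self.F_lo)
        return np.sort(eig.real) if np.allclose(eig.imag, 0) else np.sort_complex(eig)

    @property
    def is_unstable(self) -> bool:
        return bool(np.max(np.abs(np.linalg.eigvals(self.F_lo))) >= 1.0)


@dataclass(frozen=True)
class FeedbackGain:
    """Row gain K of the stabilizing dose law u = K x, with LP metadata."""

    K: np.ndarray
    verified: bool
    corner_eigs: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "K", np.asarray(self.K, float).reshape(-1))


def destabilize(
    interval: IntervalModel,
    delta_entry: float,
    position: tuple[int, int] = (0, 0),
) -> DestabilizedPlant:
    """Add ``delta_entry`` to one entry of the lower corner F_lo.

    The default position (0, 0) perturbs the absorption compartment's
    self-transition; 0.7 there pushes its eigenvalue past one.
    """
    n = interval.F_lo.shape[0]
    i, j = position
    if not (0 <= i < n and 0 <= j < n):
        raise ValueError(f"position {position} outside {n}x{n} matrix")
    D = np.zeros((n, n))
    D[i, j] = delta_entry
    return DestabilizedPlant(interval=interval, D=D, F_lo=interval.F_lo + D)


def verify_corner_stability(
    plant: DestabilizedPlant, K: np.ndarray, require_nonnegative: bool = True
) -> tuple[bool, list]:
    """A-posteriori check: every corner closed loop F + g K Schur (and
    non-negative where positivity of the closed loop is claimed)."""
    K = np.asarray(K, float).reshape(-1)
    corner_eigs = []
    ok = True
    for F, g in plant.corners():
        M = F + np.outer(g, K)
        eig = np.linalg.eigvals(M)
        corner_eigs.append(np.sort_complex(eig))
        if np.max(np.abs(eig)) >= 1.0 - SCHUR_TOL:
            ok = False
        if require_nonnegative and np.any(M < -1e-9):
            ok = False
    return ok, corner_eigs


def synthesize_state_feedback(
    plant: DestabilizedPlant,
    eps_plus: float = 1e-3,
    eps_minus: float = -1e-3,
    v: np.ndarray | None = None,
    alpha: float = 1.01,
    k_bound: float = 10.0,
) -> FeedbackGain:
    """Solve the corner-bound LP for a robustly stabilizing gain K.

    Parameters mirror the synthesis knobs: ``eps_plus`` > 0 is the strict
    Schur margin, ``eps_minus`` < 0 the strict-negativity margin on the
    negative gain part, ``v`` > 0 the chosen left Lyapunov weight and
    ``alpha`` > 1 the constraint tightening factor.  The LP minimizes the
    total gain magnitude; the returned gain carries the a-posteriori
    four-corner verification result and the v-normalized multipliers
    sigma+/- = K+/- * (g_lo . v) as metadata.
    """
    if not eps_plus > 0:
        raise ValueError("eps_plus must be positive")
    if not eps_minus < 0:
        raise ValueError("eps_minus must be negative")
    if not alpha > 1:
        raise ValueError("alpha must exceed 1")
    n = plant.F_lo.shape[0]
    v = np.ones(n) if v is None else np.asarray(v, float).reshape(-1)
    if v.size != n or np.any(v <= 0):
        raise ValueError("v must be a positive vector of matching length")

    iv = plant.interval
    F_max = np.maximum(plant.F_lo, iv.F_hi)
    F_min = np.minimum(plant.F_lo, iv.F_hi)
    g_lo, g_hi = iv.g_lo, iv.g_hi
    if np.any(g_lo < 0):
        raise ValueError("synthesis assumes a non-negative input vector family")

    # variables z = [K+ (n), K- (n)]
    nv = 2 * n
    c_obj = np.concatenate([np.ones(n), -np.ones(n)])  # sum K+ - sum K- = |K| l1
    A_ub, b_ub = [], []
    # Schur: v^T (F_max + g_hi K+ + g_lo K-) <= v^T / alpha - eps_plus, per column j
    wv_hi = float(v @ g_hi)
    wv_lo = float(v @ g_lo)
    for j in range(n):
        row = np.zeros(nv)
        row[j] = wv_hi
        row[n + j] = wv_lo
        A_ub.append(row)
        b_ub.append(v[j] / alpha - eps_plus - float(v @ F_max[:, j]))
    # Non-negativity: F_min[i,j] + g_lo[i] K+[j] + g_hi[i] K-[j] >= 0
    for i in range(n):
        for j in range(n):
            row = np.zeros(nv)
            row[j] = -g_lo[i]
            row[n + j] = -g_hi[i]
            A_ub.append(row)
            b_ub.append(F_min[i, j])
    bounds = [(0.0, k_bound)] * n + [(-k_bound, 0.0)] * n
    res = linprog(
        c_obj, A_ub=np.array(A_ub), b_ub=np.array(b_ub), bounds=bounds, method="highs"
    )
    if not res.success:
        raise SynthesisInfeasibleError(
            f"stabilization LP infeasible: {res.message}",
            diagnostics={
                "status": res.status,
                "message": res.message,
                "F_max_column_weights": (v @ F_max).tolist(),
                "v": v.tolist(),
                "alpha": alpha,
            },
        )
    K_plus, K_minus = res.x[:n], res.x[n:]
    K = K_plus + K_minus
    ok, corner_eigs = verify_corner_stability(plant, K)
    gain = FeedbackGain(
        K=K,
        verified=ok,
        corner_eigs=corner_eigs,
        meta={
            "K_plus": K_plus,
            "K_minus": K_minus,
            "sigma_plus": K_plus * wv_lo,
            "sigma_minus": K_minus * wv_lo,
            "eps_plus": eps_plus,
            "eps_minus": eps_minus,
            "v": v,
            "alpha": alpha,
            "solver_status": res.status,
            "objective": float(res.fun),
        },
    )
    if not ok:
        # never return a silently bad gain: the flag plus eigenvalues are
        # the diagnostics the caller must inspect
        gain.meta["verification_failure"] = [
            np.max(np.abs(e)) for e in corner_eigs
        ]
    return gain


def closed_loop_eigs(
    F: np.ndarray, g: np.ndarray, K: FeedbackGain | np.ndarray
) -> np.ndarray:
    """Eigenvalues of F + g K, sorted ascending (real spectra stay real)."""
    Kv = K.K if isinstance(K, FeedbackGain) else np.asarray(K, float).reshape(-1)
    g = np.asarray(g, float).reshape(-1)
    M = np.asarray(F, float) + np.outer(g, Kv)
    eig = np.linalg.eigvals(M)
    return np.sort(eig.real) if np.allclose(eig.imag, 0, atol=1e-12) else np.sort_complex(eig)


def simulate_cascade(
    model: DiscreteModel,
    K: FeedbackGain | np.ndarray,
    cfg: IntegralControllerConfig,
) -> DosingTrajectory:
    """Cascade dosing: inner state feedback plus outer integral controller.

    The administered dose is u(k) = v(k) + fs(k) with fs(k) = K x(k) and the
    integrator v(0) = ki r, v(k) = v(k-1) + ki (r - y(k)).  With K = 0 this
    reduces exactly to the plain integral controller.  ``model`` carries the
    plant actually simulated — e.g. the destabilized lower-corner F paired
    with the nominal g.
    """
    import warnings as _warnings

    Kv = K.K if isinstance(K, FeedbackGain) else np.asarray(K, float).reshape(-1)
    inner_rho = float(np.max(np.abs(np.linalg.eigvals(model.F + np.outer(model.g, Kv)))))
    if inner_rho >= 1.0:
        _warnings.warn(
            f"inner loop F + gK is not Schur (rho={inner_rho:.4f}); "
            "the cascade may diverge",
            RuntimeWarning,
            stacklevel=2,
        )
    n = model.n
    N = cfg.horizon
    x = np.zeros(n)
    states = np.empty((N + 1, n))
    outputs = np.empty(N + 1)
    doses = np.full(N + 1, np.nan)
    fs = np.full(N + 1, np.nan)
    vs = np.full(N + 1, np.nan)
    states[0] = x
    outputs[0] = model.c @ x
    v_int = cfg.ki * cfg.r if cfg.u0_override is None else cfg.u0_override
    for k in range(N):
        fs[k] = Kv @ x
        vs[k] = v_int
        u = v_int + fs[k]
        doses[k] = u
        x = model.F @ x + model.g * u
        states[k + 1] = x
        y = model.c @ x
        outputs[k + 1] = y
        v_int = v_int + cfg.ki * (cfg.r - y)
    times = np.arange(N + 1) * model.T
    return DosingTrajectory(
        times=times, doses=doses, states=states, outputs=outputs, fs=fs, v=vs
    )


def detect_infeasible_dosing(trajectory: DosingTrajectory) -> int | None:
    """Index of the first negative administered dose, or None.

    A negative dose cannot be administered; its appearance marks the step at
    which a dosing protocol stops being physically realizable.
    """
    doses = trajectory.doses[:-1]
    neg = np.flatnonzero(doses < 0.0)
    return int(neg[0]) if neg.size else None
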