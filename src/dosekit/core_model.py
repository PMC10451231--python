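"""Continuous-time three-compartment pharmacokinetic model.

The model tracks a drug through the gastrointestinal tract (compartment 1),
a central compartment (2) and the sampled tissue compartment (3):

    dx1/dt = -(ka + ke1) x1 + u
    dx2/dt = ka x1 - k23 x2
    dx3/dt = k23 x2 - ke3 x3,      y = x3

with first-order rate constants ka (absorption), ke1 and ke3 (elimination
from compartments 1 and 3) and k23 (transfer 2 -> 3), all in 1/h.  The
system matrix is Metzler and every column sum is non-positive, so the model
is a positive, mass-balanced (compartmental) system and is Hurwitz-stable
for any positive rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "RateConstants",
    "ContinuousModel",
    "TransferFunction",
    "CompartmentalCheck",
    "build_continuous_model",
    "continuous_char_roots",
    "is_compartmental",
    "continuous_transfer_function",
]

#: Rate constants identified for sulfathiazole absorption in the rat (1/h).
NOMINAL_RATES_H = {"ka": 0.0370, "ke1": 0.1214, "k23": 1.2725, "ke3": 0.2171}


@dataclass(frozen=True)
class RateConstants:
    """First-order rate constants of the three-compartment model, in 1/h.

    All four rates must be strictly positive; a zero or negative rate has no
    biological meaning for this topology.
    """

    ka: float
    ke1: float
    k23: float
    ke3: float

    def __post_init__(self) -> None:
        for name in ("ka", "ke1", "k23", "ke3"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                raise ValueError(
                    f"rate must be strictly positive: {name}={value!r}"
                )

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "RateConstants":
        return cls(
            ka=float(mapping["ka"]),
            ke1=float(mapping["ke1"]),
            k23=float(mapping["k23"]),
            ke3=float(mapping["ke3"]),
        )

    def scaled(self, factor: float) -> "RateConstants":
        """All rates multiplied by ``factor`` (time-rescaling of the model)."""
        return RateConstants(
            self.ka * factor, self.ke1 * factor, self.k23 * factor, self.ke3 * factor
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.ka, self.ke1, self.k23, self.ke3])


@dataclass(frozen=True)
class TransferFunction:
    """Rational transfer function num/den with a variable tag ("s" or "z").

    Coefficients are stored highest power first (numpy polynomial order).
    """

    num: np.ndarray
    den: np.ndarray
    var: str = "s"

    def __post_init__(self) -> None:
        object.__setattr__(self, "num", np.atleast_1d(np.asarray(self.num, float)))
        object.__setattr__(self, "den", np.atleast_1d(np.asarray(self.den, float)))
        if self.den[0] == 0.0:
            raise ValueError("denominator leading coefficient must be nonzero")

    def poles(self) -> np.ndarray:
        return np.roots(self.den)

    def __call__(self, x: complex) -> complex:
        return np.polyval(self.num, x) / np.polyval(self.den, x)


@dataclass(frozen=True)
class ContinuousModel:
    """State-space triple (A, b, c) of the continuous-time model."""

    A: np.ndarray
    b: np.ndarray
    c: np.ndarray
    rates: RateConstants | None = field(default=None)

    def __post_init__(self) -> None:
        A = np.asarray(self.A, float)
        b = np.asarray(self.b, float).reshape(-1)
        c = np.asarray(self.c, float).reshape(-1)
        if A.shape[0] != A.shape[1] or A.shape[0] != b.size or b.size != c.size:
            raise ValueError(f"inconsistent shapes: A{A.shape}, b{b.shape}, c{c.shape}")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "c", c)

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @classmethod
    def from_matrices(
        cls,
        A: Sequence[Sequence[float]],
        b: Sequence[float],
        c: Sequence[float],
        *,
        permissive: bool = False,
    ) -> "ContinuousModel":
        """Generic n-compartment constructor.

        With ``permissive=False`` the matrix must be Metzler (non-negative
        off-diagonal entries); ``permissive=True`` admits arbitrary matrices,
        e.g. deliberately destabilized ones used in robustness experiments.
        """
        model = cls(np.asarray(A, float), np.asarray(b, float), np.asarray(c, float))
        if not permissive:
            off = model.A - np.diag(np.diag(model.A))
            if np.any(off < 0):
                raise ValueError("off-diagonal entries of A must be non-negative")
        return model


def build_continuous_model(
    rates: RateConstants,
    *,
    b: Sequence[float] | None = None,
    c: Sequence[float] | None = None,
) -> ContinuousModel:
    """Assemble the three-compartment model from its rate constants.

    The input enters compartment 1 (oral dose into the GI tract) and the
    output is the concentration in compartment 3, unless ``b``/``c`` are
    overridden.
    """
    A = np.array(
        [
            [-(rates.ka + rates.ke1), 0.0, 0.0],
            [rates.ka, -rates.k23, 0.0],
            [0.0, rates.k23, -rates.ke3],
        ]
    )
    b_vec = np.array([1.0, 0.0, 0.0]) if b is None else np.asarray(b, float)
    c_vec = np.array([0.0, 0.0, 1.0]) if c is None else np.asarray(c, float)
    return ContinuousModel(A=A, b=b_vec, c=c_vec, rates=rates)


def continuous_char_roots(model: ContinuousModel) -> tuple[np.ndarray, bool]:
    """Roots of det(sI - A), sorted ascending, and a strict-stability flag.

    For the three-compartment topology the characteristic polynomial factors
    as (s + ka + ke1)(s + k23)(s + ke3), so the roots are the negated rate
    sums.  For a generic matrix the eigenvalues of A are returned instead.
    """
    if model.rates is not None and model.n == 3:
        r = model.rates
        roots = np.sort(np.array([-(r.ka + r.ke1), -r.k23, -r.ke3]))
    else:
        eig = np.linalg.eigvals(model.A)
        roots = np.sort(eig.real) if np.allclose(eig.imag, 0.0) else np.sort_complex(eig)
    stable = bool(np.all(np.real(roots) < 0.0))
    return roots, stable


@dataclass(frozen=True)
class CompartmentalCheck:
    metzler: bool
    mass_balance: bool
    stable: bool

    def __iter__(self):
        return iter((self.metzler, self.mass_balance, self.stable))


def is_compartmental(model: ContinuousModel) -> CompartmentalCheck:
    """Check the positive-system / mass-balance / stability trio.

    metzler: off-diagonal entries of A all >= 0 (state stays non-negative);
    mass_balance: every column sum of A <= 0 (no compartment creates mass);
    stable: all characteristic roots strictly negative.
    """
    A = model.A
    off = A - np.diag(np.diag(A))
    metzler = bool(np.all(off >= 0.0))
    mass_balance = bool(np.all(A.sum(axis=0) <= 1e-12))
    _, stable = continuous_char_roots(model)
    return CompartmentalCheck(metzler, mass_balance, stable)


def continuous_transfer_function(model: ContinuousModel) -> TransferFunction:
    """G(s) = c^T (sI - A)^{-1} b as a polynomial fraction.

    The denominator is the characteristic polynomial det(sI - A); the
    numerator is obtained from the state-space realization.
    """
    from scipy.signal import ss2tf

    num, den = ss2tf(
        model.A, model.b.reshape(-1, 1), model.c.reshape(1, -1), np.zeros((1, 1))
    )
    num = np.atleast_1d(np.squeeze(num))
    # strip the leading zero of a strictly proper numerator
    nz = np.flatnonzero(np.abs(num) > 0)
    num = num[nz[0]:] if nz.size else np.array([0.0])
    return TransferFunction(num=num, den=den, var="s")
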