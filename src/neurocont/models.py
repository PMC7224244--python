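"""Model library: firing-rate nonlinearity, coupling kernels, and a scalar toy model.

The neural field models treated by this package share two ingredients: a
sigmoidal firing-rate function ``f(u) = 1/(1 + exp(-beta*u))`` converting
activity to firing frequency, and an even synaptic coupling kernel ``w``
describing how activity at one location drives activity at another.  The
threshold shift ``u - h`` is applied at call sites, not here.

A scalar toy problem ``g(u; mu) = u**4 - u + mu**2 - 1`` is included as the
standard low-dimensional exercise for the continuation engine: its fixed
points lie on a closed curve in the ``(mu, u)`` plane with a fold at each
end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "firing_rate",
    "CouplingKernel",
    "mexican_hat_1d",
    "exponential_1d",
    "mexican_hat_2d",
    "parametric_mexican_hat_1d",
    "kernel_eval",
    "toy_residual",
]

# exp argument clamp: preserves monotonicity and the (0,1) range at extreme beta*u
_EXP_CLAMP = 700.0


def firing_rate(u, beta):
    """Sigmoidal firing rate ``f(u) = 1/(1 + exp(-beta*u))`` and its derivative.

    Parameters
    ----------
    u : array_like
        Activity (already threshold-shifted by the caller where relevant).
    beta : float
        Steepness, ``beta > 0``.

    Returns
    -------
    f : ndarray or float
        Firing rate, strictly in ``(0, 1)`` for finite input.
    fprime : ndarray or float
        Derivative ``beta * f * (1 - f)``.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("firing_rate: non-finite input")
    z = np.clip(beta * u, -_EXP_CLAMP, _EXP_CLAMP)
    f = 1.0 / (1.0 + np.exp(-z))
    # keep the range strictly open: at extreme arguments 1/(1+e^-z) rounds
    # to exactly 0 or 1 in float64
    f = np.clip(f, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
    fprime = beta * f * (1.0 - f)
    if f.ndim == 0:
        return float(f), float(fprime)
    return f, fprime


@dataclass(frozen=True)
class CouplingKernel:
    """An even synaptic coupling kernel, one of four fixed functional forms.

    kind:
        ``mexican_hat_1d``            ``10 exp(-4 x^2) - 6 exp(-x^2)``
        ``exponential_1d``            ``(1/2) exp(-|x|)`` (unit integral)
        ``mexican_hat_2d``            ``exp(-r^2) - 0.17 exp(-0.2 r^2)``
        ``parametric_mexican_hat_1d`` ``10 exp(-4 x^2) - B exp(-x^2)``

    Kernels are pure pointwise functions; truncation of infinite-domain
    integrals is owned by consumers.
    """

    kind: str
    params: dict = field(default_factory=dict)

    _KINDS = (
        "mexican_hat_1d",
        "exponential_1d",
        "mexican_hat_2d",
        "parametric_mexican_hat_1d",
    )

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}; one of {self._KINDS}")
        if self.kind == "parametric_mexican_hat_1d" and "B" not in self.params:
            raise ValueError("parametric_mexican_hat_1d requires parameter 'B'")

    @property
    def ndim(self) -> int:
        return 2 if self.kind == "mexican_hat_2d" else 1

    def __call__(self, *displacement):
        return kernel_eval(self, *displacement)


def mexican_hat_1d() -> CouplingKernel:
    """Lateral-inhibition kernel ``10 exp(-4x^2) - 6 exp(-x^2)`` on the circle."""
    return CouplingKernel("mexican_hat_1d")


def exponential_1d() -> CouplingKernel:
    """Purely excitatory kernel ``(1/2) exp(-|x|)``; integrates to 1 on the line."""
    return CouplingKernel("exponential_1d")


def mexican_hat_2d() -> CouplingKernel:
    """Radially symmetric kernel ``exp(-r^2) - 0.17 exp(-0.2 r^2)``."""
    return CouplingKernel("mexican_hat_2d")


def parametric_mexican_hat_1d(B: float) -> CouplingKernel:
    """One-parameter family ``10 exp(-4x^2) - B exp(-x^2)``; ``B=6`` recovers
    the fixed Mexican hat."""
    return CouplingKernel("parametric_mexican_hat_1d", {"B": float(B)})


def kernel_eval(kernel: CouplingKernel, *displacement):
    """Evaluate a coupling kernel at a displacement.

    1D kernels take a single offset ``x``; the 2D kernel takes ``(x, y)``.
    Evenness (radial symmetry in 2D) holds to machine precision because only
    ``x**2`` (resp. ``x**2 + y**2``) enters.
    """
    if len(displacement) != kernel.ndim:
        raise ValueError(
            f"kernel {kernel.kind!r} expects {kernel.ndim} displacement "
            f"component(s), got {len(displacement)}"
        )
    if kernel.kind == "mexican_hat_1d":
        x = np.asarray(displacement[0], dtype=float)
        return 10.0 * np.exp(-4.0 * x**2) - 6.0 * np.exp(-(x**2))
    if kernel.kind == "exponential_1d":
        x = np.asarray(displacement[0], dtype=float)
        return 0.5 * np.exp(-np.abs(x))
    if kernel.kind == "parametric_mexican_hat_1d":
        x = np.asarray(displacement[0], dtype=float)
        B = kernel.params["B"]
        return 10.0 * np.exp(-4.0 * x**2) - B * np.exp(-(x**2))
    # mexican_hat_2d
    x = np.asarray(displacement[0], dtype=float)
    y = np.asarray(displacement[1], dtype=float)
    r2 = x**2 + y**2
    return np.exp(-r2) - 0.17 * np.exp(-0.2 * r2)


def toy_residual(u: float, mu: float):
    """Scalar toy fixed-point residual ``g(u; mu) = u^4 - u + mu^2 - 1``.

    Returns ``(g, g_u, g_mu)`` with exact partials ``4u^3 - 1`` and ``2 mu``.
    ``g`` is even in ``mu``, so its zero set is symmetric about ``mu = 0``.
    """
    u = float(u)
    mu = float(mu)
    if not (np.isfinite(u) and np.isfinite(mu)):
        raise ValueError("toy_residual: non-finite input")
    g = u**4 - u + mu**2 - 1.0
    return g, 4.0 * u**3 - 1.0, 2.0 * mu
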