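"""Wendland C2 smoothing kernel in two dimensions.

The kernel has compact support of radius ``2*h`` and is normalised so
that its integral over the plane is exactly one:

    W(r, h) = 7 / (4 pi h^2) * (1 - q/2)^4 * (1 + 2 q),   q = r/h <= 2.

Its radial derivative is ``dW/dr = -(35 / (8 pi h^3)) * q * (1 - q/2)^3``
which is non-positive everywhere on the support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KernelSpec", "wendland_kernel"]


@dataclass(frozen=True)
class KernelSpec:
    """Smoothing length and derived kernel geometry.

    Attributes
    ----------
    h : float
        Smoothing length (um).
    """

    h: float

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("smoothing length h must be positive")

    @property
    def support_radius(self) -> float:
        """Cutoff radius of the compactly supported kernel (um)."""
        return 2.0 * self.h

    @property
    def eta_corr(self) -> float:
        """Singularity correction eta = 0.01 h^2 (um^2)."""
        return 0.01 * self.h**2

    @property
    def w0(self) -> float:
        """Kernel value at zero separation (um^-2)."""
        return 7.0 / (4.0 * np.pi * self.h**2)


def wendland_kernel(r, spec: KernelSpec):
    """Evaluate the Wendland C2 kernel and its radial derivative.

    Parameters
    ----------
    r : array_like
        Non-negative particle separations (um).
    spec : KernelSpec

    Returns
    -------
    w : ndarray
        Kernel values (um^-2); zero for ``r >= 2h``.
    dw_dr : ndarray
        Radial derivative (um^-3); non-positive on the support.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("kernel argument r must be non-negative")
    q = r / spec.h
    inside = q < 2.0
    qc = np.where(inside, q, 2.0)
    alpha = 7.0 / (4.0 * np.pi * spec.h**2)
    one = 1.0 - 0.5 * qc
    w = alpha * one**4 * (1.0 + 2.0 * qc)
    dw = -(5.0 * alpha / spec.h) * qc * one**3
    w = np.where(inside, w, 0.0)
    dw = np.where(inside, dw, 0.0)
    if w.ndim == 0:
        return float(w), float(dw)
    return w, dw
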