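"""Real spherical harmonics and the spiculated radial law.

A tumor phantom surface is the star-shaped graph of a radial profile

    rho(theta, phi) = d + A * Re{Y_l^m(theta, phi)} / max|Re{Y_l^m}|

where ``Y_l^m`` is the complex spherical harmonic with the orthonormal
normalization

    Y_l^m = sqrt((2l+1)/(4 pi) * (l-m)!/(l+m)!) * P_l^m(cos theta) * e^{i m phi}

and ``P_l^m`` the associated Legendre function (Condon-Shortley phase
included, as in scipy and MATLAB).  The offset ``d`` controls spiculatedness:
because the oscillating term is always normalized to peak amplitude ``A``,
a small ``d`` gives deep relative spikes (most spiculated) and a large ``d``
approaches a sphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import sph_harm_y

__all__ = ["HarmonicSpec", "eval_real_harmonic", "radial_profile"]


@dataclass(frozen=True)
class HarmonicSpec:
    """Parameters of one phantom's radial law.

    Attributes
    ----------
    degree_l : int
        Spherical-harmonic degree (angular frequency of the spikes).
    order_m : int
        Spherical-harmonic order, ``0 <= order_m <= degree_l``.
    amplitude_A : float
        Peak radial amplitude of the oscillation, in model units.
    spiculation_d : float
        Radial offset; must exceed ``amplitude_A`` so the radius stays
        positive.  Small values are the most spiculated.
    """

    degree_l: int = 10
    order_m: int = 5
    amplitude_A: float = 10.0
    spiculation_d: float = 11.0

    def __post_init__(self) -> None:
        if self.degree_l < 0 or not 0 <= self.order_m <= self.degree_l:
            raise ValueError(
                f"require 0 <= order_m <= degree_l, got l={self.degree_l}, "
                f"m={self.order_m}"
            )
        if self.amplitude_A < 0:
            raise ValueError("amplitude_A must be non-negative")
        if self.spiculation_d <= self.amplitude_A:
            raise ValueError(
                "spiculation_d must exceed amplitude_A so the radial profile "
                f"stays positive (d={self.spiculation_d}, A={self.amplitude_A})"
            )


def eval_real_harmonic(degree_l: int, order_m: int, theta, phi):
    """Real part of the orthonormal spherical harmonic ``Y_l^m``.

    Parameters
    ----------
    degree_l, order_m : int
        Degree and order with ``0 <= order_m <= degree_l``.
    theta : array_like
        Polar angle in radians, in ``[0, pi]``.
    phi : array_like
        Azimuthal angle in radians.

    Returns
    -------
    ndarray or float
        ``sqrt((2l+1)/4pi (l-m)!/(l+m)!) P_l^m(cos theta) cos(m phi)``.
    """
    if degree_l < 0 or order_m < 0 or order_m > degree_l:
        raise ValueError(
            f"invalid harmonic indices l={degree_l}, m={order_m}: "
            "require 0 <= m <= l"
        )
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    val = np.real(sph_harm_y(degree_l, order_m, theta, phi))
    if val.ndim == 0:
        return float(val)
    return val


def radial_profile(spec: HarmonicSpec, theta, phi, normalizer: float):
    """Radius of the phantom surface at ``(theta, phi)``, in model units.

    ``normalizer`` is ``max |Re{Y_l^m}|`` over the sampling grid in use; the
    profile is then bounded by ``d - A <= rho <= d + A``.
    """
    if not normalizer > 0:
        raise ValueError(f"normalizer must be positive, got {normalizer}")
    y = eval_real_harmonic(spec.degree_l, spec.order_m, theta, phi)
    return spec.spiculation_d + spec.amplitude_A * y / normalizer
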