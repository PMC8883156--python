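"""Ward reflectance model and its perceptual gloss reparameterization.

The Ward model describes a glossy surface with three physical parameters:
diffuse reflectance ``rho_d``, specular energy ``rho_s``, and specular lobe
spread ``alpha``.  Pellacini-style perceptual gloss coordinates re-express
these as contrast gloss ``c`` (how strongly highlights stand out against the
diffuse body color) and distinctness-of-image gloss ``d`` (how sharp reflected
images appear, ``d = 1 - alpha``).  Psychophysical stimulus grids are defined
in (c, d) space; rendering happens in (rho_d, rho_s, alpha) space, so both
directions of the conversion are provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "WardBRDF",
    "PerceptualGloss",
    "DirectionPair",
    "ward_to_perceptual",
    "perceptual_to_ward",
    "eval_ward",
]


@dataclass(frozen=True)
class WardBRDF:
    """Physical Ward parameters.

    Parameters
    ----------
    rho_d : float
        Diffuse reflectance in [0, 1].
    rho_s : float
        Specular energy in [0, 1]; ``rho_d + rho_s <= 1`` for energy
        conservation.
    alpha : float
        Spread of the specular lobe, in (0, 1].  Small alpha means a sharp,
        mirror-like highlight.
    """

    rho_d: float
    rho_s: float
    alpha: float

    def __post_init__(self) -> None:
        if self.rho_d < 0 or self.rho_s < 0:
            raise ValueError("rho_d and rho_s must be nonnegative")
        if self.rho_d + self.rho_s > 1.0 + 1e-12:
            raise ValueError(
                f"energy conservation violated: rho_d + rho_s = "
                f"{self.rho_d + self.rho_s:.6g} > 1"
            )
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")


@dataclass(frozen=True)
class PerceptualGloss:
    """Perceptual gloss coordinates: contrast gloss c and DOI gloss d."""

    c: float
    d: float

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("contrast gloss c must be nonnegative")
        if not (0.0 <= self.d < 1.0 + 1e-12):
            raise ValueError("DOI gloss d must lie in [0, 1]")


@dataclass(frozen=True)
class DirectionPair:
    """Incoming and outgoing directions in spherical angles (radians).

    Polar angles are measured from the surface normal and must lie in
    [0, pi/2); azimuths in [0, 2*pi).
    """

    theta_i: float
    phi_i: float
    theta_o: float
    phi_o: float

    def __post_init__(self) -> None:
        for th in (self.theta_i, self.theta_o):
            if not (0.0 <= th < math.pi / 2):
                raise ValueError("polar angles must lie in [0, pi/2)")

    def swapped(self) -> "DirectionPair":
        """Exchange incoming and outgoing directions (reciprocity test)."""
        return DirectionPair(self.theta_o, self.phi_o, self.theta_i, self.phi_i)


def ward_to_perceptual(b: WardBRDF) -> PerceptualGloss:
    """Convert physical Ward parameters to perceptual gloss (c, d).

    ``c = (rho_s + rho_d/2)**(1/3) - (rho_d/2)**(1/3)`` and ``d = 1 - alpha``.
    c is zero exactly when the specular energy is zero, and grows with
    rho_s; d grows as the lobe tightens.
    """
    c = (b.rho_s + b.rho_d / 2.0) ** (1.0 / 3.0) - (b.rho_d / 2.0) ** (1.0 / 3.0)
    return PerceptualGloss(c=c, d=1.0 - b.alpha)


def perceptual_to_ward(g: PerceptualGloss, rho_d: float) -> WardBRDF:
    """Invert the perceptual mapping at a given diffuse reflectance.

    Closed form: ``rho_s = (c + (rho_d/2)**(1/3))**3 - rho_d/2`` and
    ``alpha = 1 - d``.  Raises if the implied rho_s is negative or breaks
    energy conservation.
    """
    if not (0.0 <= rho_d <= 1.0):
        raise ValueError("rho_d must lie in [0, 1]")
    rho_s = (g.c + (rho_d / 2.0) ** (1.0 / 3.0)) ** 3 - rho_d / 2.0
    # snap round-off from c == 0 to an exact zero
    if abs(rho_s) < 1e-12:
        rho_s = 0.0
    if rho_s < 0.0:
        raise ValueError(f"implied rho_s = {rho_s:.6g} is negative")
    return WardBRDF(rho_d=rho_d, rho_s=rho_s, alpha=1.0 - g.d)


def printed_gloss_value(x: float, decimals: int = 3) -> float:
    """Display convention for gloss parameters: truncate toward zero.

    The published parameter lists drop digits beyond the third decimal
    rather than half-rounding (e.g. c = 0.06797 is printed as 0.067);
    internal computation stays full precision.
    """
    scale = 10**decimals
    return math.trunc(x * scale) / scale


def _unit_vector(theta: float, phi: float) -> np.ndarray:
    return np.array(
        [
            math.sin(theta) * math.cos(phi),
            math.sin(theta) * math.sin(phi),
            math.cos(theta),
        ]
    )


def eval_ward(b: WardBRDF, dirs: DirectionPair) -> float:
    """Evaluate the Ward BRDF (units 1/sr) for one direction pair.

    rho = rho_d/pi
        + rho_s * exp(-tan^2(delta)/alpha^2) / (4 pi alpha^2 sqrt(cos_i cos_o))

    where delta is the angle between the half vector of the incoming and
    outgoing directions and the surface normal (the standard Ward
    convention).  Grazing geometry (either cosine equal to zero) is a domain
    error; the DirectionPair invariant already excludes it.
    """
    cos_i = math.cos(dirs.theta_i)
    cos_o = math.cos(dirs.theta_o)
    if cos_i <= 0.0 or cos_o <= 0.0:
        raise ValueError("grazing or sub-horizon directions are not supported")
    diffuse = b.rho_d / math.pi
    if b.rho_s == 0.0:
        return diffuse
    h = _unit_vector(dirs.theta_i, dirs.phi_i) + _unit_vector(dirs.theta_o, dirs.phi_o)
    h_norm = np.linalg.norm(h)
    if h_norm == 0.0:
        return diffuse  # opposing directions: lobe vanishes (tan delta -> inf)
    cos_delta = float(np.clip(h[2] / h_norm, -1.0, 1.0))
    if cos_delta <= 0.0:
        return diffuse
    tan2_delta = (1.0 - cos_delta**2) / cos_delta**2
    lobe = math.exp(-tan2_delta / b.alpha**2) / (
        4.0 * math.pi * b.alpha**2 * math.sqrt(cos_i * cos_o)
    )
    return diffuse + b.rho_s * lobe


def eval_ward_halfangle(
    b: WardBRDF,
    cos_delta: np.ndarray,
    cos_i: np.ndarray,
    cos_o: np.ndarray,
) -> np.ndarray:
    """Vectorized Ward evaluation from precomputed cosines.

    Used by the renderer, where normals and light directions are per-pixel
    arrays.  Pixels with nonpositive cosines contribute only diffuse.
    """
    cos_delta = np.clip(np.asarray(cos_delta, dtype=float), 0.0, 1.0)
    cos_i = np.asarray(cos_i, dtype=float)
    cos_o = np.asarray(cos_o, dtype=float)
    valid = (cos_i > 1e-6) & (cos_o > 1e-6) & (cos_delta > 1e-6)
    out = np.full(np.broadcast(cos_delta, cos_i, cos_o).shape, b.rho_d / math.pi)
    if b.rho_s == 0.0:
        return out
    cd = np.where(valid, cos_delta, 1.0)
    tan2 = (1.0 - cd**2) / cd**2
    lobe = np.exp(-tan2 / b.alpha**2) / (
        4.0 * math.pi * b.alpha**2 * np.sqrt(np.where(valid, cos_i * cos_o, 1.0))
    )
    out = out + np.where(valid, b.rho_s * lobe, 0.0)
    return out
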