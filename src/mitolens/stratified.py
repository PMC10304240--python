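"""Exact thin-film optics for stratified dielectric media.

Each homogeneous layer is represented by its 2x2 characteristic matrix

    M = [[cos(k0 h),        i sin(k0 h) / gamma],
         [i gamma sin(k0 h), cos(k0 h)        ]]

with ``h = n d cos(theta)`` the apparent thickness along the propagation
direction and ``gamma`` the characteristic admittance of the layer:
``n cos(theta)`` for s polarization and ``n / cos(theta)`` for p (the
vacuum admittance sqrt(eps0/mu0) cancels out of every amplitude ratio
and is set to 1).  The multilayer response is the ordered matrix
product; reflection and transmission amplitudes follow from the
continuity of the tangential fields at the bounding media.

Evanescent layers are carried with complex cosines (+i sqrt(sin^2-1)),
so frustrated total internal reflection through thin layers is exact;
TIR is declared only when the substrate wave is evanescent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Layer",
    "StratifiedStack",
    "TransferMatrix",
    "AngleChain",
    "RTResult",
    "refraction_chain",
    "layer_matrix",
    "stack_rt",
    "stack_rt_arrays",
    "reflectance_grid",
]

#: one-sided offset used to evaluate grazing incidence (radians)
_GRAZING_EPS = 1e-6


@dataclass(frozen=True)
class Layer:
    """A homogeneous lossless film: real refractive index, thickness in nm."""

    n: float
    d: float

    def __post_init__(self):
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")
        if self.d < 0.0:
            raise ValueError("thickness must be non-negative")


@dataclass(frozen=True)
class StratifiedStack:
    """Ordered layer list between two semi-infinite bounding media."""

    n_incident: float
    layers: tuple[Layer, ...] = ()
    n_substrate: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "layers", tuple(self.layers))

    @property
    def total_thickness(self) -> float:
        return float(sum(l.d for l in self.layers))

    @property
    def mean_index(self) -> float:
        """Thickness-weighted mean refractive index of the finite layers."""
        t = self.total_thickness
        if t == 0:
            return float("nan")
        return float(sum(l.n * l.d for l in self.layers) / t)

    def reversed(self) -> "StratifiedStack":
        return StratifiedStack(self.n_substrate, tuple(reversed(self.layers)), self.n_incident)


@dataclass(frozen=True)
class TransferMatrix:
    m11: complex
    m12: complex
    m21: complex
    m22: complex

    @property
    def determinant(self) -> complex:
        return self.m11 * self.m22 - self.m12 * self.m21

    def __matmul__(self, other: "TransferMatrix") -> "TransferMatrix":
        return TransferMatrix(
            self.m11 * other.m11 + self.m12 * other.m21,
            self.m11 * other.m12 + self.m12 * other.m22,
            self.m21 * other.m11 + self.m22 * other.m21,
            self.m21 * other.m12 + self.m22 * other.m22,
        )


@dataclass(frozen=True)
class AngleChain:
    """Snell-propagated (complex-capable) cosines through a stack.

    ``snell`` is the conserved quantity ``n0 sin(theta0)``.
    """

    snell: float
    cos_incident: complex
    cos_layers: tuple[complex, ...]
    cos_substrate: complex
    k0: float
    tir: bool

    def cos_in_medium(self, n: float) -> complex:
        """Propagation-angle cosine in a medium of index ``n``."""
        return complex(_complex_cos(np.array((self.snell / n) ** 2)))


@dataclass(frozen=True)
class RTResult:
    """Complex amplitudes and energy fractions for one polarization."""

    r: complex
    t: complex
    R: float
    T: float
    tir: bool


def _complex_cos(sin2):
    """cos(theta) from sin^2(theta); +i sqrt(sin^2 - 1) when evanescent."""
    return np.where(sin2 <= 1.0, np.sqrt(np.maximum(1.0 - sin2, 0.0)) + 0j,
                    1j * np.sqrt(np.maximum(sin2 - 1.0, 0.0)))


def refraction_chain(stack: StratifiedStack, theta0: float, wavelength: float) -> AngleChain:
    """Propagate the Snell invariant ``n0 sin(theta0)`` through the stack."""
    if not (0.0 <= theta0 <= np.pi / 2):
        raise ValueError("theta0 must lie in [0, pi/2]")
    theta0 = min(theta0, np.pi / 2 - _GRAZING_EPS)
    s0 = stack.n_incident * np.sin(theta0)
    cos_layers = tuple(complex(_complex_cos(np.array((s0 / l.n) ** 2))) for l in stack.layers)
    cos_sub = complex(_complex_cos(np.array((s0 / stack.n_substrate) ** 2)))
    return AngleChain(
        snell=float(s0),
        cos_incident=complex(np.cos(theta0)),
        cos_layers=cos_layers,
        cos_substrate=cos_sub,
        k0=2.0 * np.pi / wavelength,
        tir=bool(cos_sub.imag > 0),
    )


def _gamma(n, cos_theta, polarization: str):
    if polarization == "s":
        return n * cos_theta
    if polarization == "p":
        return n / cos_theta
    raise ValueError("polarization must be 's' or 'p'")


def layer_matrix(layer: Layer, chain: AngleChain, polarization: str) -> TransferMatrix:
    """Characteristic matrix of one layer at the chain's angle."""
    cos_theta = chain.cos_in_medium(layer.n)
    delta = chain.k0 * layer.n * layer.d * cos_theta
    g = _gamma(layer.n, cos_theta, polarization)
    c, s = np.cos(delta), np.sin(delta)
    return TransferMatrix(c, 1j * s / g, 1j * g * s, c)


def stack_rt(stack: StratifiedStack, theta0: float, wavelength: float,
             polarization: str) -> RTResult:
    """Reflection/transmission of the full stack for one polarization.

    Sign convention: at normal incidence on a bare interface,
    ``r = (n0 - ns) / (n0 + ns)`` (so 1.0 -> 1.5 gives r = -0.2).
    """
    r, t, R, T, tir = stack_rt_arrays(stack, np.array([theta0]), wavelength, polarization)
    return RTResult(complex(r[0]), complex(t[0]), float(R[0]), float(T[0]), bool(tir[0]))


def stack_rt_arrays(stack: StratifiedStack, theta0, wavelength, polarization: str):
    """Vectorised :func:`stack_rt` over an array of incidence angles.

    Returns ``(r, t, R, T, tir)`` arrays broadcast over ``theta0`` (and
    ``wavelength`` if it is an array of the same shape).
    """
    theta0 = np.minimum(np.asarray(theta0, float), np.pi / 2 - _GRAZING_EPS)
    k0 = 2.0 * np.pi / np.asarray(wavelength, float)
    s0 = stack.n_incident * np.sin(theta0)
    cos0 = np.cos(theta0).astype(complex)
    cos_s = _complex_cos((s0 / stack.n_substrate) ** 2)

    m11 = np.ones_like(cos0)
    m12 = np.zeros_like(cos0)
    m21 = np.zeros_like(cos0)
    m22 = np.ones_like(cos0)
    for layer in stack.layers:
        cl = _complex_cos((s0 / layer.n) ** 2)
        delta = k0 * layer.n * layer.d * cl
        g = _gamma(layer.n, cl, polarization)
        c, s = np.cos(delta), np.sin(delta)
        a11, a12, a21, a22 = c, 1j * s / g, 1j * g * s, c
        m11, m12, m21, m22 = (
            m11 * a11 + m12 * a21,
            m11 * a12 + m12 * a22,
            m21 * a11 + m22 * a21,
            m21 * a12 + m22 * a22,
        )

    g0 = _gamma(stack.n_incident, cos0, polarization)
    gs = _gamma(stack.n_substrate, cos_s, polarization)
    denom = g0 * m11 + g0 * gs * m12 + m21 + gs * m22
    if np.any(denom == 0):
        raise ZeroDivisionError("singular stack response (zero denominator)")
    r = (g0 * m11 + g0 * gs * m12 - m21 - gs * m22) / denom
    t = 2.0 * g0 / denom
    if polarization == "p":
        t = t * cos0 / np.where(cos_s == 0, 1.0, cos_s)
    R = np.abs(r) ** 2
    # Poynting flux ratio for the E-field amplitude ratio t
    T = np.real(stack.n_substrate * cos_s) / np.real(stack.n_incident * cos0) * np.abs(t) ** 2
    tir = cos_s.imag > 0
    T = np.where(tir, 0.0, T)
    R = np.where(tir, 1.0, R)
    return r, t, R, T, tir


def reflectance_grid(stack: StratifiedStack, wavelengths=None, angles_deg=None) -> pd.DataFrame:
    """Polarized reflectance table over a wavelength x angle grid.

    Defaults reproduce the fitting grid: 400-800 nm in 5 nm steps and
    0-90 degrees in 1 degree steps (90 degrees evaluated one-sided).
    Returns a tidy DataFrame with columns ``wavelength_nm``,
    ``angle_deg``, ``R_s``, ``R_p``.
    """
    if wavelengths is None:
        wavelengths = np.arange(400.0, 800.0 + 2.5, 5.0)
    if angles_deg is None:
        angles_deg = np.arange(0.0, 91.0, 1.0)
    wavelengths = np.asarray(wavelengths, float)
    angles = np.deg2rad(np.asarray(angles_deg, float))
    rows = []
    for lam in wavelengths:
        _, _, Rs, _, _ = stack_rt_arrays(stack, angles, lam, "s")
        _, _, Rp, _, _ = stack_rt_arrays(stack, angles, lam, "p")
        rows.append(
            pd.DataFrame(
                {
                    "wavelength_nm": lam,
                    "angle_deg": np.asarray(angles_deg, float),
                    "R_s": Rs.real,
                    "R_p": Rp.real,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def grid_reflectances(stack: StratifiedStack, wavelengths, angles_rad):
    """(n_lambda, n_theta) arrays of R_s and R_p; fast path for fitting.

    Broadcasts wavelength down the rows and angle across the columns in
    a single matrix-stack evaluation.
    """
    lam = np.asarray(wavelengths, float)[:, None]
    th = np.asarray(angles_rad, float)[None, :]
    _, _, Rs, _, _ = stack_rt_arrays(stack, th, lam, "s")
    _, _, Rp, _, _ = stack_rt_arrays(stack, th, lam, "p")
    shape = (lam.size, th.size)
    return np.broadcast_to(Rs, shape).copy(), np.broadcast_to(Rp, shape).copy()
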