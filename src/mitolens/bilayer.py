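"""Equivalent closed-bilayer fit for the 25-medium membrane wall.

The inter-compartment wall of the lens mitochondrion is a sandwich of 12
lipid films (n = 1.70, d = 1.8 nm) alternating with 11 cytosolic gaps
(n = 1.38, d = 10 nm) between cytosolic bounding media (n = 1.33) — 25
media in total, 131.6 nm of finite thickness.  For coarse meshing and
for physical insight the wall can be replaced by a four-parameter
"closed bilayer" X = {na, nb, da, db} (outer index/thickness, core
index/thickness) whose polarized reflectance over a wavelength x angle
grid best matches the full wall:

    min_X  sum_ij |R_s(l_i, t_j) - R^_s| + |R_p(l_i, t_j) - R^_p|

Two candidate topologies are supported: a plain two-layer stack
[na, da][nb, db] and the closed symmetric sandwich
[na, da][nb, db][na, da] ("aba", the default); the core index of the
best fit comes out equal to the surrounding cytosol, so the equivalent
structure is a pair of thin high-index films spaced by cytosol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .stratified import Layer, StratifiedStack, grid_reflectances

__all__ = [
    "BilayerParams",
    "reference_wall",
    "bilayer_stack",
    "objective",
    "fit_bilayer",
    "FitResult",
    "DEFAULT_WAVELENGTHS",
    "DEFAULT_ANGLES_DEG",
]

DEFAULT_WAVELENGTHS = np.arange(400.0, 800.0 + 2.5, 5.0)
DEFAULT_ANGLES_DEG = np.arange(0.0, 91.0, 1.0)

#: default optimizer bounds.  The index range spans the modelled
#: constituents, cytosol (1.33) to pure lipid (1.70); BilayerParams
#: itself admits the wider domain [1, 2] x (0, 500) nm.
BOUNDS = ((1.33, 1.70), (1.33, 1.70), (0.5, 300.0), (0.5, 300.0))


@dataclass(frozen=True)
class BilayerParams:
    """Closed-bilayer parameters: outer (a) and core (b) index/thickness."""

    na: float
    nb: float
    da: float
    db: float

    def __post_init__(self):
        if not (1.0 <= self.na <= 2.0 and 1.0 <= self.nb <= 2.0):
            raise ValueError("refractive indices must lie in [1, 2]")
        if not (0.0 < self.da < 500.0 and 0.0 < self.db < 500.0):
            raise ValueError("thicknesses must lie in (0, 500) nm")

    def as_array(self) -> np.ndarray:
        return np.array([self.na, self.nb, self.da, self.db])


def reference_wall(
    n_bound: float = 1.33,
    n_lipid: float = 1.70,
    d_lipid: float = 1.8,
    n_gap: float = 1.38,
    d_gap: float = 10.0,
    n_bilayers: int = 12,
) -> StratifiedStack:
    """The 25-medium wall: 12 lipid films alternating with 11 gaps.

    Lipid films are outermost on both sides; layer order and counts can
    be overridden for sensitivity studies.
    """
    layers: list[Layer] = []
    for i in range(n_bilayers):
        layers.append(Layer(n_lipid, d_lipid))
        if i < n_bilayers - 1:
            layers.append(Layer(n_gap, d_gap))
    return StratifiedStack(n_bound, tuple(layers), n_bound)


def bilayer_stack(params: BilayerParams, n_bound: float = 1.33,
                  topology: str = "aba") -> StratifiedStack:
    """Build the candidate stack for one of the two supported topologies.

    ``aba`` (default) is the closed sandwich [na, da][nb, db][na, da] —
    an outer leaflet of thickness ``da`` on each face of the core; it is
    the variant that reproduces the published equivalent-wall
    parameters.  ``two_layer`` is the minimal reading [na, da][nb, db].
    """
    if topology == "two_layer":
        layers = (Layer(params.na, params.da), Layer(params.nb, params.db))
    elif topology == "aba":
        layers = (
            Layer(params.na, params.da),
            Layer(params.nb, params.db),
            Layer(params.na, params.da),
        )
    else:
        raise ValueError("topology must be 'two_layer' or 'aba'")
    return StratifiedStack(n_bound, layers, n_bound)


def objective(
    params: BilayerParams,
    reference: StratifiedStack,
    wavelengths=None,
    angles_deg=None,
    topology: str = "aba",
    _reference_grids=None,
) -> float:
    """L1 distance between the polarized reflectance grids of the
    candidate bilayer and the reference wall."""
    wavelengths = DEFAULT_WAVELENGTHS if wavelengths is None else np.asarray(wavelengths, float)
    angles = np.deg2rad(DEFAULT_ANGLES_DEG if angles_deg is None else np.asarray(angles_deg, float))
    if _reference_grids is None:
        _reference_grids = grid_reflectances(reference, wavelengths, angles)
    Rs_ref, Rp_ref = _reference_grids
    cand = bilayer_stack(params, reference.n_incident, topology)
    Rs, Rp = grid_reflectances(cand, wavelengths, angles)
    return float(np.abs(Rs - Rs_ref).sum() + np.abs(Rp - Rp_ref).sum())


@dataclass(frozen=True)
class FitResult:
    params: BilayerParams
    objective: float
    topology: str
    n_starts: int
    converged: bool


def fit_bilayer(
    reference: StratifiedStack,
    init: BilayerParams | None = None,
    bounds=BOUNDS,
    wavelengths=None,
    angles_deg=None,
    topology: str = "aba",
    n_starts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Fit the closed bilayer to the reference wall's reflectance.

    A bound-constrained local minimizer is multi-started from ``init``
    (if given) plus ``n_starts`` scrambled-Sobol points in the bounds
    box; the best local minimum is reported.  The objective descends
    from every start by construction of the local search.
    """
    wavelengths = DEFAULT_WAVELENGTHS if wavelengths is None else np.asarray(wavelengths, float)
    angles_deg = DEFAULT_ANGLES_DEG if angles_deg is None else np.asarray(angles_deg, float)
    angles = np.deg2rad(angles_deg)
    ref_grids = grid_reflectances(reference, wavelengths, angles)

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def fun(x):
        x = np.clip(x, lo, hi)
        p = BilayerParams(*x)
        return objective(p, reference, wavelengths, angles_deg, topology, ref_grids)

    starts = []
    if init is not None:
        starts.append(init.as_array())
    sob = qmc.Sobol(d=4, scramble=True, seed=seed)
    starts.extend(lo + (hi - lo) * sob.random(n_starts))

    best = None
    any_ok = False
    for x0 in starts:
        res = minimize(fun, x0, method="Powell", bounds=bounds,
                       options={"xtol": 1e-6, "ftol": 1e-10, "maxiter": 4000})
        # Nelder-Mead polish: Powell's line searches stall in the long
        # curved valley this objective has; the simplex finishes the job
        polish = minimize(fun, np.clip(res.x, lo, hi), method="Nelder-Mead",
                          options={"xatol": 1e-7, "fatol": 1e-11, "maxiter": 4000})
        res = polish if polish.fun < res.fun else res
        any_ok = any_ok or res.success
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("optimizer produced no result")
    x = np.clip(best.x, lo, hi)
    return FitResult(
        params=BilayerParams(*x),
        objective=float(best.fun),
        topology=topology,
        n_starts=len(starts),
        converged=bool(any_ok),
    )
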