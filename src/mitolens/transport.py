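"""Polarized Monte Carlo ray transport with photon splitting.

A plane wave is represented by a grid of coherent ray packets fired
along +x from a disc in the y-z plane that matches the sphere radius,
so every packet traverses the mitochondrion.  Each packet carries
complex s- and p-amplitudes in a transverse basis, an accumulated
optical phase (folded into the amplitudes) and an energy weight
``|As|^2 + |Ap|^2``.

At every membrane crossing (gyroid mid-surface) the full 25-medium wall
stack is evaluated at the local incidence angle via the characteristic
matrix method; at the sphere envelope a bare Fresnel interface between
the inner compartment and the exterior applies.  Amplitudes of the two
children are the parent amplitudes times the complex reflection /
transmission coefficients (transmission rescaled so that squared
magnitude equals the transmitted energy fraction), so the energy ledger
closes exactly below total internal reflection, where the reflected
child carries everything.

Splitting strategies:

* ``"i"``   Russian roulette: one child survives with probability equal
  to its energy share and is rescaled to conserve energy in expectation.
* ``"ii"``  (default) both children are pursued; a child below
  ``epsilon`` times the per-ray input energy is dropped into the
  discard ledger.  Fully deterministic.
* ``"iii"`` like (ii), with the transmitted child fanned into a
  symmetric 3-ray angular kernel to emulate small-scale diffraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    MitochondrionModel,
    RegionLabel,
    _march_to_surface,
    _sphere_exit_distance,
    gyroid_g,
    gyroid_grad,
)
from .stratified import StratifiedStack, stack_rt_arrays

__all__ = [
    "LightPacket",
    "SourceGrid",
    "EnergyLedger",
    "ExitRecords",
    "make_source",
    "scatter",
    "trace",
]

#: nudge distance off a surface after a scatter event, nm
_SURFACE_NUDGE = 0.2
#: resolution of the precomputed wall r/t lookup tables (angles in [0, pi/2])
_TABLE_SIZE = 2048
#: generation cap for the strategy-iii angular fan (tree grows 3^depth)
_FAN_MAX_DEPTH = 6


@dataclass
class SourceGrid:
    """Square source grid in the y-z plane, direction +x.

    ``polarization`` is a Jones vector (complex pair) in the (y, z)
    transverse basis; it is normalized on construction.
    """

    spacing: float = 28.0
    extent_radius: float = 1000.0
    polarization: tuple = (1.0, 0.0)
    wavelength: float = 550.0

    def __post_init__(self):
        if not (2.0 <= self.spacing <= 50.0):
            raise ValueError("spacing must lie in [2, 50] nm")
        j = np.asarray(self.polarization, complex)
        self.polarization = tuple(j / np.linalg.norm(j))


@dataclass
class LightPacket:
    """One coherent ray packet (scalar convenience view; the tracing
    engine itself is array-based)."""

    origin: np.ndarray
    direction: np.ndarray
    wavelength: float
    amplitude_s: complex
    amplitude_p: complex
    s_basis: np.ndarray
    region: RegionLabel = RegionLabel.exterior
    depth: int = 0

    @property
    def energy(self) -> float:
        return abs(self.amplitude_s) ** 2 + abs(self.amplitude_p) ** 2


@dataclass
class EnergyLedger:
    """Exact accounting of where the input energy went."""

    input: float = 0.0
    exited_forward: float = 0.0
    exited_backward: float = 0.0
    discarded_epsilon: float = 0.0
    discarded_depth: float = 0.0
    n_events: int = 0
    n_exit_records: int = 0

    @property
    def exited(self) -> float:
        return self.exited_forward + self.exited_backward

    @property
    def discarded(self) -> float:
        return self.discarded_epsilon + self.discarded_depth

    @property
    def closure_error(self) -> float:
        """|input - exited - discarded| as a fraction of the input."""
        if self.input == 0:
            return 0.0
        return abs(self.input - self.exited - self.discarded) / self.input

    def warn_depth(self) -> bool:
        """True if more than 0.1% of the input energy hit the depth cap."""
        return self.input > 0 and self.discarded_depth > 1e-3 * self.input


class ExitRecords:
    """Struct-of-arrays container for packets that left the sphere."""

    def __init__(self, position, direction, amp_s, amp_p, s_basis, wavelength):
        self.position = np.asarray(position, float).reshape(-1, 3)
        self.direction = np.asarray(direction, float).reshape(-1, 3)
        self.amp_s = np.asarray(amp_s, complex).ravel()
        self.amp_p = np.asarray(amp_p, complex).ravel()
        self.s_basis = np.asarray(s_basis, float).reshape(-1, 3)
        self.wavelength = float(wavelength)

    def __len__(self):
        return self.position.shape[0]

    @property
    def energy(self) -> np.ndarray:
        return np.abs(self.amp_s) ** 2 + np.abs(self.amp_p) ** 2

    @property
    def forward(self) -> "ExitRecords":
        m = self.direction[:, 0] > 0
        return self._mask(m)

    @property
    def backward(self) -> "ExitRecords":
        return self._mask(self.direction[:, 0] <= 0)

    def _mask(self, m) -> "ExitRecords":
        return ExitRecords(
            self.position[m], self.direction[m], self.amp_s[m],
            self.amp_p[m], self.s_basis[m], self.wavelength,
        )

    @staticmethod
    def concatenate(parts, wavelength):
        parts = [p for p in parts if len(p)]
        if not parts:
            z = np.zeros((0, 3))
            return ExitRecords(z, z, np.zeros(0, complex), np.zeros(0, complex), z, wavelength)
        return ExitRecords(
            np.concatenate([p.position for p in parts]),
            np.concatenate([p.direction for p in parts]),
            np.concatenate([p.amp_s for p in parts]),
            np.concatenate([p.amp_p for p in parts]),
            np.concatenate([p.s_basis for p in parts]),
            wavelength,
        )


# ------------------------------------------------------------------ source

def make_source(grid: SourceGrid, model: MitochondrionModel) -> dict:
    """Build the packet arrays for a plane-wave source.

    Rays sit on a square y-z grid restricted to the disc of the sphere
    radius (closest approach <= R guarantees every ray meets the
    sphere), start one radius upstream of the front pole, travel along
    +x, and share phase, polarization and wavelength.  Per-ray energy
    is 1, so the packet count is the total input energy.
    """
    R = min(grid.extent_radius, model.radius)
    n_half = int(np.floor(R / grid.spacing))
    coords = np.arange(-n_half, n_half + 1) * grid.spacing
    yy, zz = np.meshgrid(coords, coords, indexing="ij")
    keep = yy**2 + zz**2 <= R**2 - 1e-9
    y, z = yy[keep], zz[keep]
    n = y.size
    x0 = model.center[0] - model.radius - grid.spacing
    pos = np.column_stack([np.full(n, x0), y + model.center[1], z + model.center[2]])
    dirs = np.tile([1.0, 0.0, 0.0], (n, 1))
    svec = np.tile([0.0, 1.0, 0.0], (n, 1))  # s along y, p along z
    jy, jz = grid.polarization
    amp_s = np.full(n, jy, complex)
    amp_p = np.full(n, jz, complex)
    return {
        "position": pos,
        "direction": dirs,
        "s_basis": svec,
        "amp_s": amp_s,
        "amp_p": amp_p,
        "wavelength": grid.wavelength,
    }


def source_packets(grid: SourceGrid, model: MitochondrionModel) -> list[LightPacket]:
    """:func:`make_source` as a list of :class:`LightPacket` objects."""
    src = make_source(grid, model)
    return [
        LightPacket(
            origin=src["position"][i],
            direction=src["direction"][i],
            wavelength=src["wavelength"],
            amplitude_s=complex(src["amp_s"][i]),
            amplitude_p=complex(src["amp_p"][i]),
            s_basis=src["s_basis"][i],
        )
        for i in range(len(src["amp_s"]))
    ]


# ------------------------------------------------------- wall lookup tables

class _WallTables:
    """Complex r/t of the wall stack vs incidence angle, both crossing
    directions, both polarizations, linearly interpolated.

    Transmission amplitudes are pre-scaled by sqrt(T/|t|^2) so that the
    squared magnitude of a child amplitude is its energy share.
    """

    def __init__(self, model: MitochondrionModel, wavelength: float):
        self.enabled = model.wall_stack is not None
        if not self.enabled:
            return
        self.theta = np.linspace(0.0, np.pi / 2, _TABLE_SIZE)
        nA, nB = model.n_compartment_A, model.n_compartment_B
        inner = model.wall_stack.layers
        self.tables = {}
        for key, (n0, ns) in {"AB": (nA, nB), "BA": (nB, nA)}.items():
            stack = StratifiedStack(n0, inner if key == "AB" else tuple(reversed(inner)), ns)
            per_pol = {}
            for pol in ("s", "p"):
                r, t, R, T, tir = stack_rt_arrays(stack, self.theta, wavelength, pol)
                scale = np.sqrt(np.where(np.abs(t) > 0, T / np.maximum(np.abs(t) ** 2, 1e-300), 0.0))
                te = t * scale
                # enforce exact losslessness per node so the energy
                # ledger closes to float accumulation after lookup
                norm = np.sqrt(np.abs(r) ** 2 + np.abs(te) ** 2)
                norm = np.where(norm > 0, norm, 1.0)
                per_pol[pol] = (r / norm, te / norm, tir)
            per_pol["tir"] = per_pol["s"][2]
            self.tables[key] = per_pol

    def lookup(self, key: str, theta: np.ndarray):
        """Interpolated (rs, rp, ts_eff, tp_eff, tir) at angles theta."""
        tab = self.tables[key]
        x = np.clip(theta, 0.0, np.pi / 2)
        idx = x / (np.pi / 2) * (_TABLE_SIZE - 1)
        i0 = np.clip(idx.astype(int), 0, _TABLE_SIZE - 2)
        f = idx - i0
        out = []
        for pol in ("s", "p"):
            r, te, _ = tab[pol]
            ri = r[i0] * (1 - f) + r[i0 + 1] * f
            ti = te[i0] * (1 - f) + te[i0 + 1] * f
            norm = np.sqrt(np.abs(ri) ** 2 + np.abs(ti) ** 2)
            norm = np.where(norm > 0, norm, 1.0)
            out.append(ri / norm)
            out.append(ti / norm)
        tir = tab["tir"][np.clip(np.round(idx).astype(int), 0, _TABLE_SIZE - 1)]
        return out[0], out[2], out[1], out[3], tir


def _fresnel_interface(n_i, n_t, cos_i):
    """Bare-interface Fresnel coefficients, energy-normalised t.

    Returns (rs, rp, ts_eff, tp_eff, tir, cos_t) for scalar media and an
    array of incidence cosines.
    """
    sin_i2 = 1.0 - cos_i**2
    sin_t2 = (n_i / n_t) ** 2 * sin_i2
    tir = sin_t2 > 1.0
    cos_t = np.sqrt(np.maximum(1.0 - sin_t2, 0.0))
    denom_s = n_i * cos_i + n_t * cos_t
    denom_p = n_t * cos_i + n_i * cos_t
    rs = np.where(tir, 1.0, (n_i * cos_i - n_t * cos_t) / np.where(denom_s == 0, 1, denom_s))
    rp = np.where(tir, 1.0, (n_i * cos_t - n_t * cos_i) / np.where(denom_p == 0, 1, denom_p))
    ts = 2 * n_i * cos_i / np.where(denom_s == 0, 1, denom_s)
    tp = 2 * n_i * cos_i / np.where(denom_p == 0, 1, denom_p)
    flux = np.where(tir, 0.0, (n_t * cos_t) / np.maximum(n_i * cos_i, 1e-300))
    ts_eff = np.where(tir, 0.0, ts) * np.sqrt(flux)
    tp_eff = np.where(tir, 0.0, tp) * np.sqrt(flux)
    return rs + 0j, rp + 0j, ts_eff + 0j, tp_eff + 0j, tir, cos_t


# --------------------------------------------------------------- basis math

def _rotate_basis(dirs, svec_old, amp_s, amp_p, svec_new):
    """Re-express transverse amplitudes in a new s basis (same dirs)."""
    p_old = np.cross(dirs, svec_old)
    p_new = np.cross(dirs, svec_new)
    c = np.einsum("ij,ij->i", svec_old, svec_new)
    s = np.einsum("ij,ij->i", p_old, svec_new)
    amp_s_new = amp_s * c + amp_p * s
    amp_p_new = amp_s * np.einsum("ij,ij->i", svec_old, p_new) + amp_p * np.einsum(
        "ij,ij->i", p_old, p_new
    )
    return amp_s_new, amp_p_new


def _incidence_basis(dirs, normals, svec_old):
    """Unit s vector of the plane of incidence; falls back to the
    previous basis at (near-)normal incidence."""
    s = np.cross(dirs, normals)
    norm = np.linalg.norm(s, axis=1)
    degenerate = norm < 1e-9
    safe = np.where(degenerate[:, None], svec_old, s / np.where(norm[:, None] == 0, 1, norm[:, None]))
    n2 = np.linalg.norm(safe, axis=1, keepdims=True)
    return safe / n2


# -------------------------------------------------------------- the tracer

def scatter(packet: LightPacket, hit, model: MitochondrionModel):
    """Split one packet at a surface hit into (transmitted, reflected).

    Scalar wrapper around the array engine's physics; children are
    ``None`` where the corresponding branch carries no energy (TIR, or
    an index-matched null interface for the reflected branch).
    """
    tables = _WallTables(model, packet.wavelength)
    state = {
        "position": packet.origin.reshape(1, 3),
        "direction": packet.direction.reshape(1, 3),
        "s_basis": packet.s_basis.reshape(1, 3),
        "amp_s": np.array([packet.amplitude_s]),
        "amp_p": np.array([packet.amplitude_p]),
        "region": np.array([int(hit.from_region)], np.int8),
        "depth": np.array([packet.depth]),
    }
    hit_pos = hit.position.reshape(1, 3)
    # orient normal along propagation
    n = hit.normal.reshape(1, 3).copy()
    flip = np.einsum("ij,ij->i", state["direction"], n) < 0
    n[flip] *= -1
    to_region = np.array([int(hit.to_region)], np.int8)
    trans, refl = _scatter_arrays(
        model, tables, packet.wavelength, state, hit_pos,
        np.array([hit.path_length]), n, to_region,
    )

    def mk(st):
        if st is None or st["amp_s"].size == 0:
            return None
        e = float(np.abs(st["amp_s"][0]) ** 2 + np.abs(st["amp_p"][0]) ** 2)
        if e <= 1e-300:
            return None
        return LightPacket(
            origin=st["position"][0],
            direction=st["direction"][0],
            wavelength=packet.wavelength,
            amplitude_s=complex(st["amp_s"][0]),
            amplitude_p=complex(st["amp_p"][0]),
            s_basis=st["s_basis"][0],
            region=RegionLabel(int(st["region"][0])),
            depth=packet.depth + 1,
        )

    return mk(trans), mk(refl)


def _scatter_arrays(model, tables, wavelength, state, hit_pos, path_len, normals, to_region):
    """Vectorised scatter of all packets in ``state`` at their hits.

    ``normals`` must already be oriented along propagation.  Returns
    (transmitted_state, reflected_state); amplitudes include the
    propagation phase to the hit and the r/t coefficients.
    """
    dirs = state["direction"]
    region = state["region"]
    n_from = np.where(region == int(RegionLabel.compartment_A),
                      model.n_compartment_A,
                      np.where(region == int(RegionLabel.compartment_B),
                               model.n_compartment_B, model.n_exterior))
    n_to = np.where(to_region == int(RegionLabel.compartment_A),
                    model.n_compartment_A,
                    np.where(to_region == int(RegionLabel.compartment_B),
                             model.n_compartment_B, model.n_exterior))

    cos_i = np.clip(np.einsum("ij,ij->i", dirs, normals), 0.0, 1.0)
    theta = np.arccos(cos_i)

    # rotate amplitudes into the local plane of incidence
    svec_new = _incidence_basis(dirs, normals, state["s_basis"])
    amp_s, amp_p = _rotate_basis(dirs, state["s_basis"], state["amp_s"], state["amp_p"], svec_new)

    # propagation phase since the previous event
    phase = np.exp(1j * 2.0 * np.pi * n_from * path_len / wavelength)
    amp_s = amp_s * phase
    amp_p = amp_p * phase

    # coefficients: wall tables for interior crossings, Fresnel at the sphere
    on_sphere = (region == int(RegionLabel.exterior)) | (to_region == int(RegionLabel.exterior))
    rs = np.empty(len(dirs), complex)
    rp = np.empty(len(dirs), complex)
    ts = np.empty(len(dirs), complex)
    tp = np.empty(len(dirs), complex)
    tir = np.zeros(len(dirs), bool)
    cos_t = np.empty(len(dirs))

    if np.any(on_sphere):
        m = on_sphere
        frs, frp, fts, ftp, ftir, fct = _fresnel_interface(n_from[m], n_to[m], cos_i[m])
        rs[m], rp[m], ts[m], tp[m], tir[m], cos_t[m] = frs, frp, fts, ftp, ftir, fct
    inner = ~on_sphere
    if np.any(inner):
        m = inner
        a_to_b = region[m] == int(RegionLabel.compartment_A)
        for key, sel in (("AB", a_to_b), ("BA", ~a_to_b)):
            if not np.any(sel):
                continue
            idx = np.flatnonzero(m)[sel]
            krs, krp, kts, ktp, _ = tables.lookup(key, theta[idx])
            # exact Snell criterion at the bounding compartments; under
            # TIR the wall reflection is unit-modulus (phase retained)
            ktir = (n_from[idx] / n_to[idx]) ** 2 * (1.0 - cos_i[idx] ** 2) > 1.0
            krs = np.where(ktir, krs / np.maximum(np.abs(krs), 1e-300), krs)
            krp = np.where(ktir, krp / np.maximum(np.abs(krp), 1e-300), krp)
            rs[idx], rp[idx], ts[idx], tp[idx], tir[idx] = krs, krp, kts, ktp, ktir
        sin_t2 = (n_from[m] / n_to[m]) ** 2 * (1.0 - cos_i[m] ** 2)
        cos_t[m] = np.sqrt(np.maximum(1.0 - sin_t2, 0.0))

    # child directions
    mu = n_from / n_to
    d_trans = mu[:, None] * dirs + (cos_t - mu * cos_i)[:, None] * normals
    nrm = np.linalg.norm(d_trans, axis=1, keepdims=True)
    d_trans = d_trans / np.where(nrm == 0, 1, nrm)
    d_refl = dirs - 2.0 * cos_i[:, None] * normals
    d_refl /= np.linalg.norm(d_refl, axis=1, keepdims=True)

    depth = state["depth"] + 1
    trans = {
        "position": hit_pos + _SURFACE_NUDGE * normals,
        "direction": d_trans,
        "s_basis": svec_new,
        "amp_s": np.where(tir, 0, amp_s * ts),
        "amp_p": np.where(tir, 0, amp_p * tp),
        "region": to_region.copy(),
        "depth": depth,
    }
    refl = {
        "position": hit_pos - _SURFACE_NUDGE * normals,
        "direction": d_refl,
        "s_basis": svec_new,
        "amp_s": amp_s * rs,
        "amp_p": amp_p * rp,
        "region": region.copy(),
        "depth": depth,
    }
    return trans, refl


def _energy(state) -> np.ndarray:
    return np.abs(state["amp_s"]) ** 2 + np.abs(state["amp_p"]) ** 2


def _take(state, m):
    return {k: (v[m] if isinstance(v, np.ndarray) else v) for k, v in state.items()}


def _rodrigues(vec, axis, angle):
    """Rotate vectors about unit axes by per-row angles."""
    c = np.cos(angle)[:, None]
    s = np.sin(angle)[:, None]
    return vec * c + np.cross(axis, vec) * s + axis * np.einsum(
        "ij,ij->i", axis, vec
    )[:, None] * (1 - c)


def trace(
    model: MitochondrionModel,
    source,
    strategy: str = "ii",
    epsilon: float = 1e-9,
    max_depth: int = 60,
    seed: int = 0,
    diffraction_halfangle: float | None = None,
) -> tuple[ExitRecords, EnergyLedger]:
    """Trace a source through the model; returns exit records + ledger.

    ``source`` is a :class:`SourceGrid` or the dict from
    :func:`make_source`.  ``epsilon`` is the discard threshold as a
    fraction of the per-ray input energy; ``max_depth`` caps the split
    generation count.  Strategy ``"i"`` uses the seeded RNG, ``"ii"``
    and ``"iii"`` are deterministic.
    """
    if strategy not in ("i", "ii", "iii"):
        raise ValueError("strategy must be 'i', 'ii' or 'iii'")
    if isinstance(source, SourceGrid):
        if diffraction_halfangle is None and strategy == "iii":
            diffraction_halfangle = source.wavelength / (np.pi * source.spacing)
        source = make_source(source, model)
    wavelength = source["wavelength"]
    if diffraction_halfangle is None:
        diffraction_halfangle = 0.02

    tables = _WallTables(model, wavelength)
    rng = np.random.default_rng(seed)

    state = {
        "position": source["position"].astype(float),
        "direction": source["direction"].astype(float),
        "s_basis": source["s_basis"].astype(float),
        "amp_s": source["amp_s"].astype(complex),
        "amp_p": source["amp_p"].astype(complex),
        "region": np.full(len(source["amp_s"]), int(RegionLabel.exterior), np.int8),
        "depth": np.zeros(len(source["amp_s"]), int),
    }
    ledger = EnergyLedger(input=float(_energy(state).sum()))
    cutoff = epsilon * 1.0  # per-ray input energy is 1
    exits = []

    while state["amp_s"].size:
        pos, dirs = state["position"], state["direction"]
        outside = state["region"] == int(RegionLabel.exterior)

        t0, t1 = _sphere_exit_distance(model, pos, dirs)
        # packets with no forward sphere crossing have left (or, after a
        # nudge at a grazing hit, sit just outside heading out): exited
        miss = np.isnan(t1) | (t1 <= 1e-9)
        if np.any(miss):
            sub = _take(state, miss)
            exits.append(ExitRecords(sub["position"], sub["direction"], sub["amp_s"],
                                     sub["amp_p"], sub["s_basis"], wavelength))
            state = _take(state, ~miss)
            pos, dirs, outside = state["position"], state["direction"], state["region"] == 0
            t0, t1 = _sphere_exit_distance(model, pos, dirs)
            if not state["amp_s"].size:
                break

        # distance to the next event
        t_event = np.where(outside, t0, t1)
        to_region = np.full(len(t_event), int(RegionLabel.exterior), np.int8)

        inside = ~outside
        if model.wall_stack is not None and np.any(inside):
            g = gyroid_g(model, pos[inside])
            sign = np.where(state["region"][inside] == int(RegionLabel.compartment_A), 1.0, -1.0)
            t_mid = _march_to_surface(model, pos[inside], dirs[inside], t_event[inside], sign)
            hit_mid = np.isfinite(t_mid) & (t_mid < t_event[inside])
            ti = t_event[inside].copy()
            ti[hit_mid] = t_mid[hit_mid]
            t_event[inside] = ti
            tr = to_region[inside]
            other = np.where(state["region"][inside] == int(RegionLabel.compartment_A),
                             int(RegionLabel.compartment_B), int(RegionLabel.compartment_A))
            tr[hit_mid] = other[hit_mid]
            to_region[inside] = tr

        hit_pos = pos + t_event[:, None] * dirs
        on_sphere = to_region == int(RegionLabel.exterior)

        normals = np.empty_like(dirs)
        if np.any(on_sphere):
            nm = (hit_pos[on_sphere] - model.center) / model.radius
            # orient along propagation (entry vs exit)
            sgn = np.sign(np.einsum("ij,ij->i", dirs[on_sphere], nm))
            normals[on_sphere] = nm * np.where(sgn == 0, 1.0, sgn)[:, None]
        if np.any(~on_sphere):
            grad = gyroid_grad(model, hit_pos[~on_sphere])
            gn = np.linalg.norm(grad, axis=1, keepdims=True)
            nm = grad / np.maximum(gn, 1e-300)
            sgn = np.sign(np.einsum("ij,ij->i", dirs[~on_sphere], nm))
            normals[~on_sphere] = nm * np.where(sgn == 0, 1.0, sgn)[:, None]

        # entry classification: packets arriving from outside
        entering = outside
        if np.any(entering):
            probe = hit_pos[entering] + 0.5 * dirs[entering]
            g_in = gyroid_g(model, probe)
            tr = np.where(g_in >= 0, int(RegionLabel.compartment_A),
                          int(RegionLabel.compartment_B)).astype(np.int8)
            if model.wall_stack is None and model.n_compartment_A == model.n_compartment_B:
                tr[:] = int(RegionLabel.compartment_A)
            to_region[entering] = tr

        ledger.n_events += len(t_event)
        trans, refl = _scatter_arrays(
            model, tables, wavelength, state, hit_pos, t_event, normals, to_region
        )

        new_states = []
        for branch, st in (("t", trans), ("r", refl)):
            e = _energy(st)
            if strategy == "i":
                continue  # handled jointly below
            keep = e > cutoff
            deep = keep & (st["depth"] > max_depth)
            ledger.discarded_epsilon += float(e[~keep].sum())
            ledger.discarded_depth += float(e[deep].sum())
            keep &= ~deep
            exit_mask = keep & (st["region"] == int(RegionLabel.exterior))
            if branch == "t" and np.any(exit_mask):
                sub = _take(st, exit_mask)
                exits.append(ExitRecords(sub["position"], sub["direction"], sub["amp_s"],
                                         sub["amp_p"], sub["s_basis"], wavelength))
                keep &= ~exit_mask
            if np.any(keep):
                kept = _take(st, keep)
                if branch == "t" and strategy == "iii":
                    # fan only the early generations: an unconditional
                    # 3-way fan grows the tree as 3^depth
                    fan = kept["depth"] <= _FAN_MAX_DEPTH
                    if np.any(fan):
                        fanned = _fan_diffraction(_take(kept, fan), diffraction_halfangle)
                        rest = _take(kept, ~fan)
                        kept = {k: np.concatenate([fanned[k], rest[k]]) for k in kept}
                new_states.append(kept)

        if strategy == "i":
            eT, eR = _energy(trans), _energy(refl)
            tot = eT + eR
            pT = np.where(tot > 0, eT / np.maximum(tot, 1e-300), 1.0)
            take_t = rng.random(len(pT)) < pT
            scale_t = np.sqrt(np.where(pT > 0, 1.0 / np.maximum(pT, 1e-300), 0.0))
            scale_r = np.sqrt(np.where(pT < 1, 1.0 / np.maximum(1 - pT, 1e-300), 0.0))
            for st, m, sc in ((trans, take_t, scale_t), (refl, ~take_t, scale_r)):
                st = _take(st, m)
                st["amp_s"] = st["amp_s"] * sc[m]
                st["amp_p"] = st["amp_p"] * sc[m]
                e = _energy(st)
                keep = e > cutoff
                deep = keep & (st["depth"] > max_depth)
                ledger.discarded_epsilon += float(e[~keep].sum())
                ledger.discarded_depth += float(e[deep].sum())
                keep &= ~deep
                exit_mask = keep & (st["region"] == int(RegionLabel.exterior))
                if np.any(exit_mask):
                    sub = _take(st, exit_mask)
                    exits.append(ExitRecords(sub["position"], sub["direction"], sub["amp_s"],
                                             sub["amp_p"], sub["s_basis"], wavelength))
                    keep &= ~exit_mask
                if np.any(keep):
                    new_states.append(_take(st, keep))

        if new_states:
            state = {
                k: np.concatenate([s[k] for s in new_states])
                for k in new_states[0]
            }
        else:
            state = {"amp_s": np.zeros(0, complex)}

    records = ExitRecords.concatenate(exits, wavelength)
    ledger.n_exit_records = len(records)
    ledger.exited_forward = float(records.forward.energy.sum())
    ledger.exited_backward = float(records.backward.energy.sum())
    return records, ledger


def _fan_diffraction(state, halfangle):
    """Replace each packet by a symmetric 3-ray angular kernel
    (weights 1/4, 1/2, 1/4) about the plane-of-incidence axis."""
    parts = []
    for off, w in ((-halfangle, 0.25), (0.0, 0.5), (halfangle, 0.25)):
        st = {k: v.copy() for k, v in state.items()}
        if off != 0.0:
            ang = np.full(len(st["amp_s"]), off)
            st["direction"] = _rodrigues(st["direction"], st["s_basis"], ang)
            st["direction"] /= np.linalg.norm(st["direction"], axis=1, keepdims=True)
        st["amp_s"] = st["amp_s"] * np.sqrt(w)
        st["amp_p"] = st["amp_p"] * np.sqrt(w)
        parts.append(st)
    return {k: np.concatenate([p[k] for p in parts]) for k in parts[0]}
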