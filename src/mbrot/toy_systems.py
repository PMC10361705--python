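"""Synthetic desk-scale fixtures with known ground truth.

Two generators:

* :func:`make_two_state_toy` — a pair of two-domain "mini-ribosome"
  structures whose second domain (the SSU analogue) differs by a known rigid
  rotation, exercising contact merging and angle recovery end to end.
* :func:`make_brownian_trajectory` — overdamped (Euler-Maruyama) Brownian
  motion on an analytic double-well landscape with known diffusion
  coefficient, optionally with orthogonal harmonic dimensions whose stiffness
  differs between basins (a controllable configurational-entropy asymmetry).

Both are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial.transform import Rotation

from .structio import MolecularStructure, ResidueMapping


class FixtureError(ValueError):
    pass


# --- two-state structure pair ----------------------------------------------


@dataclass
class ToySpec:
    """Parameters of the two-domain toy structure pair.

    Domains are helical chains of four-atom residues (backbone B1, B2 and a
    two-atom sidechain S1, S2) facing each other across an interface gap; the endpoint
    pair differs by ``rotation_angle`` (degrees) of domain 2 about the
    inter-domain axis, plus an optional orthogonal ``tilt_angle``.
    """

    atoms_per_domain: int = 60
    rotation_angle: float = 12.0
    tilt_angle: float = 0.0
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    interface_gap: float = 0.8       # nm between helix axes minus diameters
    helix_radius: float = 0.5        # nm
    rise_per_residue: float = 0.15   # nm
    jitter: float = 0.004            # nm positional noise
    min_interface_contacts: int = 6
    polymer_type: str = "protein"    # or "nucleic_acid"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.rotation_angle <= 30.0):
            raise FixtureError("rotation_angle must be in (0, 30] degrees")
        if self.atoms_per_domain < 30:
            raise FixtureError("atoms_per_domain must be >= 30")
        if self.polymer_type not in ("protein", "nucleic_acid"):
            raise FixtureError("polymer_type must be 'protein' or 'nucleic_acid'")


@dataclass
class ToyGroundTruth:
    rotation_matrix: np.ndarray
    axis: np.ndarray
    angle_deg: float
    tilt_deg: float
    pivot: np.ndarray
    bonds: list[tuple[int, int]]
    n_residues_per_domain: int


def _helix_domain(n_residues, spec: ToySpec, rng) -> np.ndarray:
    """(n_residues, 4, 3) positions for B1, B2, S1, S2 of each residue."""
    dtheta = 0.52
    out = np.empty((n_residues, 4, 3))
    for r in range(n_residues):
        t = r * dtheta
        center = np.array(
            [spec.helix_radius * np.cos(t), spec.helix_radius * np.sin(t),
             spec.rise_per_residue * r]
        )
        tangent = np.array(
            [-spec.helix_radius * np.sin(t) * dtheta,
             spec.helix_radius * np.cos(t) * dtheta, spec.rise_per_residue]
        )
        tangent /= np.linalg.norm(tangent)
        outward = np.array([np.cos(t), np.sin(t), 0.0])
        out[r, 0] = center
        out[r, 1] = center + 0.15 * tangent
        out[r, 2] = center + 0.14 * outward
        out[r, 3] = center + 0.28 * outward
    out += rng.normal(0.0, spec.jitter, size=out.shape)
    return out


def _assemble(spec: ToySpec, dom1: np.ndarray, dom2: np.ndarray) -> MolecularStructure:
    n_res = dom1.shape[0]
    names, serials, resi, resn, chains, subunits, pos = [], [], [], [], [], [], []
    resname = "TOY" if spec.polymer_type == "protein" else "TON"
    serial = 0
    for chain, subunit, dom in (("L", "LSU", dom1), ("S", "SSU_body", dom2)):
        for r in range(n_res):
            for a, name in enumerate(("B1", "B2", "S1", "S2")):
                serial += 1
                serials.append(serial)
                names.append(name)
                resi.append(r + 1)
                resn.append(resname)
                chains.append(chain)
                subunits.append(subunit)
                pos.append(dom[r, a])
    return MolecularStructure(
        serials=serials, names=names, elements=["C"] * serial,
        residue_index=resi, residue_names=resn, chain_ids=chains,
        positions=np.array(pos), subunits=subunits,
        polymer_types=[spec.polymer_type] * serial,
    )


def _toy_bonds(n_residues: int) -> list[tuple[int, int]]:
    """Chain bonds B1-B2, B2-B1(next), B1-S1, S1-S2 per domain."""
    bonds = []
    for dom in range(2):
        base = dom * 4 * n_residues
        for r in range(n_residues):
            b1 = base + 4 * r + 1
            b2 = b1 + 1
            s1 = b1 + 2
            s2 = b1 + 3
            bonds.append((b1, b2))
            bonds.append((b1, s1))
            bonds.append((s1, s2))
            if r + 1 < n_residues:
                bonds.append((b2, base + 4 * (r + 1) + 1))
    return bonds


def make_two_state_toy(
    spec: ToySpec | None = None, max_retries: int = 5
) -> tuple[MolecularStructure, MolecularStructure, ToyGroundTruth]:
    """Build the (rotated, unrotated) structure pair.

    The second returned structure is the unrotated base geometry; in the
    first, domain 2 is rigidly rotated by the spec's angle about the
    inter-domain axis through the domain-2 centroid (plus the optional
    orthogonal tilt).  The ground-truth record carries the exact rotation and
    the covalent bond list.
    """
    spec = spec or ToySpec()
    n_res = max(10, int(np.ceil(spec.atoms_per_domain / 4)))
    axis = np.asarray(spec.axis, dtype=float)
    axis = axis / np.linalg.norm(axis)

    for attempt in range(max_retries):
        rng = np.random.default_rng(spec.seed + 1000 * attempt)
        dom1 = _helix_domain(n_res, spec, rng)
        dom2 = _helix_domain(n_res, spec, rng)
        # face the second helix toward the first (180 degrees about z) so the
        # outward sidechains of both domains meet across the interface gap
        dom2 = dom2 * np.array([-1.0, -1.0, 1.0])
        offset = 2.0 * spec.helix_radius + spec.interface_gap
        dom2 = dom2 + np.array([offset, 0.0, 0.0])

        pivot = dom2.reshape(-1, 3).mean(axis=0)
        rot = Rotation.from_rotvec(np.radians(spec.rotation_angle) * axis)
        if spec.tilt_angle:
            tilt_axis = np.array([0.0, 1.0, 0.0])
            tilt_axis -= np.dot(tilt_axis, axis) * axis
            tilt_axis /= np.linalg.norm(tilt_axis)
            tilt = Rotation.from_rotvec(np.radians(spec.tilt_angle) * tilt_axis)
            rot = tilt * rot
        dom2_rotated = (dom2.reshape(-1, 3) - pivot) @ rot.as_matrix().T + pivot

        struct_a = _assemble(spec, dom1, dom2_rotated.reshape(n_res, 4, 3))
        struct_b = _assemble(spec, dom1, dom2)

        ok = True
        for s in (struct_a, struct_b):
            half = 4 * n_res
            d = s.positions[:half, None, :] - s.positions[None, half:, :]
            dist = np.linalg.norm(d, axis=2)
            if dist.min() < 0.12:
                ok = False
            if np.sum(dist < 0.6) < spec.min_interface_contacts:
                ok = False
        if ok:
            truth = ToyGroundTruth(
                rotation_matrix=rot.as_matrix(), axis=axis,
                angle_deg=spec.rotation_angle, tilt_deg=spec.tilt_angle,
                pivot=pivot, bonds=_toy_bonds(n_res), n_residues_per_domain=n_res,
            )
            return struct_a, struct_b, truth
    raise FixtureError(
        f"could not generate a clash-free toy pair in {max_retries} attempts"
    )


def identity_mapping(n_residues: int) -> ResidueMapping:
    """Identity residue correspondence for the toy domains."""
    ident = {r: r for r in range(1, n_residues + 1)}
    return ResidueMapping(domains={"LSU": dict(ident), "SSU_body": dict(ident)})


# --- Brownian dynamics on an analytic landscape -----------------------------


@dataclass
class BrownianSpec:
    """Overdamped dynamics on a symmetric quartic double well.

    ``V(x) = barrier * (x^2 - 1)^2 + basin_offset * s(x)`` with ``s`` a
    logistic switch of width ``switch_width`` (0 in the left basin, 1 in the
    right), minima near x = -1 and +1.  ``n_extra_dims`` adds orthogonal
    harmonic coordinates whose stiffness interpolates between
    ``stiffness_left`` (x < 0) and ``stiffness_right``, giving the basins
    different configurational entropy.  Choosing ``basin_offset`` to cancel
    the entropic free-energy difference at the reference temperature yields
    energy-entropy compensation: the wide basin is increasingly stabilized as
    temperature rises.
    """

    barrier: float = 6.0          # k_B T
    d0: float = 1.0               # (coordinate units)^2 / tau_ru
    kbt: float = 1.0
    dt: float = 5.0e-4
    n_steps: int = 2_000_000
    save_every: int = 20
    seed: int = 0
    x0: float = -1.0
    n_extra_dims: int = 0
    stiffness_left: float = 10.0
    stiffness_right: float = 10.0
    basin_offset: float = 0.0
    switch_width: float = 0.2
    reflect_at: float = np.inf   # reflecting walls at +/- this coordinate

    def __post_init__(self):
        if self.barrier < 0:
            raise FixtureError("barrier must be nonnegative")
        if self.d0 <= 0 or self.kbt <= 0:
            raise FixtureError("d0 and kbt must be positive")
        max_curv = max(8.0 * self.barrier, 4.0 * self.barrier,
                       self.stiffness_left, self.stiffness_right)
        if self.dt * self.d0 * max_curv / self.kbt > 0.1:
            raise FixtureError(
                f"dt = {self.dt} violates the overdamped stability bound for "
                f"curvature {max_curv:.3g}; reduce dt"
            )


@dataclass
class BrownianTrajectory:
    """Saved frames of the reaction coordinate plus per-frame energy."""

    coordinate: np.ndarray
    extra: np.ndarray | None
    potential_energy: np.ndarray
    frame_interval: float
    spec: BrownianSpec = field(repr=False, default=None)

    @property
    def n_frames(self) -> int:
        return len(self.coordinate)


@njit(cache=True)
def _brownian_core(barrier, kbt, d0, dt, n_steps, save_every, seed,
                   x0, n_extra, k_left, k_right, offset, width, reflect):
    np.random.seed(seed)
    n_saved = n_steps // save_every
    xs = np.empty(n_saved)
    ys = np.empty((n_saved, n_extra))
    us = np.empty(n_saved)
    x = x0
    y = np.zeros(n_extra)
    mob = d0 / kbt
    noise = np.sqrt(2.0 * d0 * dt)
    saved = 0
    for step in range(1, n_steps + 1):
        s = 1.0 / (1.0 + np.exp(-x / width))
        k = k_left + (k_right - k_left) * s
        dkdx = (k_right - k_left) * s * (1.0 - s) / width
        ysq = 0.0
        for j in range(n_extra):
            ysq += y[j] * y[j]
        dvdx = (4.0 * barrier * x * (x * x - 1.0) + 0.5 * ysq * dkdx
                + offset * s * (1.0 - s) / width)
        x += -mob * dvdx * dt + noise * np.random.normal()
        if x > reflect:
            x = 2.0 * reflect - x
        elif x < -reflect:
            x = -2.0 * reflect - x
        for j in range(n_extra):
            y[j] += -mob * k * y[j] * dt + noise * np.random.normal()
        if step % save_every == 0:
            s = 1.0 / (1.0 + np.exp(-x / width))
            k = k_left + (k_right - k_left) * s
            ysq = 0.0
            for j in range(n_extra):
                ysq += y[j] * y[j]
            u = barrier * (x * x - 1.0) ** 2 + offset * s + 0.5 * k * ysq
            xs[saved] = x
            for j in range(n_extra):
                ys[saved, j] = y[j]
            us[saved] = u
            saved += 1
    return xs, ys, us


def make_brownian_trajectory(spec: BrownianSpec | None = None) -> BrownianTrajectory:
    """Euler-Maruyama path on the spec's landscape; deterministic per seed."""
    spec = spec or BrownianSpec()
    xs, ys, us = _brownian_core(
        spec.barrier, spec.kbt, spec.d0, spec.dt, spec.n_steps, spec.save_every,
        spec.seed, spec.x0, spec.n_extra_dims, spec.stiffness_left,
        spec.stiffness_right, spec.basin_offset, spec.switch_width,
        spec.reflect_at,
    )
    return BrownianTrajectory(
        coordinate=xs,
        extra=ys if spec.n_extra_dims else None,
        potential_energy=us,
        frame_interval=spec.dt * spec.save_every,
        spec=spec,
    )


def analytic_free_energy(spec: BrownianSpec, x: np.ndarray) -> np.ndarray:
    """Marginal free energy F(x) in k_B T, minimum offset to zero.

    The orthogonal harmonic dimensions integrate out to an entropic term
    ``(n/2) ln k(x)`` on top of the double-well potential.
    """
    x = np.asarray(x, dtype=float)
    s = 1.0 / (1.0 + np.exp(-x / spec.switch_width))
    v = (spec.barrier * (x**2 - 1.0) ** 2 + spec.basin_offset * s) / spec.kbt
    if spec.n_extra_dims:
        k = spec.stiffness_left + (spec.stiffness_right - spec.stiffness_left) * s
        v = v + 0.5 * spec.n_extra_dims * np.log(k)
    return v - v.min()
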