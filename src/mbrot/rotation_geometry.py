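"""Euler-angle decomposition of small-subunit body orientation.

The orientation of the SSU body relative to the LSU is expressed as a
rigid-body rotation of a reference structure, decomposed in z-x-z Euler
angles (phi, theta, psi) in a frame whose z axis is the pure-rotation axis
(defined by classical and rotated reference body orientations).  The reported
collective coordinates are

* ``phi_body = phi + psi`` — net body rotation about the reference axis,
* ``theta_body = theta``  — tilt (eukaryotic "rolling") magnitude,
* ``psi_body = phi + C``  — tilt direction, with an arbitrary offset ``C``.

At ``theta -> 0`` only ``phi + psi`` is geometrically meaningful; frames in
that regime are flagged ``tilt_defined = False`` and reported with
``phi = phi + psi``, ``psi = 0``.

Core-residue sets — residues that move rigidly with their domain — are found
by iterating a least-squares fit with a 1 Angstrom (0.1 nm) inclusion rule to
a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import MolecularStructure, ResidueMapping, Trajectory

THETA_UNDEFINED_DEG = 0.1  # below this tilt the tilt direction is unreported


class GeometryError(ValueError):
    """Raised for degenerate point sets or invalid rotation input."""


@dataclass
class EulerAngles:
    phi: float
    theta: float
    psi: float
    tilt_defined: bool = True


@dataclass
class RotationReference:
    """Reference structures and the pure-rotation axis.

    ``structure_classical`` defines the zero of all angles; ``axis`` is the
    unit rotation axis between the classical and rotated reference body
    orientations, expressed in the classical structure's coordinates.
    ``psi_offset_C`` (degrees) shifts the reported tilt direction;
    ``core_atom_name`` names the per-residue proxy atom used for alignment
    (P for rRNA backbones, configurable for toy systems).
    """

    structure_classical: MolecularStructure
    axis: np.ndarray
    structure_rotated: MolecularStructure | None = None
    psi_offset_C: float = 0.0
    core_atom_name: str = "P"

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(self.axis)
        if not np.isfinite(norm) or norm < 1e-12:
            raise GeometryError("rotation axis must be a nonzero vector")
        self.axis = self.axis / norm


@dataclass
class CoreSet:
    """Converged per-domain core residues used for rigid-body fits."""

    residues: dict[str, list[int]]
    convergence_iterations: int = 0

    def domain(self, name: str) -> list[int]:
        return self.residues[name]


@dataclass
class RotationSeries:
    """Per-frame (phi_body, theta_body, psi_body) in degrees."""

    phi_body: np.ndarray
    theta_body: np.ndarray
    psi_body: np.ndarray
    tilt_defined: np.ndarray = field(default=None)

    def __post_init__(self):
        self.phi_body = np.asarray(self.phi_body, dtype=float)
        self.theta_body = np.asarray(self.theta_body, dtype=float)
        self.psi_body = np.asarray(self.psi_body, dtype=float)
        if self.tilt_defined is None:
            self.tilt_defined = np.ones(len(self.phi_body), dtype=bool)
        else:
            self.tilt_defined = np.asarray(self.tilt_defined, dtype=bool)
        if np.any(self.theta_body < -1e-9):
            raise GeometryError("theta_body must be nonnegative")

    def __len__(self) -> int:
        return len(self.phi_body)

    def unwrapped_phi(self) -> np.ndarray:
        return np.degrees(np.unwrap(np.radians(self.phi_body)))


# --- rigid-body superposition ----------------------------------------------


def superpose(
    mobile_points: np.ndarray, target_points: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid transform mapping mobile onto target.

    Returns ``(R, t, rmsd)`` such that ``R @ x + t`` superposes the mobile
    points onto the target points; ``R`` is a proper rotation.  Requires at
    least three non-collinear point pairs.
    """
    mobile = np.asarray(mobile_points, dtype=float)
    target = np.asarray(target_points, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError(f"point sets must match as (n, 3); got {mobile.shape} vs {target.shape}")
    n = len(mobile)
    if n < 3:
        raise GeometryError(f"need >= 3 point pairs, got {n}")
    cm_m = mobile.mean(axis=0)
    cm_t = target.mean(axis=0)
    mob_c = mobile - cm_m
    tgt_c = target - cm_t
    if np.linalg.matrix_rank(mob_c, tol=1e-10) < 2:
        raise GeometryError("mobile point set is collinear or degenerate")
    # Kabsch via SVD of the covariance; the sign correction enforces a
    # proper rotation
    h = mob_c.T @ tgt_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rmat = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cm_t - rmat @ cm_m
    rmsd = float(np.sqrt(np.mean(np.sum((mob_c @ rmat.T - tgt_c) ** 2, axis=1))))
    return rmat, t, rmsd


def _apply_transform(rmat: np.ndarray, t: np.ndarray, points: np.ndarray) -> np.ndarray:
    return points @ rmat.T + t


# --- core-residue selection -------------------------------------------------


def _proxy_coords(
    structure: MolecularStructure, domain: str, atom_name: str
) -> dict[int, np.ndarray]:
    out: dict[int, np.ndarray] = {}
    for k in range(structure.n_atoms):
        if structure.subunits[k] == domain and structure.names[k] == atom_name:
            out[int(structure.residue_index[k])] = structure.positions[k]
    return out


def select_core_points(
    reference_xyz: dict[int, np.ndarray],
    target_xyz: dict[int, np.ndarray],
    threshold: float = 0.1,
    max_iterations: int = 100,
) -> tuple[list[int], int]:
    """Fixed point of the fit/include/exclude rule over mapped residues.

    Fit on the included set, then re-include every mapped residue whose proxy
    atom lies within ``threshold`` (nm) of its fitted position and exclude the
    rest; iterate until the included set stops changing.  Errors if the set
    shrinks below three residues or oscillates.
    """
    common = sorted(set(reference_xyz) & set(target_xyz))
    if len(common) < 3:
        raise GeometryError(f"only {len(common)} mapped residues; need >= 3")
    ref = np.array([reference_xyz[r] for r in common])
    tgt = np.array([target_xyz[r] for r in common])

    included = np.ones(len(common), dtype=bool)
    seen: list[frozenset] = [frozenset(np.nonzero(included)[0])]
    for iteration in range(1, max_iterations + 1):
        if included.sum() < 3:
            raise GeometryError(
                f"core shrank to {int(included.sum())} residues at iteration {iteration}"
            )
        rmat, t, _ = superpose(ref[included], tgt[included])
        deviations = np.linalg.norm(_apply_transform(rmat, t, ref) - tgt, axis=1)
        new_included = deviations <= threshold
        if np.array_equal(new_included, included):
            return [common[k] for k in np.nonzero(included)[0]], iteration
        key = frozenset(np.nonzero(new_included)[0])
        if key in seen:
            raise GeometryError(
                f"core selection oscillates (cycle length {len(seen) - seen.index(key)})"
            )
        seen.append(key)
        included = new_included
    raise GeometryError(f"core selection did not converge in {max_iterations} iterations")


def select_core(
    reference: MolecularStructure,
    target: MolecularStructure,
    mapping: ResidueMapping,
    domains: tuple[str, ...] = ("LSU", "SSU_body"),
    threshold: float = 0.1,
    atom_name: str = "P",
) -> CoreSet:
    """Converged core residues (reference numbering) per domain."""
    residues: dict[str, list[int]] = {}
    iterations = 0
    for domain in domains:
        dom_map = mapping.domain(domain)
        ref_xyz = _proxy_coords(reference, domain, atom_name)
        tgt_all = _proxy_coords(target, domain, atom_name)
        ref_sel = {r: ref_xyz[r] for r in dom_map if r in ref_xyz}
        tgt_sel = {r: tgt_all[dom_map[r]] for r in dom_map if dom_map[r] in tgt_all}
        core, n_iter = select_core_points(ref_sel, tgt_sel, threshold=threshold)
        residues[domain] = core
        iterations = max(iterations, n_iter)
    return CoreSet(residues=residues, convergence_iterations=iterations)


# --- Euler decomposition ----------------------------------------------------


def axis_frame(axis: np.ndarray) -> np.ndarray:
    """Deterministic right-handed orthonormal basis with the given z axis.

    Columns are (e1, e2, axis); e1 is built from the cardinal direction least
    aligned with the axis.
    """
    z = np.asarray(axis, dtype=float)
    z = z / np.linalg.norm(z)
    seed = np.zeros(3)
    seed[np.argmin(np.abs(z))] = 1.0
    e1 = seed - np.dot(seed, z) * z
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(z, e1)
    return np.column_stack([e1, e2, z])


def euler_decompose(
    rotation_matrix: np.ndarray,
    axis: np.ndarray,
    orthogonality_tol: float = 1e-8,
) -> EulerAngles:
    """z-x-z Euler angles (degrees) of a rotation, with z = the given axis.

    theta is in [0, 180].  When theta falls below ``THETA_UNDEFINED_DEG`` only
    phi + psi is defined; the sum is reported as phi, psi is set to zero and
    the result is flagged ``tilt_defined = False``.
    """
    rmat = np.asarray(rotation_matrix, dtype=float)
    if rmat.shape != (3, 3):
        raise GeometryError(f"rotation matrix must be 3x3, got {rmat.shape}")
    if np.max(np.abs(rmat @ rmat.T - np.eye(3))) > max(orthogonality_tol, 1e-12):
        raise GeometryError("matrix is not orthogonal within tolerance")
    if np.linalg.det(rmat) < 0:
        raise GeometryError("improper rotation (determinant -1)")
    frame = axis_frame(axis)
    local = frame.T @ rmat @ frame
    import warnings

    with warnings.catch_warnings():
        # at theta = 0 only phi + psi is defined; scipy resolves the gimbal
        # lock by zeroing psi, which is exactly the reporting convention here
        warnings.filterwarnings("ignore", message="Gimbal lock")
        phi, theta, psi = Rotation.from_matrix(local).as_euler("ZXZ", degrees=True)
    if theta < 0:  # scipy ZXZ returns theta >= 0, but guard anyway
        theta, phi, psi = -theta, phi + 180.0, psi + 180.0
    if theta < THETA_UNDEFINED_DEG:
        total = (phi + psi + 180.0) % 360.0 - 180.0
        return EulerAngles(phi=total, theta=theta, psi=0.0, tilt_defined=False)
    return EulerAngles(phi=phi, theta=theta, psi=psi, tilt_defined=True)


def compose_zxz(phi: float, theta: float, psi: float, axis: np.ndarray) -> np.ndarray:
    """Inverse of :func:`euler_decompose` (angles in degrees)."""
    frame = axis_frame(axis)
    local = Rotation.from_euler("ZXZ", [phi, theta, psi], degrees=True).as_matrix()
    return frame @ local @ frame.T


# --- body-angle pipeline ----------------------------------------------------


def rotation_axis_between(
    classical: MolecularStructure,
    rotated: MolecularStructure,
    mapping: ResidueMapping | None = None,
    atom_name: str = "P",
) -> np.ndarray:
    """Pure-rotation axis between two reference body orientations.

    Both structures are placed in the classical LSU frame, then the rotation
    carrying the classical body onto the rotated body is extracted; its
    rotation axis (unit vector, classical coordinates, oriented so the
    classical -> rotated rotation angle is positive) is returned.
    """
    def coords(struct, domain):
        xyz = _proxy_coords(struct, domain, atom_name)
        if mapping is not None and struct is not classical:
            dom_map = mapping.domain(domain)
            return {r: xyz[dom_map[r]] for r in dom_map if dom_map[r] in xyz}
        return xyz

    lsu_c = coords(classical, "LSU")
    lsu_r = coords(rotated, "LSU")
    common = sorted(set(lsu_c) & set(lsu_r))
    rmat_lsu, t_lsu, _ = superpose(
        np.array([lsu_r[r] for r in common]), np.array([lsu_c[r] for r in common])
    )
    body_c = coords(classical, "SSU_body")
    body_r = coords(rotated, "SSU_body")
    common_b = sorted(set(body_c) & set(body_r))
    rot_aligned = _apply_transform(rmat_lsu, t_lsu, np.array([body_r[r] for r in common_b]))
    rmat_body, _, _ = superpose(np.array([body_c[r] for r in common_b]), rot_aligned)
    rotvec = Rotation.from_matrix(rmat_body).as_rotvec()
    angle = np.linalg.norm(rotvec)
    if angle < 1e-10:
        raise GeometryError("reference structures differ by no rotation")
    return rotvec / angle


def compute_body_angles(
    frame_structure: MolecularStructure,
    reference: RotationReference,
    cores: CoreSet,
    mapping: ResidueMapping,
) -> EulerAngles:
    """Body rotation/tilt angles of one frame relative to the classical reference.

    Step 1 aligns the reference onto the frame's LSU core (fixing the lab
    frame); step 2 superposes the LSU-aligned classical SSU body core onto the
    frame's SSU body core; step 3 decomposes the residual body rotation about
    the pure-rotation axis.  Returns ``phi_body`` (phi + psi), ``theta_body``
    and ``psi_body`` (phi + C) in degrees.
    """
    ref = reference.structure_classical
    name = reference.core_atom_name

    def core_pair(domain):
        dom_map = mapping.domain(domain)
        ref_xyz = _proxy_coords(ref, domain, name)
        frame_xyz = _proxy_coords(frame_structure, domain, name)
        ref_pts, frame_pts, missing = [], [], []
        for r in cores.domain(domain):
            tgt = dom_map.get(r)
            if r not in ref_xyz or tgt is None or tgt not in frame_xyz:
                missing.append(r)
                continue
            ref_pts.append(ref_xyz[r])
            frame_pts.append(frame_xyz[tgt])
        if missing:
            raise GeometryError(f"missing core atoms in frame for {domain}: {missing[:10]}")
        return np.array(ref_pts), np.array(frame_pts)

    ref_lsu, frame_lsu = core_pair("LSU")
    rmat_lsu, t_lsu, _ = superpose(ref_lsu, frame_lsu)

    ref_body, frame_body = core_pair("SSU_body")
    body_aligned = _apply_transform(rmat_lsu, t_lsu, ref_body)
    rmat_body, _, _ = superpose(body_aligned, frame_body)

    # the decomposition frame is fixed in the reference structure and carried
    # through the LSU alignment, so all three angles are invariant under
    # rigid motion of the whole complex
    frame_basis = rmat_lsu @ axis_frame(reference.axis)
    local = frame_basis.T @ rmat_body @ frame_basis
    angles = euler_decompose(local, np.array([0.0, 0.0, 1.0]))
    if angles.tilt_defined:
        phi_body = angles.phi + angles.psi
        psi_body = angles.phi + reference.psi_offset_C
    else:
        phi_body = angles.phi
        psi_body = 0.0
    phi_body = (phi_body + 180.0) % 360.0 - 180.0
    return EulerAngles(
        phi=phi_body, theta=angles.theta, psi=psi_body % 360.0,
        tilt_defined=angles.tilt_defined,
    )


def compute_rotation_series(
    trajectory: Trajectory,
    structure: MolecularStructure,
    reference: RotationReference,
    cores: CoreSet,
    mapping: ResidueMapping,
) -> RotationSeries:
    """Apply :func:`compute_body_angles` to every trajectory frame."""
    phis, thetas, psis, flags = [], [], [], []
    for frame in trajectory.frames:
        angles = compute_body_angles(structure.with_positions(frame), reference, cores, mapping)
        phis.append(angles.phi)
        thetas.append(angles.theta)
        psis.append(angles.psi)
        flags.append(angles.tilt_defined)
    return RotationSeries(
        phi_body=np.array(phis), theta_body=np.array(thetas),
        psi_body=np.array(psis), tilt_defined=np.array(flags),
    )
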