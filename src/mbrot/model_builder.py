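"""Construction of single-basin and multi-basin all-atom structure-based models.

The potential has the standard structure-based (Go-like) form: harmonic bonds,
angles and improper dihedrals, planar ring dihedrals of periodicity 2, proper
dihedrals with the ``F_D(x) = [1 - cos x] + 1/2 [1 - cos 3x]`` shape, 12-6
native contacts and a purely repulsive ``(sigma_nc/r)^12`` excluded volume.

A multi-basin model is built from two endpoint structures ("rotated" and
"unrotated").  Proper-dihedral minima are placed at the circular mean of the
two endpoint values and inter-subunit contacts found in both endpoints are
given a single isoenergetic well, so that no common interaction favors either
endpoint.  Contacts present in only one endpoint (or too dissimilar to admit a
deep shared well) are endpoint-specific "unique" contacts with fixed weights.

Energy bookkeeping follows two global identities: the total stabilizing
(contact + dihedral) energy equals ``N * eps`` for ``N`` atoms, and contacts
carry ``R_C/D = 2`` times the dihedral total.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .structio import MolecularStructure

CONTACT_CLASSES = ("common", "rotated_unique", "unrotated_unique")

# atom names treated as backbone when classifying proper dihedrals;
# B* names are the toy-system backbone
_BACKBONE_NAMES = {
    "N", "CA", "C", "O",
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'",
    "B1", "B2", "B3",
}


class TopologyError(ValueError):
    """Raised for invalid or incomplete force-field construction input."""


@dataclass
class ForceFieldParams:
    """Tunable parameters of the structure-based model (reduced units, nm).

    ``eps_reduced`` is the reduced energy unit (1 r.u. = 2 k_B T at the
    reference temperature).  ``R_C_over_D`` fixes the contact/dihedral energy
    ratio and ``R_bb_sc_*`` the backbone/sidechain dihedral ratio per polymer
    type.  ``sigma_scale`` shrinks contact well positions (0.96 of the native
    distance) to counteract entropic expansion.  ``iso_threshold`` is the
    eps_iso/eps_C fraction above which an inter-subunit pair shared by both
    endpoints is classified "common".  ``w_rotated_unique``/
    ``w_unrotated_unique`` are the fixed weights of endpoint-specific
    contacts.  Bonded strengths and the nonbonded floor follow all-atom
    structure-based conventions; they are not normalization targets.
    """

    eps_reduced: float = 1.0
    R_C_over_D: float = 2.0
    R_bb_sc_protein: float = 2.0
    R_bb_sc_nucleic: float = 1.0
    sigma_scale: float = 0.96
    iso_threshold: float = 0.5
    w_rotated_unique: float = 0.21
    w_unrotated_unique: float = 0.19
    eps_r: float = 10000.0       # r.u. / nm^2
    eps_theta: float = 80.0      # r.u. / rad^2
    eps_chi_imp: float = 10.0    # r.u. / rad^2
    eps_chi_planar: float = 40.0
    eps_nc: float = 0.01
    sigma_nc: float = 0.25
    contact_cutoff: float = 0.6  # nm
    min_seq_sep: int = 3         # minimum |residue separation| within a chain
    shadow: bool = False
    shadow_radius: float = 0.1   # nm
    bond_cutoff: float = 0.18    # nm, for bond inference on toy systems
    sigma_scale_stage: str = "after_solve"  # or "before_solve"
    scale_unique: bool = True

    def __post_init__(self):
        for name in ("eps_reduced", "R_C_over_D", "w_rotated_unique", "w_unrotated_unique"):
            if getattr(self, name) <= 0:
                raise TopologyError(f"{name} must be > 0")
        if not (0 < self.sigma_scale <= 1):
            raise TopologyError("sigma_scale must be in (0, 1]")
        if not (0 < self.iso_threshold < 1):
            raise TopologyError("iso_threshold must be in (0, 1)")
        if self.sigma_scale_stage not in ("after_solve", "before_solve"):
            raise TopologyError("sigma_scale_stage must be 'after_solve' or 'before_solve'")

    def rbb_sc(self, polymer_type: str) -> float:
        return self.R_bb_sc_protein if polymer_type == "protein" else self.R_bb_sc_nucleic


@dataclass
class ContactPair:
    """One stabilizing 12-6 pair.

    ``sigma_prime`` is the unscaled well position (native distance, or the
    isoenergetic solution when both endpoint distances are defined);
    ``sigma`` is the well position actually used in the potential.
    ``iso_fraction`` is eps_iso/eps_C, the depth fraction shared by the two
    endpoint distances; it is None for single-endpoint contacts.
    """

    i: int
    j: int
    sigma: float
    sigma_prime: float
    eps: float = 1.0
    contact_class: str = "common"
    r_native_a: float | None = None
    r_native_b: float | None = None
    iso_fraction: float | None = None

    def __post_init__(self):
        if self.i >= self.j:
            self.i, self.j = min(self.i, self.j), max(self.i, self.j)
        if self.sigma <= 0 or self.sigma_prime <= 0:
            raise TopologyError(f"contact ({self.i},{self.j}): sigma must be positive")
        if self.contact_class not in CONTACT_CLASSES:
            raise TopologyError(f"unknown contact class {self.contact_class!r}")


@dataclass
class ProperDihedral:
    i: int
    j: int
    k: int
    l: int
    phi0: float              # radians
    weight: float = 0.0
    kind: str = "bb"         # "bb" or "sc"
    group: str = ""          # middle-bond group id
    chain_type: str = "protein"


@dataclass
class Topology:
    """All energy terms of the model, indexed by atom serial."""

    atoms: MolecularStructure
    bonds: list = field(default_factory=list)             # (i, j, r0, eps_r)
    angles: list = field(default_factory=list)            # (i, j, k, theta0, eps_theta)
    impropers: list = field(default_factory=list)         # (i, j, k, l, chi0, eps)
    planar_dihedrals: list = field(default_factory=list)  # (i, j, k, l, eps)
    proper_dihedrals: list[ProperDihedral] = field(default_factory=list)
    contacts: list[ContactPair] = field(default_factory=list)
    eps_nc: float = 0.01
    sigma_nc: float = 0.25
    exclusions: set = field(default_factory=set)          # {(i, j)} serial pairs, i<j

    def sum_contact_weights(self) -> float:
        return float(sum(c.eps for c in self.contacts))

    def sum_dihedral_weights(self, kind: str | None = None) -> float:
        return float(
            sum(d.weight for d in self.proper_dihedrals if kind is None or d.kind == kind)
        )

    def contacts_of_class(self, contact_class: str) -> list[ContactPair]:
        return [c for c in self.contacts if c.contact_class == contact_class]

    def validate(self) -> None:
        serials = set(int(s) for s in self.atoms.serials)
        for c in self.contacts:
            if c.i not in serials or c.j not in serials:
                raise TopologyError(f"contact ({c.i},{c.j}) references unknown serial")
        groups = {d.group for d in self.proper_dihedrals}
        if "" in groups and self.proper_dihedrals:
            raise TopologyError("ungrouped proper dihedral present")


# --- geometry helpers -------------------------------------------------------


def _index_of_serial(structure: MolecularStructure) -> dict[int, int]:
    return {int(s): idx for idx, s in enumerate(structure.serials)}


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in radians for four points."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.arctan2(y, x))


def infer_bonds(structure: MolecularStructure, cutoff: float = 0.18) -> list[tuple[int, int]]:
    """Distance-based covalent bond inference for toy systems (serial pairs)."""
    tree = cKDTree(structure.positions)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    serials = structure.serials
    out = []
    for a, b in pairs:
        i, j = int(serials[a]), int(serials[b])
        out.append((min(i, j), max(i, j)))
    return sorted(out)


def _bond_graph(bonds) -> dict[int, set[int]]:
    graph: dict[int, set[int]] = defaultdict(set)
    for i, j, *_ in bonds:
        graph[int(i)].add(int(j))
        graph[int(j)].add(int(i))
    return graph


def bonded_exclusions(bonds, max_bonds: int = 3) -> set[tuple[int, int]]:
    """All serial pairs within ``max_bonds`` covalent bonds (1-2, 1-3, 1-4)."""
    graph = _bond_graph(bonds)
    excl: set[tuple[int, int]] = set()
    for start in graph:
        seen = {start: 0}
        frontier = [start]
        for depth in range(1, max_bonds + 1):
            nxt = []
            for node in frontier:
                for nb in graph[node]:
                    if nb not in seen:
                        seen[nb] = depth
                        nxt.append(nb)
            frontier = nxt
        for node in seen:
            if node != start:
                excl.add((min(start, node), max(start, node)))
    return excl


# --- contact map ------------------------------------------------------------


def _point_segment_distance(p, a, b) -> tuple[float, float]:
    """Distance from point p to segment ab and the projection parameter t."""
    ab = b - a
    denom = float(np.dot(ab, ab))
    t = float(np.dot(p - a, ab) / denom) if denom > 0 else 0.0
    closest = a + np.clip(t, 0.0, 1.0) * ab
    return float(np.linalg.norm(p - closest)), t


def compute_contact_map(
    structure: MolecularStructure,
    params: ForceFieldParams,
    bonds: list | None = None,
) -> list[tuple[int, int, float]]:
    """Candidate stabilizing pairs as (serial_i, serial_j, native distance).

    Pairs must be within ``contact_cutoff``, separated by at least
    ``min_seq_sep`` residues when on the same chain, and not be covalent
    neighbors (within three bonds).  With ``params.shadow`` enabled, a pair is
    discarded when a third atom lies within ``shadow_radius`` of the segment
    connecting it (line-of-sight occlusion).
    """
    if structure.n_atoms == 0:
        raise TopologyError("empty structure")
    if bonds is None:
        bonds = infer_bonds(structure, params.bond_cutoff)
    excluded = bonded_exclusions(bonds, max_bonds=3)

    pos = structure.positions
    serials = structure.serials
    resi = structure.residue_index
    chains = structure.chain_ids
    tree = cKDTree(pos)
    raw = tree.query_pairs(params.contact_cutoff, output_type="ndarray")

    contacts = []
    for a, b in raw:
        i, j = int(serials[a]), int(serials[b])
        key = (min(i, j), max(i, j))
        if key in excluded:
            continue
        if chains[a] == chains[b] and abs(int(resi[a]) - int(resi[b])) < params.min_seq_sep:
            continue
        r = float(np.linalg.norm(pos[a] - pos[b]))
        if params.shadow:
            nearby = tree.query_ball_point((pos[a] + pos[b]) / 2.0, r)
            occluded = False
            for k in nearby:
                if k in (a, b):
                    continue
                d, t = _point_segment_distance(pos[k], pos[a], pos[b])
                if 0.0 < t < 1.0 and d < params.shadow_radius:
                    occluded = True
                    break
            if occluded:
                continue
        contacts.append((key[0], key[1], r))
    contacts.sort()
    return contacts


# --- isoenergetic well ------------------------------------------------------


def lj1206(r: float, sigma: float, eps: float = 1.0) -> float:
    """12-6 contact energy ``eps [(sigma/r)^12 - 2 (sigma/r)^6]``."""
    x6 = (sigma / r) ** 6
    return eps * (x6 * x6 - 2.0 * x6)


def solve_isoenergetic_sigma(r_a: float, r_b: float) -> tuple[float, float]:
    """Well position making the two endpoint distances isoenergetic.

    For the 12-6 form the closed solution is
    ``sigma'^6 = 2 (r_a^-6 - r_b^-6) / (r_a^-12 - r_b^-12)`` with the
    degenerate limit ``sigma' = r_a`` when the distances coincide.  Returns
    ``(sigma_prime, iso_fraction)`` where ``iso_fraction = -V(r_a)/eps_C`` in
    (0, 1] is the shared fractional well depth.
    """
    if r_a <= 0 or r_b <= 0:
        raise TopologyError("native distances must be positive")
    if np.isclose(r_a, r_b, rtol=1e-12, atol=1e-12):
        return float(r_a), 1.0
    ia6, ib6 = r_a**-6, r_b**-6
    sigma6 = 2.0 * (ia6 - ib6) / (ia6 * ia6 - ib6 * ib6)
    sigma_prime = float(sigma6 ** (1.0 / 6.0))
    iso_fraction = -lj1206(r_a, sigma_prime)
    return sigma_prime, float(iso_fraction)


# --- topology assembly ------------------------------------------------------


def _enumerate_bonded_terms(structure: MolecularStructure, bonds, params: ForceFieldParams):
    """Harmonic bonds/angles and proper dihedrals from the bond graph.

    Equilibrium values are measured from the input structure (the toy-system
    stand-in for a transferable bonded-geometry table).
    """
    idx = _index_of_serial(structure)
    pos = structure.positions
    graph = _bond_graph(bonds)

    bond_terms = []
    for (i, j) in bonds:
        r0 = float(np.linalg.norm(pos[idx[i]] - pos[idx[j]]))
        bond_terms.append((i, j, r0, params.eps_r))

    angle_terms = []
    for center in sorted(graph):
        nbrs = sorted(graph[center])
        for i, k in itertools.combinations(nbrs, 2):
            v1 = pos[idx[i]] - pos[idx[center]]
            v2 = pos[idx[k]] - pos[idx[center]]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            theta0 = float(np.arccos(np.clip(cosang, -1.0, 1.0)))
            angle_terms.append((i, center, k, theta0, params.eps_theta))

    name_of = {int(s): str(n) for s, n in zip(structure.serials, structure.names)}
    chain_of = {int(s): str(c) for s, c in zip(structure.serials, structure.chain_ids)}
    ptype_of = {int(s): str(p) for s, p in zip(structure.serials, structure.polymer_types)}

    dihedrals = []
    for (j, k) in bonds:
        for i in sorted(graph[j]):
            if i == k:
                continue
            for l in sorted(graph[k]):
                if l == j or l == i:
                    continue
                phi0 = dihedral_angle(pos[idx[i]], pos[idx[j]], pos[idx[k]], pos[idx[l]])
                is_bb = name_of[j] in _BACKBONE_NAMES and name_of[k] in _BACKBONE_NAMES
                group = f"{chain_of[j]}:{min(j, k)}-{max(j, k)}"
                dihedrals.append(
                    ProperDihedral(
                        i=i, j=j, k=k, l=l, phi0=phi0, weight=0.0,
                        kind="bb" if is_bb else "sc", group=group,
                        chain_type=ptype_of[j],
                    )
                )
    return bond_terms, angle_terms, dihedrals


def assign_dihedral_strengths(topology: Topology, params: ForceFieldParams) -> Topology:
    """Distribute dihedral weights over middle-bond groups.

    Every member of a group shares the group weight equally.  Backbone groups
    of all polymer types carry the same group weight; sidechain group weights
    are set per polymer type so that the summed backbone/sidechain ratio
    equals ``R_bb_sc`` for that polymer type.  Weights here are
    pre-normalization; :func:`normalize_energies` applies the global scale.
    """
    if not topology.proper_dihedrals:
        raise TopologyError("no proper dihedrals to weight")
    groups: dict[str, list[ProperDihedral]] = defaultdict(list)
    for d in topology.proper_dihedrals:
        groups[d.group].append(d)

    by_type: dict[str, dict[str, int]] = defaultdict(lambda: {"bb": 0, "sc": 0})
    group_kind: dict[str, tuple[str, str]] = {}
    for gid, members in groups.items():
        kind = "bb" if any(d.kind == "bb" for d in members) else "sc"
        ctype = members[0].chain_type
        group_kind[gid] = (kind, ctype)
        by_type[ctype][kind] += 1

    w_bb = 1.0  # common backbone group weight across polymer types
    w_sc: dict[str, float] = {}
    for ctype, counts in by_type.items():
        if counts["sc"] == 0:
            w_sc[ctype] = 0.0
        elif counts["bb"] == 0:
            w_sc[ctype] = 1.0
        else:
            ratio = params.rbb_sc(ctype)
            w_sc[ctype] = counts["bb"] * w_bb / (ratio * counts["sc"])

    new_dihedrals = []
    for gid, members in groups.items():
        kind, ctype = group_kind[gid]
        gw = w_bb if kind == "bb" else w_sc[ctype]
        per = gw / len(members)
        for d in members:
            new_dihedrals.append(replace(d, weight=per, kind=kind))
    return replace(topology, proper_dihedrals=new_dihedrals)


def normalize_energies(topology: Topology, params: ForceFieldParams) -> Topology:
    """Apply the two global energy identities.

    After normalization ``sum(eps_C) / sum(dihedral weights) = R_C/D`` and
    ``sum(eps_C) + sum(dihedral weights) = N eps`` with N the atom count.
    Endpoint-specific (unique) contacts keep their fixed weights; the common
    contacts and the dihedrals absorb the two scalar rescalings.
    """
    if not topology.contacts:
        raise TopologyError("cannot normalize: no contacts")
    if not topology.proper_dihedrals:
        raise TopologyError("cannot normalize: no proper dihedrals")
    n_atoms = topology.atoms.n_atoms
    total = n_atoms * params.eps_reduced
    ratio = params.R_C_over_D
    target_d = total / (1.0 + ratio)
    target_c = total * ratio / (1.0 + ratio)

    sum_unique = sum(c.eps for c in topology.contacts if c.contact_class != "common")
    sum_common = sum(c.eps for c in topology.contacts if c.contact_class == "common")
    sum_d = topology.sum_dihedral_weights()
    if sum_common <= 0:
        raise TopologyError("cannot normalize: no common contacts")
    if target_c <= sum_unique:
        raise TopologyError(
            f"unique-contact weight total {sum_unique:.3g} exceeds the contact "
            f"energy budget {target_c:.3g}; increase N or eps"
        )
    alpha = (target_c - sum_unique) / sum_common
    beta = target_d / sum_d

    contacts = [
        c if c.contact_class != "common" else replace(c, eps=c.eps * alpha)
        for c in topology.contacts
    ]
    dihedrals = [replace(d, weight=d.weight * beta) for d in topology.proper_dihedrals]
    return replace(topology, contacts=contacts, proper_dihedrals=dihedrals)


def build_single_basin(
    structure: MolecularStructure,
    params: ForceFieldParams | None = None,
    bonds: list[tuple[int, int]] | None = None,
    planar_dihedrals: list | None = None,
    impropers: list | None = None,
    normalize: bool = True,
) -> Topology:
    """Build a single-basin structure-based topology from one structure.

    Bonded equilibrium values come from the input structure; contacts come
    from :func:`compute_contact_map` with well positions at
    ``sigma_scale`` times the native distance.
    """
    params = params or ForceFieldParams()
    if any(p not in ("protein", "nucleic_acid") for p in structure.polymer_types):
        raise TopologyError("untyped residues present")
    if bonds is None:
        bonds = infer_bonds(structure, params.bond_cutoff)
    bond_terms, angle_terms, dihedrals = _enumerate_bonded_terms(structure, bonds, params)

    contact_list = []
    for (i, j, r) in compute_contact_map(structure, params, bonds=bonds):
        contact_list.append(
            ContactPair(
                i=i, j=j,
                sigma=params.sigma_scale * r, sigma_prime=r,
                eps=1.0, contact_class="common",
                r_native_a=r, r_native_b=r, iso_fraction=1.0,
            )
        )

    exclusions = bonded_exclusions(bond_terms, max_bonds=3)
    exclusions |= {(c.i, c.j) for c in contact_list}
    top = Topology(
        atoms=structure,
        bonds=bond_terms,
        angles=angle_terms,
        impropers=list(impropers or []),
        planar_dihedrals=list(planar_dihedrals or []),
        proper_dihedrals=dihedrals,
        contacts=contact_list,
        eps_nc=params.eps_nc,
        sigma_nc=params.sigma_nc,
        exclusions=exclusions,
    )
    top = assign_dihedral_strengths(top, params)
    if normalize:
        top = normalize_energies(top, params)
    return top


# --- multi-basin merge ------------------------------------------------------


def circular_mean(a: float, b: float, tol: float = 1e-8) -> float:
    """Circular mean of two angles in radians; errors on antipodal input."""
    vx = np.cos(a) + np.cos(b)
    vy = np.sin(a) + np.sin(b)
    if np.hypot(vx, vy) < tol:
        raise TopologyError(
            f"circular mean undefined for antipodal angles {a:.6f}, {b:.6f}"
        )
    return float(np.arctan2(vy, vx))


def _is_inter_subunit(structure: MolecularStructure, idx: dict[int, int], i: int, j: int) -> bool:
    return structure.subunits[idx[i]] != structure.subunits[idx[j]]


def merge_basins(
    top_rotated: Topology,
    top_unrotated: Topology,
    struct_rotated: MolecularStructure,
    struct_unrotated: MolecularStructure,
    params: ForceFieldParams | None = None,
) -> Topology:
    """Combine two endpoint topologies into one multi-basin topology.

    Endpoint A is the "rotated" structure and endpoint B the "unrotated" one.
    Proper-dihedral minima move to the circular mean of the endpoint values.
    Inter-subunit contacts shared by both endpoint maps get the isoenergetic
    well; those with shared depth fraction above ``iso_threshold`` (and all
    intra-subunit pairs) are "common".  Contacts present in a single endpoint
    map (or shared but too dissimilar) are endpoint-specific with the fixed
    unique weights; a shared-but-dissimilar pair joins the endpoint where it
    is shorter.  The global normalization identities are re-imposed over the
    merged term lists.
    """
    params = params or ForceFieldParams()
    if not struct_rotated.same_atom_table(struct_unrotated):
        raise TopologyError("endpoint structures have different atom tables")
    if not top_rotated.atoms.same_atom_table(top_unrotated.atoms):
        raise TopologyError("endpoint topologies have different atom tables")

    idx = _index_of_serial(struct_rotated)

    # bonded terms: average endpoint equilibrium values (identical for rigid
    # endpoint pairs); harmonic terms do not bias either endpoint measurably
    bonds = [
        (ba[0], ba[1], 0.5 * (ba[2] + bb[2]), ba[3])
        for ba, bb in zip(top_rotated.bonds, top_unrotated.bonds)
    ]
    angles = [
        (aa[0], aa[1], aa[2], 0.5 * (aa[3] + ab[3]), aa[4])
        for aa, ab in zip(top_rotated.angles, top_unrotated.angles)
    ]

    dihedrals = []
    d_unrot = {(d.i, d.j, d.k, d.l): d for d in top_unrotated.proper_dihedrals}
    for d in top_rotated.proper_dihedrals:
        other = d_unrot.get((d.i, d.j, d.k, d.l))
        if other is None:
            raise TopologyError(f"dihedral {(d.i, d.j, d.k, d.l)} missing in unrotated topology")
        dihedrals.append(replace(d, phi0=circular_mean(d.phi0, other.phi0), weight=0.0))

    map_rot = {(i, j): r for (i, j, r) in compute_contact_map(struct_rotated, params)}
    map_unrot = {(i, j): r for (i, j, r) in compute_contact_map(struct_unrotated, params)}

    def make_pair(i, j, sigma_prime, eps, cls, r_a, r_b, frac):
        if params.sigma_scale_stage == "before_solve":
            scale_now = 1.0  # distances were pre-scaled below
        else:
            scale_now = params.sigma_scale
        if cls != "common" and not params.scale_unique:
            scale_now = 1.0
        return ContactPair(
            i=i, j=j, sigma=scale_now * sigma_prime, sigma_prime=sigma_prime,
            eps=eps, contact_class=cls, r_native_a=r_a, r_native_b=r_b,
            iso_fraction=frac,
        )

    pre = params.sigma_scale if params.sigma_scale_stage == "before_solve" else 1.0

    contacts: list[ContactPair] = []
    for key in sorted(set(map_rot) | set(map_unrot)):
        i, j = key
        in_rot, in_unrot = key in map_rot, key in map_unrot
        inter = _is_inter_subunit(struct_rotated, idx, i, j)
        if in_rot and in_unrot:
            r_a, r_b = pre * map_rot[key], pre * map_unrot[key]
            sigma_prime, frac = solve_isoenergetic_sigma(r_a, r_b)
            if not inter or frac > params.iso_threshold:
                contacts.append(make_pair(i, j, sigma_prime, 1.0, "common",
                                          map_rot[key], map_unrot[key], frac))
            elif r_a <= r_b:
                contacts.append(make_pair(i, j, r_a, params.w_rotated_unique,
                                          "rotated_unique", map_rot[key], map_unrot[key], frac))
            else:
                contacts.append(make_pair(i, j, r_b, params.w_unrotated_unique,
                                          "unrotated_unique", map_rot[key], map_unrot[key], frac))
        elif in_rot:
            r_a = pre * map_rot[key]
            if not inter:
                contacts.append(make_pair(i, j, r_a, 1.0, "common", map_rot[key], None, None))
            else:
                contacts.append(make_pair(i, j, r_a, params.w_rotated_unique,
                                          "rotated_unique", map_rot[key], None, None))
        else:
            r_b = pre * map_unrot[key]
            if not inter:
                contacts.append(make_pair(i, j, r_b, 1.0, "common", None, map_unrot[key], None))
            else:
                contacts.append(make_pair(i, j, r_b, params.w_unrotated_unique,
                                          "unrotated_unique", None, map_unrot[key], None))

    exclusions = set(top_rotated.exclusions) | set(top_unrotated.exclusions)
    exclusions |= {(c.i, c.j) for c in contacts}

    merged = Topology(
        atoms=struct_rotated,
        bonds=bonds,
        angles=angles,
        impropers=list(top_rotated.impropers),
        planar_dihedrals=list(top_rotated.planar_dihedrals),
        proper_dihedrals=dihedrals,
        contacts=contacts,
        eps_nc=params.eps_nc,
        sigma_nc=params.sigma_nc,
        exclusions=exclusions,
    )
    merged = assign_dihedral_strengths(merged, params)
    merged = normalize_energies(merged, params)
    return merged


def contact_map_report(topology: Topology) -> "pandas.DataFrame":  # noqa: F821
    """Tabular contact report (i, j, r_A, r_B, sigma, eps, class)."""
    import pandas as pd

    rows = [
        {
            "i": c.i, "j": c.j,
            "r_rotated": c.r_native_a, "r_unrotated": c.r_native_b,
            "sigma": c.sigma, "eps": c.eps,
            "iso_fraction": c.iso_fraction, "class": c.contact_class,
        }
        for c in topology.contacts
    ]
    return pd.DataFrame(rows)
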