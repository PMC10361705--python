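"""Structure, trajectory and topology file I/O plus the shared geometric types.

Coordinates are stored in nm internally (PDB Angstrom values are converted on
read), energies in reduced units.  PDB/GRO handling is delegated to biotite;
XTC/TRR trajectories are read through MDAnalysis; plain-text XYZ is supported
as an exchange dialect for desk-scale systems.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

A_TO_NM = 0.1

SUBUNIT_LABELS = ("LSU", "SSU_body", "SSU_head", "other")

# minimal residue-name -> polymer-type lookup; toy generators register their own
_PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "TOY",  # generic protein-like toy residue
}
_NUCLEIC_RESNAMES = {
    "A", "U", "G", "C", "DA", "DT", "DG", "DC", "RA", "RU", "RG", "RC",
    "TON",  # generic nucleic-like toy residue
}


class StructureFormatError(ValueError):
    """Raised when a structure or topology file cannot be parsed."""


class TrajectoryError(ValueError):
    """Raised for trajectory reading problems (truncation, atom mismatch)."""


@dataclass
class MolecularStructure:
    """All non-hydrogen atoms of a (macro)molecular model.

    Parallel arrays over atoms; ``positions`` are in nm.  ``subunits`` carries
    one of ``LSU``, ``SSU_body``, ``SSU_head`` or ``other`` per atom and
    ``polymer_types`` one of ``protein`` / ``nucleic_acid`` per atom.
    """

    serials: np.ndarray
    names: np.ndarray
    elements: np.ndarray
    residue_index: np.ndarray
    residue_names: np.ndarray
    chain_ids: np.ndarray
    positions: np.ndarray
    subunits: np.ndarray = field(default=None)
    polymer_types: np.ndarray = field(default=None)

    def __post_init__(self):
        self.serials = np.asarray(self.serials, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        for attr in ("names", "elements", "residue_names", "chain_ids"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=object))
        self.residue_index = np.asarray(self.residue_index, dtype=np.int64)
        n = len(self.serials)
        if n == 0:
            raise StructureFormatError("structure contains no atoms")
        if self.positions.shape != (n, 3):
            raise StructureFormatError(
                f"positions shape {self.positions.shape} != ({n}, 3)"
            )
        if not np.all(np.isfinite(self.positions)):
            raise StructureFormatError("non-finite coordinates")
        if len(np.unique(self.serials)) != n:
            raise StructureFormatError("duplicate atom serials")
        if self.subunits is None:
            self.subunits = np.asarray(["other"] * n, dtype=object)
        else:
            self.subunits = np.asarray(self.subunits, dtype=object)
            bad = set(self.subunits) - set(SUBUNIT_LABELS)
            if bad:
                raise StructureFormatError(f"unknown subunit labels: {sorted(bad)}")
        if self.polymer_types is None:
            self.polymer_types = np.asarray(
                [_polymer_type_of(rn) for rn in self.residue_names], dtype=object
            )
        else:
            self.polymer_types = np.asarray(self.polymer_types, dtype=object)

    @property
    def n_atoms(self) -> int:
        return len(self.serials)

    def subset(self, mask: np.ndarray) -> "MolecularStructure":
        mask = np.asarray(mask)
        return MolecularStructure(
            serials=self.serials[mask],
            names=self.names[mask],
            elements=self.elements[mask],
            residue_index=self.residue_index[mask],
            residue_names=self.residue_names[mask],
            chain_ids=self.chain_ids[mask],
            positions=self.positions[mask],
            subunits=self.subunits[mask],
            polymer_types=self.polymer_types[mask],
        )

    def with_positions(self, positions: np.ndarray) -> "MolecularStructure":
        out = self.subset(np.ones(self.n_atoms, dtype=bool))
        out.positions = np.asarray(positions, dtype=np.float64)
        if out.positions.shape != (self.n_atoms, 3):
            raise ValueError("replacement positions have wrong shape")
        return out

    def same_atom_table(self, other: "MolecularStructure") -> bool:
        return (
            self.n_atoms == other.n_atoms
            and np.array_equal(self.serials, other.serials)
            and all(self.names == other.names)
            and np.array_equal(self.residue_index, other.residue_index)
            and all(self.chain_ids == other.chain_ids)
        )


@dataclass
class Trajectory:
    """Ordered coordinate frames (nm) sharing one atom table.

    ``frame_interval`` is the time between saved frames in reduced time units;
    ``potential_energy`` (per frame, reduced units) is required for
    temperature reweighting and optional otherwise.
    """

    frames: np.ndarray
    frame_interval: float
    potential_energy: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TrajectoryError(f"frames must be (n_frames, n_atoms, 3), got {self.frames.shape}")
        if self.frame_interval <= 0:
            raise TrajectoryError("frame_interval must be positive")
        if self.potential_energy is not None:
            self.potential_energy = np.asarray(self.potential_energy, dtype=np.float64)
            if len(self.potential_energy) != len(self.frames):
                raise TrajectoryError("potential_energy length differs from frame count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass
class ResidueMapping:
    """Reference->target residue correspondence, one dict per domain.

    Stands in for a structural alignment (e.g. STAMP) between a reference
    ribosome and the system under study; must be one-to-one within each
    domain.
    """

    domains: dict[str, dict[int, int]]

    def __post_init__(self):
        for domain, pairs in self.domains.items():
            targets = list(pairs.values())
            if len(set(targets)) != len(targets):
                raise StructureFormatError(f"duplicate target residue in domain {domain!r}")

    def domain(self, name: str) -> dict[int, int]:
        if name not in self.domains:
            raise KeyError(f"mapping has no domain {name!r}; present: {sorted(self.domains)}")
        return self.domains[name]


def _polymer_type_of(residue_name: str) -> str:
    rn = residue_name.strip().upper()
    if rn in _NUCLEIC_RESNAMES:
        return "nucleic_acid"
    if rn in _PROTEIN_RESNAMES:
        return "protein"
    # unknown residues default to protein; callers may override per chain
    return "protein"


def _is_hydrogen(element: str, name: str) -> bool:
    el = element.strip().upper()
    if el:
        return el == "H"
    nm = name.strip().upper()
    return nm.startswith("H") or (len(nm) > 1 and nm[0].isdigit() and nm[1] == "H")


def read_structure(
    path: str | os.PathLike,
    chain_subunits: dict[str, str] | None = None,
    chain_polymer: dict[str, str] | None = None,
    keep_hetero: bool = False,
) -> MolecularStructure:
    """Read a PDB file into a :class:`MolecularStructure`.

    Coordinates are converted Angstrom -> nm, hydrogens are removed, and
    HETATM records (ions/ligands) are dropped unless ``keep_hetero`` is set.
    ``chain_subunits`` maps chain IDs to subunit labels; unmapped chains get
    ``other``.  ``chain_polymer`` overrides the residue-name based
    protein/nucleic-acid classification per chain.
    """
    import biotite.structure.io.pdb as pdbio

    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        atoms = pdb_file.get_structure(model=1, extra_fields=["atom_id"])
    except Exception as exc:  # report the offending line where we can find it
        line_no = _first_bad_atom_line(path)
        where = f" (line {line_no})" if line_no else ""
        raise StructureFormatError(f"cannot parse PDB {path}{where}: {exc}") from exc

    keep = np.ones(atoms.array_length(), dtype=bool)
    if not keep_hetero:
        keep &= ~atoms.hetero
    for i in range(atoms.array_length()):
        if keep[i] and _is_hydrogen(atoms.element[i], atoms.atom_name[i]):
            keep[i] = False
    if not keep.any():
        raise StructureFormatError(f"no non-hydrogen atoms in {path}")

    atoms = atoms[keep]
    chain_subunits = chain_subunits or {}
    subunits = np.asarray(
        [chain_subunits.get(c, "other") for c in atoms.chain_id], dtype=object
    )
    if chain_polymer:
        polymer = np.asarray(
            [
                chain_polymer.get(c, _polymer_type_of(rn))
                for c, rn in zip(atoms.chain_id, atoms.res_name)
            ],
            dtype=object,
        )
    else:
        polymer = None

    return MolecularStructure(
        serials=atoms.atom_id,
        names=atoms.atom_name,
        elements=atoms.element,
        residue_index=atoms.res_id,
        residue_names=atoms.res_name,
        chain_ids=atoms.chain_id,
        positions=atoms.coord * A_TO_NM,
        subunits=subunits,
        polymer_types=polymer,
    )


def _first_bad_atom_line(path) -> int | None:
    try:
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                if line.startswith(("ATOM", "HETATM")):
                    try:
                        float(line[30:38]), float(line[38:46]), float(line[46:54])
                    except (ValueError, IndexError):
                        return i
    except OSError:
        return None
    return None


def _to_atom_array(structure: MolecularStructure):
    import biotite.structure as struc

    atoms = struc.AtomArray(structure.n_atoms)
    atoms.coord = structure.positions / A_TO_NM
    atoms.chain_id = np.asarray(structure.chain_ids, dtype="U4")
    atoms.res_id = structure.residue_index
    atoms.res_name = np.asarray(structure.residue_names, dtype="U5")
    atoms.atom_name = np.asarray(structure.names, dtype="U6")
    atoms.element = np.asarray(structure.elements, dtype="U2")
    atoms.set_annotation("atom_id", structure.serials)
    return atoms


def write_structure(structure: MolecularStructure, path: str | os.PathLike) -> None:
    """Write PDB (``.pdb``) or GRO (``.gro``), chosen by file suffix."""
    suffix = os.path.splitext(str(path))[1].lower()
    if suffix == ".gro":
        import biotite.structure.io.gro as groio

        atoms = _to_atom_array(structure)
        gro = groio.GROFile()
        gro.set_structure(atoms)
        gro.write(str(path))
    else:
        import biotite.structure.io.pdb as pdbio

        atoms = _to_atom_array(structure)
        pdb = pdbio.PDBFile()
        pdb.set_structure(atoms)
        pdb.write(str(path))


# --- trajectories -----------------------------------------------------------


def read_trajectory(
    path: str | os.PathLike,
    structure: MolecularStructure,
    frame_interval: float = 1.0,
) -> Trajectory:
    """Read an XTC/TRR (via MDAnalysis) or plain XYZ trajectory.

    Frames are converted to nm.  The atom count must match ``structure``;
    a mismatch or a truncated file raises :class:`TrajectoryError`.
    """
    suffix = os.path.splitext(str(path))[1].lower()
    if suffix == ".xyz":
        frames = _read_xyz_frames(path)
    elif suffix in (".xtc", ".trr"):
        from MDAnalysis import coordinates as mdacoords

        reader_cls = mdacoords.XTC.XTCReader if suffix == ".xtc" else mdacoords.TRR.TRRReader
        try:
            reader = reader_cls(str(path))
            frames = np.array([ts.positions.copy() for ts in reader]) * A_TO_NM
        except Exception as exc:
            raise TrajectoryError(f"cannot read trajectory {path}: {exc}") from exc
    else:
        raise TrajectoryError(f"unsupported trajectory format: {suffix!r}")

    if frames.shape[1] != structure.n_atoms:
        raise TrajectoryError(
            f"trajectory has {frames.shape[1]} atoms but structure has {structure.n_atoms}"
        )
    return Trajectory(frames=frames, frame_interval=frame_interval)


def _read_xyz_frames(path) -> np.ndarray:
    """Parse multi-frame XYZ (coordinates in Angstrom) into an (F, N, 3) nm array."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise TrajectoryError(f"{path}: expected atom count at line {i + 1}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise TrajectoryError(f"{path}: truncated frame at line {i + 1} (needs {n} atoms)")
        coords = np.empty((n, 3))
        for j, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise TrajectoryError(f"{path}: malformed atom line {i + 3 + j}")
            coords[j] = [float(x) for x in parts[1:4]]
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise TrajectoryError(f"{path}: no frames")
    return np.array(frames) * A_TO_NM


def write_trajectory_xyz(
    trajectory: Trajectory, structure: MolecularStructure, path: str | os.PathLike
) -> None:
    """Write frames as multi-frame XYZ in Angstrom (desk-scale systems only)."""
    with open(path, "w") as fh:
        for f, frame in enumerate(trajectory.frames):
            fh.write(f"{structure.n_atoms}\n")
            fh.write(f"frame {f}\n")
            for name, (x, y, z) in zip(structure.names, frame / A_TO_NM):
                el = str(name)[:1]
                fh.write(f"{el} {x:14.6f} {y:14.6f} {z:14.6f}\n")


# --- residue mappings -------------------------------------------------------


def read_residue_mapping(
    path: str | os.PathLike, required_domains: tuple[str, ...] = ("LSU", "SSU_body")
) -> ResidueMapping:
    """Read a TSV of (domain, reference_residue, target_residue) rows.

    Each domain section must define a one-to-one correspondence; missing
    required domains and duplicated targets are errors.
    """
    import pandas as pd

    table = pd.read_csv(path, sep="\t", comment="#")
    needed = {"domain", "reference_residue", "target_residue"}
    if not needed.issubset(table.columns):
        raise StructureFormatError(
            f"mapping file must have columns {sorted(needed)}, got {list(table.columns)}"
        )
    domains: dict[str, dict[int, int]] = {}
    for domain, sub in table.groupby("domain"):
        refs = sub["reference_residue"].astype(int).tolist()
        tgts = sub["target_residue"].astype(int).tolist()
        if len(set(refs)) != len(refs):
            raise StructureFormatError(f"duplicate reference residue in domain {domain!r}")
        domains[str(domain)] = dict(zip(refs, tgts))
    for dom in required_domains:
        if dom not in domains:
            raise StructureFormatError(f"mapping file lacks required domain {dom!r}")
    return ResidueMapping(domains=domains)


def write_residue_mapping(mapping: ResidueMapping, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("domain\treference_residue\ttarget_residue\n")
        for domain, pairs in mapping.domains.items():
            for ref, tgt in pairs.items():
                fh.write(f"{domain}\t{ref}\t{tgt}\n")


# --- GROMACS-dialect topology files ----------------------------------------


def write_topology(topology, path: str | os.PathLike) -> None:
    """Write a topology in a GROMACS-style dialect.

    Contacts are emitted as 12-6 pair interactions with ``C6 = 2 eps sigma^6``
    and ``C12 = eps sigma^12`` so the minimum sits at ``sigma`` with depth
    ``eps``.  Dihedral rows carry a function tag: ``proper``, ``improper`` or
    ``planar``.
    """
    top = topology
    missing = []
    if top.atoms is None or top.atoms.n_atoms == 0:
        missing.append("atoms")
    for section in ("bonds", "angles", "proper_dihedrals", "contacts"):
        if getattr(top, section) is None:
            missing.append(section)
    if missing:
        raise StructureFormatError(f"topology incomplete, missing sections: {missing}")

    with open(path, "w") as fh:
        fh.write("; mbrot structure-based topology (reduced units, nm)\n")
        fh.write(f"; nonbonded eps_nc={top.eps_nc:.6g} sigma_nc={top.sigma_nc:.6g}\n")
        fh.write("\n[ atoms ]\n; serial name residue resname chain subunit polymer\n")
        s = top.atoms
        for k in range(s.n_atoms):
            fh.write(
                f"{s.serials[k]:6d} {s.names[k]:>6s} {s.residue_index[k]:5d} "
                f"{s.residue_names[k]:>5s} {s.chain_ids[k]:>2s} {s.subunits[k]:>8s} "
                f"{s.polymer_types[k]}\n"
            )
        fh.write("\n[ bonds ]\n; i j r0_nm eps_r\n")
        for (i, j, r0, k) in top.bonds:
            fh.write(f"{int(i):6d} {int(j):6d} {r0:.9f} {k:.9g}\n")
        fh.write("\n[ angles ]\n; i j k theta0_rad eps_theta\n")
        for (i, j, k_, t0, w) in top.angles:
            fh.write(f"{int(i):6d} {int(j):6d} {int(k_):6d} {t0:.9f} {w:.9g}\n")
        fh.write("\n[ dihedrals ]\n; i j k l value weight kind class group\n")
        for (i, j, k_, l, chi0, w) in top.impropers:
            fh.write(
                f"{int(i):6d} {int(j):6d} {int(k_):6d} {int(l):6d} "
                f"{chi0:.9f} {w:.9g} improper - -\n"
            )
        for (i, j, k_, l, w) in top.planar_dihedrals:
            fh.write(
                f"{int(i):6d} {int(j):6d} {int(k_):6d} {int(l):6d} "
                f"{0.0:.9f} {w:.9g} planar - -\n"
            )
        for d in top.proper_dihedrals:
            fh.write(
                f"{d.i:6d} {d.j:6d} {d.k:6d} {d.l:6d} {d.phi0:.9f} {d.weight:.9g} "
                f"proper {d.kind} {d.group}\n"
            )
        fh.write("\n[ pairs ]\n; i j C6 C12 class\n")
        for c in top.contacts:
            c6 = 2.0 * c.eps * c.sigma**6
            c12 = c.eps * c.sigma**12
            fh.write(f"{c.i:6d} {c.j:6d} {c6:.12g} {c12:.12g} {c.contact_class}\n")
        fh.write("\n[ exclusions ]\n; i j\n")
        for (i, j) in sorted(top.exclusions):
            fh.write(f"{int(i):6d} {int(j):6d}\n")


def read_topology(path: str | os.PathLike):
    """Parse a topology written by :func:`write_topology` back into a Topology."""
    from .model_builder import ContactPair, ProperDihedral, Topology

    sections: dict[str, list[list[str]]] = {}
    current = None
    eps_nc, sigma_nc = 0.01, 0.25
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split(";")[0].strip()
            if raw.startswith("; nonbonded"):
                parts = dict(p.split("=") for p in raw.replace("; nonbonded", "").split())
                eps_nc = float(parts["eps_nc"])
                sigma_nc = float(parts["sigma_nc"])
            if not line:
                continue
            if line.startswith("["):
                current = line.strip("[] ").lower()
                sections[current] = []
                continue
            if current is None:
                raise StructureFormatError(f"{path}: data outside any section at line {lineno}")
            sections[current].append(line.split())

    for needed in ("atoms", "bonds", "angles", "dihedrals", "pairs"):
        if needed not in sections:
            raise StructureFormatError(f"{path}: missing section [ {needed} ]")

    arows = sections["atoms"]
    atoms = MolecularStructure(
        serials=[int(r[0]) for r in arows],
        names=[r[1] for r in arows],
        elements=[r[1][0] for r in arows],
        residue_index=[int(r[2]) for r in arows],
        residue_names=[r[3] for r in arows],
        chain_ids=[r[4] for r in arows],
        positions=np.zeros((len(arows), 3)),
        subunits=[r[5] for r in arows],
        polymer_types=[r[6] for r in arows],
    )
    bonds = [(int(r[0]), int(r[1]), float(r[2]), float(r[3])) for r in sections["bonds"]]
    angles = [
        (int(r[0]), int(r[1]), int(r[2]), float(r[3]), float(r[4]))
        for r in sections["angles"]
    ]
    impropers, planars, propers = [], [], []
    for r in sections["dihedrals"]:
        i, j, k, l = (int(x) for x in r[:4])
        value, weight, tag = float(r[4]), float(r[5]), r[6]
        if tag == "improper":
            impropers.append((i, j, k, l, value, weight))
        elif tag == "planar":
            planars.append((i, j, k, l, weight))
        else:
            propers.append(
                ProperDihedral(i=i, j=j, k=k, l=l, phi0=value, weight=weight,
                               kind=r[7], group=r[8])
            )
    contacts = []
    for r in sections["pairs"]:
        i, j, c6, c12 = int(r[0]), int(r[1]), float(r[2]), float(r[3])
        sigma = (2.0 * c12 / c6) ** (1.0 / 6.0)
        eps = c6**2 / (4.0 * c12)
        contacts.append(
            ContactPair(i=i, j=j, sigma=sigma, sigma_prime=sigma, eps=eps,
                        contact_class=r[4] if len(r) > 4 else "common")
        )
    exclusions = {tuple(int(x) for x in r[:2]) for r in sections.get("exclusions", [])}
    return Topology(
        atoms=atoms,
        bonds=bonds,
        angles=angles,
        impropers=impropers,
        planar_dihedrals=planars,
        proper_dihedrals=propers,
        contacts=contacts,
        eps_nc=eps_nc,
        sigma_nc=sigma_nc,
        exclusions=exclusions,
    )
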