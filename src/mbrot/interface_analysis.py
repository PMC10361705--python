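"""Inter-subunit contact formation along the rotation coordinate, and per-atom
flexibility (rmsf) of the rotated/unrotated ensembles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_builder import ContactPair
from .rotation_geometry import superpose
from .structio import Trajectory


class AnalysisError(ValueError):
    pass


def contact_formed(distance: float, sigma: float, formation_factor: float = 1.2):
    """A contact is formed iff ``distance < formation_factor * sigma`` (strict).

    The 1.2 factor is the common native-contact formation convention.
    Accepts scalars or arrays.
    """
    if np.any(np.asarray(distance) <= 0) or np.any(np.asarray(sigma) <= 0):
        raise AnalysisError("distance and sigma must be positive")
    return np.asarray(distance) < formation_factor * np.asarray(sigma)


@dataclass
class ContactTimeline:
    """Per-bin contact formation probabilities along a coordinate.

    ``p_contact[b, c]`` is the formation frequency of contact ``c`` among the
    frames falling in coordinate bin ``b``; ``p_atom[b, a]`` is the average
    over the contacts that involve atom ``a`` (so ``p_atom * n_contacts``
    recovers the per-atom sum exactly).
    """

    bin_edges: np.ndarray
    bin_counts: np.ndarray
    contact_pairs: list[tuple[int, int]]
    p_contact: np.ndarray
    atom_serials: np.ndarray
    n_contacts_per_atom: np.ndarray
    p_atom: np.ndarray


def contact_probability_vs_q(
    trajectory: Trajectory,
    contacts: list[ContactPair],
    angle_series: np.ndarray,
    bins=40,
    formation_factor: float = 1.2,
    structure=None,
) -> ContactTimeline:
    """Formation probability of each contact, binned over a coordinate.

    ``contacts`` is typically restricted to one class (rotated-unique or
    unrotated-unique) before the call; ``angle_series`` must be aligned
    frame-by-frame with the trajectory.  Pass ``structure`` when atom serials
    are not simply 1..n_atoms in frame order.
    """
    angle_series = np.asarray(angle_series, dtype=float)
    if len(angle_series) != trajectory.n_frames:
        raise AnalysisError(
            f"angle series has {len(angle_series)} entries for "
            f"{trajectory.n_frames} frames"
        )
    if not contacts:
        raise AnalysisError("no contacts supplied")

    serials = structure.serials if structure is not None else np.arange(trajectory.n_atoms) + 1
    serial_to_index = {int(s): k for k, s in enumerate(serials)}

    ii = np.array([serial_to_index[c.i] for c in contacts])
    jj = np.array([serial_to_index[c.j] for c in contacts])
    sigma = np.array([c.sigma for c in contacts])

    diff = trajectory.frames[:, ii, :] - trajectory.frames[:, jj, :]
    dist = np.linalg.norm(diff, axis=2)                      # (F, C)
    formed = contact_formed(dist, sigma[None, :], formation_factor)

    counts, edges = np.histogram(angle_series, bins=bins)
    n_bins = len(edges) - 1
    assign = np.clip(np.digitize(angle_series, edges) - 1, 0, n_bins - 1)

    p_contact = np.full((n_bins, len(contacts)), np.nan)
    for b in range(n_bins):
        mask = assign == b
        if counts[b] > 0:
            p_contact[b] = formed[mask].mean(axis=0)

    atom_serials = np.unique(np.array([[c.i, c.j] for c in contacts]).ravel())
    atom_pos = {int(s): k for k, s in enumerate(atom_serials)}
    n_per_atom = np.zeros(len(atom_serials))
    membership = np.zeros((len(atom_serials), len(contacts)))
    for c_idx, c in enumerate(contacts):
        for s in (c.i, c.j):
            a = atom_pos[int(s)]
            n_per_atom[a] += 1
            membership[a, c_idx] = 1.0
    p_atom = (p_contact @ membership.T) / n_per_atom[None, :]

    return ContactTimeline(
        bin_edges=edges, bin_counts=counts, contact_pairs=[(c.i, c.j) for c in contacts],
        p_contact=p_contact, atom_serials=atom_serials,
        n_contacts_per_atom=n_per_atom, p_atom=p_atom,
    )


def tse_contact_atoms(
    timeline: ContactTimeline,
    tse_window: tuple[float, float] = (3.0, 4.0),
    probability_threshold: float = 0.8,
) -> list[int]:
    """Atoms with at least one contact formed above threshold inside the TSE.

    In-window formation probabilities are count-weighted averages of the
    per-bin values; the window defaults to a 1-degree band around the
    transition-state-ensemble position of the rotation coordinate.
    """
    centers = 0.5 * (timeline.bin_edges[:-1] + timeline.bin_edges[1:])
    lo, hi = tse_window
    in_window = (centers >= lo) & (centers <= hi) & (timeline.bin_counts > 0)
    if not np.any(in_window):
        raise AnalysisError(f"no occupied bins inside the TSE window [{lo}, {hi}]")
    w = timeline.bin_counts[in_window].astype(float)
    p_window = (w[:, None] * timeline.p_contact[in_window]).sum(axis=0) / w.sum()

    atoms = set()
    for c_idx, (i, j) in enumerate(timeline.contact_pairs):
        if p_window[c_idx] > probability_threshold:
            atoms.add(i)
            atoms.add(j)
    return sorted(atoms)


# --- flexibility ------------------------------------------------------------


def rmsf(
    trajectory: Trajectory,
    ensemble_window: tuple[float, float],
    angle_series: np.ndarray,
    alignment_core: np.ndarray,
) -> np.ndarray:
    """Per-atom rmsf (nm) within one coordinate-defined ensemble.

    Frames with coordinate inside ``ensemble_window`` are aligned on the
    ``alignment_core`` atom indices (removing rigid-body motion), first onto
    the initial frame and then onto the resulting mean structure; the rmsf is
    ``sqrt(<|x_i - <x_i>|^2>)``.
    """
    angle_series = np.asarray(angle_series, dtype=float)
    if len(angle_series) != trajectory.n_frames:
        raise AnalysisError("angle series misaligned with trajectory")
    lo, hi = ensemble_window
    mask = (angle_series > lo) & (angle_series < hi)
    frames = trajectory.frames[mask]
    if len(frames) < 2:
        raise AnalysisError(f"fewer than 2 frames in window [{lo}, {hi}]")
    core = np.asarray(alignment_core, dtype=int)

    def align_all(frames_in, reference):
        out = np.empty_like(frames_in)
        for k, fr in enumerate(frames_in):
            rmat, t, _ = superpose(fr[core], reference[core])
            out[k] = fr @ rmat.T + t
        return out

    aligned = align_all(frames, frames[0])
    aligned = align_all(aligned, aligned.mean(axis=0))
    mean = aligned.mean(axis=0)
    return np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))


def delta_rmsf(rmsf_rotated: np.ndarray, rmsf_unrotated: np.ndarray) -> np.ndarray:
    """Per-atom flexibility change upon rotation (positive = more mobile)."""
    return np.asarray(rmsf_rotated) - np.asarray(rmsf_unrotated)
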