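"""Conformational deformations and their projection onto normal modes.

The experimentally observed change between two conformations (e.g. an open
and a closed crystal form) is condensed into a single 3M-dimensional
deformation vector over the M mapped C-alpha sites, after least-squares
rigid superposition removes the external (translation/rotation) degrees of
freedom.  Its similarity to an ANM mode u_k is the correlation cosine
cos(u_k, dr); a subset of m modes accounts for the deformation with
cumulative overlap

    CO(m) = sqrt( sum_{k=1..m} cos^2(u_k, dr) )

which reaches 1 once the mode basis spans the internal subspace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elastic_models import ModeSet
from .structure_io import AlignmentMap, CoarseModel, Structure

__all__ = [
    "DeformationVector",
    "superpose",
    "apply_transform",
    "deformation_vector",
    "overlap",
    "cumulative_overlap",
    "generate_conformers",
]


@dataclass(frozen=True)
class DeformationVector:
    """Superposition-free displacement over mapped nodes.

    ``delta`` is the 3M vector (Angstrom) of mapped "closed" coordinates,
    superposed onto the "open" frame, minus the open coordinates;
    ``rmsd`` is |delta| / sqrt(M).
    """

    delta: np.ndarray
    mapping: AlignmentMap
    rmsd: float

    @property
    def n_mapped(self) -> int:
        return len(self.mapping)


def _check_superposable(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise ValueError("superposition needs at least 3 mapped pairs")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("mapped coordinates are collinear")


def superpose(coords_a: np.ndarray, coords_b: np.ndarray,
              mapping: AlignmentMap | None = None
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch) of B onto A.

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (det = +1) such that ``coords_b @ rotation.T + translation`` best fits
    ``coords_a`` over the mapped pairs.
    """
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    if mapping is None:
        if coords_a.shape != coords_b.shape:
            raise ValueError("shapes differ and no mapping given")
        a_sel, b_sel = coords_a, coords_b
    else:
        a_sel = coords_a[mapping.a_indices]
        b_sel = coords_b[mapping.b_indices]
    _check_superposable(a_sel)
    _check_superposable(b_sel)

    cen_a = a_sel.mean(axis=0)
    cen_b = b_sel.mean(axis=0)
    cov = (b_sel - cen_b).T @ (a_sel - cen_a)
    u, _, vt = np.linalg.svd(cov)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T
    trans = cen_a - rot @ cen_b
    moved = b_sel @ rot.T + trans
    rmsd = float(np.sqrt(((moved - a_sel) ** 2).sum() / a_sel.shape[0]))
    return rot, trans, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ rotation.T + translation


def _coords_of(obj) -> np.ndarray:
    if isinstance(obj, CoarseModel):
        return obj.coords
    if isinstance(obj, Structure):
        raise TypeError("build a CoarseModel first")
    return np.asarray(obj, dtype=float).reshape(-1, 3)


def deformation_vector(open_model, closed_model,
                       mapping: AlignmentMap | None = None
                       ) -> DeformationVector:
    """Deformation from the open toward the closed conformation on mapped
    nodes, after optimal superposition of closed onto open."""
    open_xyz = _coords_of(open_model)
    closed_xyz = _coords_of(closed_model)
    if mapping is None:
        if open_xyz.shape[0] != closed_xyz.shape[0]:
            raise ValueError("node counts differ and no mapping given")
        mapping = AlignmentMap.identity(open_xyz.shape[0])
    mapping.validate(open_xyz.shape[0], closed_xyz.shape[0])
    rot, trans, rmsd = superpose(open_xyz, closed_xyz, mapping)
    moved = apply_transform(closed_xyz[mapping.b_indices], rot, trans)
    delta = (moved - open_xyz[mapping.a_indices]).ravel()
    return DeformationVector(delta, mapping, rmsd)


def _mapped_mode(mode_vector: np.ndarray,
                 deformation: DeformationVector) -> np.ndarray:
    """Slice a 3N mode of the open model to the mapped nodes, renormalized."""
    u = np.asarray(mode_vector, dtype=float)
    m = deformation.n_mapped
    if u.size == 3 * m:
        sliced = u
    else:
        idx = deformation.mapping.a_indices
        sliced = u.reshape(-1, 3)[idx].ravel()
    norm = np.linalg.norm(sliced)
    if norm == 0:
        raise ValueError("mode vector vanishes on mapped nodes")
    return sliced / norm


def overlap(mode_vector: np.ndarray,
            deformation: DeformationVector) -> float:
    """Signed correlation cosine between a mode and the deformation."""
    dnorm = np.linalg.norm(deformation.delta)
    # below superposition round-off (Angstrom scale) the direction is noise
    if dnorm < 1e-10:
        raise ValueError("no conformational change")
    u = _mapped_mode(mode_vector, deformation)
    return float(u @ deformation.delta / dnorm)


def cumulative_overlap(modes: ModeSet, deformation: DeformationVector,
                       m: int | None = None) -> np.ndarray:
    """CO(1..m) profile; entry i-1 is CO(i) = sqrt(sum of the first i
    squared cosines).  Non-decreasing; equals 1 at m = 3M-6 for a full
    mapping."""
    if m is None:
        m = modes.n_modes
    if not 1 <= m <= modes.n_modes:
        raise ValueError(f"m={m} outside 1..{modes.n_modes}")
    cos2 = np.array(
        [overlap(modes.mode(k), deformation) ** 2 for k in range(1, m + 1)]
    )
    return np.sqrt(np.cumsum(cos2))


def amplitude_for_rmsd(modes: ModeSet, k: int, target_rmsd: float) -> float:
    """Amplitude s_k such that the C-alpha RMSD of each conformer from the
    reference equals ``target_rmsd`` (unit mode norm assumed)."""
    lam = modes.eigenvalue(k)
    n = modes.n_nodes
    return float(target_rmsd * np.sqrt(n * lam))


def generate_conformers(model: CoarseModel, modes: ModeSet, k: int,
                        amplitude: float | None = None,
                        target_rmsd: float = 1.0,
                        all_atom_source: CoarseModel | None = None):
    """Harmonic conformer pair along non-zero ANM mode ``k``:

        R(+/-) = R0 +/- s_k * lambda_k^(-1/2) * u_k

    Returns two (N, 3) coordinate arrays.  With ``all_atom_source`` (a
    CoarseModel carrying heavy atoms) two displaced CoarseModels are
    returned instead, every atom of a residue shifted rigidly by that
    residue's C-alpha mode component — no subsequent minimization.
    """
    if modes.dof_per_node != 3:
        raise ValueError("conformer generation needs ANM (3-D) modes")
    if amplitude is None:
        amplitude = amplitude_for_rmsd(modes, k, target_rmsd)
    lam = modes.eigenvalue(k)
    disp = (amplitude / np.sqrt(lam)) * modes.mode(k).reshape(-1, 3)
    plus = model.coords + disp
    minus = model.coords - disp
    if all_atom_source is not None:
        return (all_atom_source.with_coords(all_atom_source.coords + disp),
                all_atom_source.with_coords(all_atom_source.coords - disp))
    return plus, minus
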