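"""Subsystem normal-mode analysis in a coupled environment, and
cross-structure slow-mode comparison.

Partitioning the ANM Hessian over a subsystem S and its environment E,

    H = [[H_SS, H_SE],
         [H_ES, H_EE]],

the effective (Schur-complement) Hessian

    H~ = H_SS - H_SE H_EE^+ H_ES

describes the stiffness of S with the elastic response of E folded in;
its normal modes are the subsystem's collective motions in the presence
of the environment.  Comparing such modes across structurally aligned
family members quantifies the conservation of slow dynamics: the summary
statistic is the mean cumulative overlap <CO(m)> of the reference's first
m modes onto the partner's first m modes, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .elastic_models import ZERO_MODE_RTOL, HessianMatrix, ModeSet
from .structure_io import AlignmentMap

__all__ = [
    "SubsystemPartition",
    "schur_complement",
    "effective_hessian",
    "subsystem_modes",
    "mode_correlation_matrix",
    "family_overlap_summary",
]


@dataclass(frozen=True)
class SubsystemPartition:
    subsystem: tuple[int, ...]       # node indices, sorted
    environment: tuple[int, ...]
    h_ss: np.ndarray
    h_se: np.ndarray
    h_ee: np.ndarray
    effective: np.ndarray            # H~ = H_SS - H_SE H_EE^+ H_ES
    dof_per_node: int = 3


def _relative_pinv(matrix: np.ndarray) -> np.ndarray:
    """Pseudoinverse with the package-wide relative zero threshold, so the
    rigid-body null space of an isolated environment is projected out."""
    return np.linalg.pinv(matrix, rcond=ZERO_MODE_RTOL, hermitian=True)


def schur_complement(matrix: np.ndarray, s_indices: np.ndarray) -> tuple[
        np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Blocks (H_SS, H_SE, H_EE, H~) of ``matrix`` for row/column set S."""
    n = matrix.shape[0]
    s_mask = np.zeros(n, dtype=bool)
    s_mask[s_indices] = True
    e_idx = np.nonzero(~s_mask)[0]
    s_idx = np.nonzero(s_mask)[0]
    h_ss = matrix[np.ix_(s_idx, s_idx)]
    h_se = matrix[np.ix_(s_idx, e_idx)]
    h_ee = matrix[np.ix_(e_idx, e_idx)]
    if h_se.size == 0 or not np.any(h_se):
        effective = h_ss.copy()
    else:
        effective = h_ss - h_se @ _relative_pinv(h_ee) @ h_se.T
    return h_ss, h_se, h_ee, effective


def effective_hessian(hessian: HessianMatrix,
                      subsystem: list[int]) -> SubsystemPartition:
    """Partition an ANM Hessian over subsystem *node* indices and build the
    effective Hessian; H_EE is pseudo-inverted so that rigid modes of the
    isolated environment do not blow up the complement."""
    n = hessian.n_nodes
    sub = sorted(set(int(i) for i in subsystem))
    if not sub:
        raise ValueError("empty subsystem")
    if any(i < 0 or i >= n for i in sub):
        raise ValueError("subsystem index out of range")
    if len(sub) == n:
        raise ValueError("subsystem covers all nodes; use plain NMA")
    env = sorted(set(range(n)) - set(sub))
    s_dof = np.concatenate([[3 * i, 3 * i + 1, 3 * i + 2] for i in sub])
    h_ss, h_se, h_ee, eff = schur_complement(hessian.matrix, s_dof)
    return SubsystemPartition(
        tuple(sub), tuple(env), h_ss, h_se, h_ee, eff, dof_per_node=3
    )


def subsystem_modes(partition: SubsystemPartition) -> ModeSet:
    """Normal modes of the effective Hessian.  Coupling to the environment
    generally removes the rigid-body nullity, so n_zero is simply counted,
    not asserted."""
    evals, evecs = scipy.linalg.eigh(partition.effective)
    lam_max = float(evals[-1]) if evals.size else 0.0
    n_zero = int(np.sum(evals <= ZERO_MODE_RTOL * max(lam_max, 1e-300)))
    return ModeSet(
        evals, evecs, n_zero, partition.dof_per_node,
        meta={"subsystem": partition.subsystem},
    )


def _sliced_mode(modes: ModeSet, k: int, node_idx: np.ndarray) -> np.ndarray:
    u = modes.mode(k).reshape(-1, modes.dof_per_node)[node_idx].ravel()
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError(f"mode {k} vanishes on mapped nodes")
    return u / norm


def mode_correlation_matrix(modes_a: ModeSet, modes_b: ModeSet,
                            mapping: AlignmentMap | None = None,
                            n: int = 10) -> np.ndarray:
    """|cosine| between the first n modes of two structures restricted to
    mapped nodes (each slice re-normalized).

    The structures must have been superposed over the mapped C-alphas
    before computing ``modes_b``, otherwise directions are not comparable.
    """
    if mapping is None:
        if modes_a.n_nodes != modes_b.n_nodes:
            raise ValueError("node counts differ and no mapping given")
        mapping = AlignmentMap.identity(modes_a.n_nodes)
    if len(mapping) < 3:
        raise ValueError("mapping too small: need at least 3 pairs")
    mapping.validate(modes_a.n_nodes, modes_b.n_nodes)
    n = min(n, modes_a.n_modes, modes_b.n_modes)
    ua = [_sliced_mode(modes_a, k, mapping.a_indices) for k in range(1, n + 1)]
    ub = [_sliced_mode(modes_b, k, mapping.b_indices) for k in range(1, n + 1)]
    out = np.empty((n, n))
    for k in range(n):
        for l in range(n):
            out[k, l] = abs(ua[k] @ ub[l])
    return out


def family_overlap_summary(matrix: np.ndarray, m: int = 10) -> float:
    """Mean cumulative overlap <CO(m)> x 100 over the reference's first m
    modes: for each row k, CO_k = min(1, sqrt(sum_l cos^2_kl)) over the
    partner's first m modes; the average is reported in percent."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < m or matrix.shape[1] < m:
        raise ValueError(
            f"m={m} exceeds available modes {matrix.shape}"
        )
    co = np.sqrt((matrix[:m, :m] ** 2).sum(axis=1))
    co = np.minimum(co, 1.0)
    return float(co.mean() * 100.0)
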