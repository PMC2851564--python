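"""Markov model of intramolecular communication.

Residue pairs are weighted by an affinity built from heavy-atom contacts,

    a_ij = N_ij / sqrt(N_i N_j),

with N_ij the number of atom-atom contacts between residues i and j within
a threshold distance (4 Angstrom by default) and N_i, N_j their heavy-atom
counts.  The column-stochastic transition matrix m_ij = a_ij / d_j gives
the probability that a signal hops from residue j to residue i in one step.
Communication is quantified by hitting times H(j|i) — the expected number
of steps for a random walk started at i to first reach j — obtained in
closed form from the degrees and the pseudoinverse of the weighted
Laplacian Gamma = D - A, and by maximum-likelihood (Dijkstra) pathways
under the edge cost -log m_ij.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .structure_io import CoarseModel

__all__ = [
    "AffinityModel",
    "MarkovModel",
    "CommunicationResult",
    "build_affinity",
    "build_markov",
    "hitting_times",
    "mean_receive_time",
    "decompose_hitting",
    "shortest_path",
    "group_path_stats",
]

DEFAULT_CONTACT_THRESHOLD = 4.0  # Angstrom, heavy-atom contact distance


@dataclass(frozen=True)
class AffinityModel:
    """Symmetric non-negative affinities with zero diagonal."""

    affinity: np.ndarray          # (N, N)
    threshold: float
    labels: tuple[str, ...] = ()

    @property
    def n_nodes(self) -> int:
        return self.affinity.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.affinity.sum(axis=0)

    @property
    def laplacian(self) -> np.ndarray:
        """Weighted Laplacian Gamma = D - A."""
        return np.diag(self.degrees) - self.affinity

    def components(self) -> list[list[int]]:
        n_comp, lab = connected_components(self.affinity > 0, directed=False)
        return [list(np.nonzero(lab == c)[0]) for c in range(n_comp)]


@dataclass(frozen=True)
class MarkovModel:
    """Column-stochastic transition matrix, m_ij = P(j -> i in one step)."""

    transition: np.ndarray
    affinity: AffinityModel

    @property
    def n_nodes(self) -> int:
        return self.transition.shape[0]


@dataclass
class CommunicationResult:
    """All-pairs hitting times and derived quantities.

    ``hitting[j, i]`` is the expected step count from source i to target j;
    ``commute = hitting + hitting.T`` is symmetric.
    """

    hitting: np.ndarray
    affinity: AffinityModel
    self_part: np.ndarray
    cross_part: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def commute(self) -> np.ndarray:
        return self.hitting + self.hitting.T

    @property
    def n_nodes(self) -> int:
        return self.hitting.shape[0]


def build_affinity(model: CoarseModel,
                   threshold: float = DEFAULT_CONTACT_THRESHOLD,
                   labels: bool = True) -> AffinityModel:
    """Affinity matrix from heavy-atom contact counts.

    Sequence neighbours receive no special treatment; ligand nodes
    participate exactly like residue nodes.
    """
    n = model.n_nodes
    atom_xyz = []
    owner = []
    for i, node in enumerate(model.nodes):
        for xyz in node.heavy_coords:
            atom_xyz.append(xyz)
            owner.append(i)
    atom_xyz = np.asarray(atom_xyz, dtype=float)
    owner = np.asarray(owner)
    n_atoms = np.bincount(owner, minlength=n).astype(float)

    counts = np.zeros((n, n))
    tree = cKDTree(atom_xyz)
    for ia, ib in tree.query_pairs(threshold):
        i, j = owner[ia], owner[ib]
        if i != j:
            counts[i, j] += 1
            counts[j, i] += 1
    aff = counts / np.sqrt(np.outer(n_atoms, n_atoms))
    np.fill_diagonal(aff, 0.0)

    degrees = aff.sum(axis=0)
    isolated = np.nonzero(degrees == 0)[0]
    if isolated.size:
        names = ", ".join(model.labels[i] for i in isolated)
        raise ValueError(f"isolated node(s) with zero affinity: {names}")
    return AffinityModel(
        aff, threshold, tuple(model.labels) if labels else ()
    )


def build_markov(affinity: AffinityModel) -> MarkovModel:
    degrees = affinity.degrees
    if np.any(degrees <= 0):
        bad = np.nonzero(degrees <= 0)[0].tolist()
        raise ValueError(f"zero-degree column(s): {bad}")
    return MarkovModel(affinity.affinity / degrees[None, :], affinity)


def _require_connected(affinity: AffinityModel) -> None:
    comps = affinity.components()
    if len(comps) > 1:
        sizes = ", ".join(str(len(c)) for c in comps)
        raise ValueError(
            f"affinity graph is disconnected: {len(comps)} components "
            f"(sizes {sizes})"
        )


def hitting_times(affinity: AffinityModel) -> CommunicationResult:
    """All-pairs hitting times from the weighted-Laplacian pseudoinverse:

        H(j|i) = sum_k d_k ( G+_ki - G+_ji - G+_kj + G+_jj )

    split into the self part (the [G+]_jj-bearing terms, dominated by the
    target's own mean-square fluctuation) and the cross part (the
    cross-correlation terms).  The commute time obeys
    tau_ij = H(j|i) + H(i|j) = Vol * effective resistance(i, j).
    """
    _require_connected(affinity)
    d = affinity.degrees
    gplus = np.linalg.pinv(affinity.laplacian, hermitian=True)
    dg = d @ gplus                      # row vector, sum_k d_k G+_k.
    vol = d.sum()
    diag = np.diag(gplus)
    # self[j, i] = sum_k d_k (G+_jj - G+_kj) : independent of i
    self_col = vol * diag - dg
    self_part = np.repeat(self_col[:, None], affinity.n_nodes, axis=1)
    # cross[j, i] = sum_k d_k (G+_ki - G+_ji)
    cross_part = dg[None, :] - vol * gplus
    hitting = self_part + cross_part
    np.fill_diagonal(hitting, 0.0)
    return CommunicationResult(hitting, affinity, self_part, cross_part)


def mean_receive_time(result: CommunicationResult,
                      convention: str = "receive") -> np.ndarray:
    """Per-node mean hitting time profile.

    ``receive`` (default): node r is profiled as the mean over all source
    nodes of the time to hit r — minima mark the most efficient receivers.
    ``broadcast``: mean over all targets of the time from node r.
    """
    if convention == "receive":
        return result.hitting.mean(axis=1)
    if convention == "broadcast":
        return result.hitting.mean(axis=0)
    raise ValueError("convention must be 'receive' or 'broadcast'")


def decompose_hitting(affinity_a: AffinityModel,
                      affinity_b: AffinityModel) -> np.ndarray:
    """Difference (state A minus state B) of the cross-correlation
    contribution to the hitting-time matrix, for two states sharing a node
    labelling (e.g. open minus closed+ligands)."""
    if affinity_a.n_nodes != affinity_b.n_nodes:
        raise ValueError(
            "states have different node counts; supply mapped models"
        )
    res_a = hitting_times(affinity_a)
    res_b = hitting_times(affinity_b)
    return res_a.cross_part - res_b.cross_part


def shortest_path(markov: MarkovModel, source: int,
                  target: int) -> tuple[list[int], float]:
    """Maximum-likelihood communication pathway.

    Dijkstra under the step cost -log m_ij for the hop j -> i; ties are
    broken by fewer hops, then lexicographic node order along the path.
    Returns (node path, total cost); cost = -log(path probability).
    """
    if source == target:
        raise ValueError("source equals target")
    n = markov.n_nodes
    with np.errstate(divide="ignore"):
        cost = -np.log(markov.transition)
    best: dict[int, tuple[float, int, tuple[int, ...]]] = {}
    heap = [(0.0, 0, (source,))]
    while heap:
        dist, hops, path = heapq.heappop(heap)
        node = path[-1]
        if node in best and (dist, hops, path) > best[node]:
            continue
        if node == target:
            return list(path), float(dist)
        for nxt in range(n):
            w = cost[nxt, node]
            if not np.isfinite(w) or nxt == node:
                continue
            cand = (dist + w, hops + 1, path + (nxt,))
            if nxt not in best or cand < best[nxt]:
                best[nxt] = cand
                heapq.heappush(heap, cand)
    raise ValueError(f"target {target} unreachable from {source}")


def group_path_stats(result: CommunicationResult, group_a: list[int],
                     group_b: list[int]) -> tuple[float, float]:
    """Mean and standard deviation of hitting times over all ordered pairs
    between two disjoint residue groups (both directions)."""
    set_a, set_b = set(group_a), set(group_b)
    if not set_a or not set_b:
        raise ValueError("empty group")
    if set_a & set_b:
        raise ValueError("groups overlap")
    values = []
    for i in set_a:
        for j in set_b:
            values.append(result.hitting[j, i])
            values.append(result.hitting[i, j])
    values = np.asarray(values)
    return float(values.mean()), float(values.std())
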