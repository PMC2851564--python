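"""Elastic network models: GNM Kirchhoff and ANM Hessian matrices, their
normal modes, and mode-derived observables.

The Gaussian network model (GNM) treats the protein as an N-node network of
C-alpha sites joined by uniform springs whenever two sites lie within a
cutoff distance R_c; its Kirchhoff (graph Laplacian) matrix Gamma fully
determines the isotropic fluctuation statistics:

    <(dR_i)^2>  =  (3 k_B T / gamma) [Gamma^-1]_ii
                =  c * sum_k (1/lambda_k) (u_k)_i^2      (non-zero modes k)

The anisotropic network model (ANM) penalises changes of the scalar
inter-node distance and yields a 3N x 3N Hessian whose 3N-6 non-zero modes
carry directional information.  gamma and c = 3 k_B T / gamma default to 1:
all fluctuations are relative, and comparison with experimental B-factors
is done after uniform mean-matching rescaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .structure_io import CoarseModel

__all__ = [
    "KirchhoffMatrix",
    "HessianMatrix",
    "ModeSet",
    "DisconnectedNetworkError",
    "DegenerateNetworkWarning",
    "build_kirchhoff",
    "build_hessian",
    "decompose",
    "msf_profile",
    "cross_correlations",
    "predict_bfactors",
    "find_hinges",
    "map_gnm_to_anm",
]

#: Community-standard C-alpha cutoffs (Angstrom).
DEFAULT_GNM_CUTOFF = 10.0
DEFAULT_ANM_CUTOFF = 15.0

#: Relative eigenvalue threshold below which a mode counts as zero.
ZERO_MODE_RTOL = 1e-10

B_FACTOR_PREFACTOR = 8.0 * np.pi**2 / 3.0


class DisconnectedNetworkError(ValueError):
    """The contact network splits into more than one component."""

    def __init__(self, components: list[list[int]]):
        self.components = components
        sizes = ", ".join(str(len(c)) for c in components)
        super().__init__(
            f"disconnected network: {len(components)} components "
            f"(sizes {sizes})"
        )


class DegenerateNetworkWarning(UserWarning):
    """ANM geometry is degenerate (e.g. collinear): unexpected null space."""


def _contact_matrix(coords: np.ndarray, cutoff: float) -> np.ndarray:
    """Boolean contact matrix; contacts use the closed interval <= cutoff."""
    dists = squareform(pdist(coords))
    contacts = dists <= cutoff
    np.fill_diagonal(contacts, False)
    return contacts


@dataclass(frozen=True)
class KirchhoffMatrix:
    matrix: np.ndarray  # (N, N)
    cutoff: float
    gamma: float

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def dof_per_node(self) -> int:
        return 1


@dataclass(frozen=True)
class HessianMatrix:
    matrix: np.ndarray  # (3N, 3N)
    cutoff: float
    gamma: float

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0] // 3

    @property
    def dof_per_node(self) -> int:
        return 3


@dataclass
class ModeSet:
    """Full spectrum of a network matrix with zero-mode bookkeeping.

    Mode numbering in the public interface is 1-based over the *non-zero*
    modes: "mode 1" is the slowest internal mode, matching common usage.
    """

    all_eigenvalues: np.ndarray        # ascending
    all_eigenvectors: np.ndarray       # columns match eigenvalues
    n_zero: int
    dof_per_node: int
    scale: float = 1.0                 # c = 3 k_B T / gamma
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.all_eigenvectors.shape[0] // self.dof_per_node

    @property
    def n_modes(self) -> int:
        """Number of non-zero (internal) modes."""
        return self.all_eigenvalues.size - self.n_zero

    @property
    def eigenvalues(self) -> np.ndarray:
        """Non-zero eigenvalues, ascending (mode 1 first)."""
        return self.all_eigenvalues[self.n_zero:]

    @property
    def eigenvectors(self) -> np.ndarray:
        """Columns are the non-zero modes (column 0 = mode 1)."""
        return self.all_eigenvectors[:, self.n_zero:]

    def mode(self, k: int) -> np.ndarray:
        """Eigenvector of non-zero mode ``k`` (1-based)."""
        self._check_mode(k)
        return self.all_eigenvectors[:, self.n_zero + k - 1]

    def eigenvalue(self, k: int) -> float:
        self._check_mode(k)
        return float(self.all_eigenvalues[self.n_zero + k - 1])

    def _check_mode(self, k: int) -> None:
        if not 1 <= k <= self.n_modes:
            raise IndexError(
                f"mode {k} out of range 1..{self.n_modes} "
                "(zero modes are excluded from numbering)"
            )

    def per_node_square(self, k: int) -> np.ndarray:
        """Per-node squared mode shape (summed over x,y,z for ANM)."""
        u = self.mode(k)
        if self.dof_per_node == 1:
            return u**2
        return (u.reshape(-1, 3) ** 2).sum(axis=1)


def build_kirchhoff(model: CoarseModel, cutoff: float = DEFAULT_GNM_CUTOFF,
                    gamma: float = 1.0) -> KirchhoffMatrix:
    """GNM Kirchhoff matrix: Gamma_ij = -gamma for i != j in contact
    (node-pair distance <= cutoff), diagonal fixed by zero row sums."""
    if model.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    contacts = _contact_matrix(model.coords, cutoff)
    gamma_mat = -gamma * contacts.astype(float)
    np.fill_diagonal(gamma_mat, 0.0)
    np.fill_diagonal(gamma_mat, -gamma_mat.sum(axis=1))
    return KirchhoffMatrix(gamma_mat, cutoff, gamma)


def build_hessian(model: CoarseModel, cutoff: float = DEFAULT_ANM_CUTOFF,
                  gamma: float = 1.0) -> HessianMatrix:
    """ANM Hessian: the off-diagonal 3x3 block of a contacting pair (i,j)
    is -gamma * outer(e_ij, e_ij) with e_ij the unit separation vector;
    diagonal super-blocks make every block row sum to zero."""
    coords = model.coords
    n = model.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    contacts = _contact_matrix(coords, cutoff)
    hess = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in np.nonzero(contacts[i])[0]:
            if j <= i:
                continue
            d = coords[j] - coords[i]
            dist2 = float(d @ d)
            if dist2 == 0.0:
                raise ValueError(
                    f"coincident nodes {model.labels[i]} and {model.labels[j]}"
                )
            block = -gamma * np.outer(d, d) / dist2
            hess[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
            hess[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
    for i in range(n):
        row = hess[3 * i:3 * i + 3].reshape(3, n, 3)
        hess[3 * i:3 * i + 3, 3 * i:3 * i + 3] = -row.sum(axis=1)
    return HessianMatrix(hess, cutoff, gamma)


def _components_from_kirchhoff(kirchhoff: KirchhoffMatrix) -> list[list[int]]:
    adjacency = (kirchhoff.matrix != 0) & ~np.eye(kirchhoff.n_nodes, dtype=bool)
    n_comp, labels = connected_components(adjacency, directed=False)
    return [list(np.nonzero(labels == c)[0]) for c in range(n_comp)]


def decompose(matrix: KirchhoffMatrix | HessianMatrix,
              scale: float = 1.0) -> ModeSet:
    """Full eigendecomposition with zero modes counted at relative
    tolerance ``lambda <= 1e-10 * lambda_max``.

    A connected GNM must give exactly one zero mode; more raises
    :class:`DisconnectedNetworkError` listing the components.  An ANM whose
    null space differs from the 6 rigid-body modes warns (degenerate or
    disconnected geometry) but still returns the spectrum.
    """
    evals, evecs = scipy.linalg.eigh(matrix.matrix)
    lam_max = float(evals[-1]) if evals.size else 0.0
    n_zero = int(np.sum(evals <= ZERO_MODE_RTOL * max(lam_max, 1e-300)))
    dof = matrix.dof_per_node
    if dof == 1 and n_zero != 1:
        raise DisconnectedNetworkError(_components_from_kirchhoff(matrix))
    if dof == 3 and n_zero != 6:
        warnings.warn(
            f"ANM null space has dimension {n_zero}, not 6 "
            "(degenerate or disconnected geometry)",
            DegenerateNetworkWarning,
            stacklevel=2,
        )
    return ModeSet(evals, evecs, n_zero, dof, scale=scale)


def msf_profile(modes: ModeSet,
                mode_subset: list[int] | None = None) -> np.ndarray:
    """Per-node mean-square fluctuation, c * sum_k (u_k)_i^2 / lambda_k.

    ``mode_subset`` (1-based non-zero mode indices) restricts the sum,
    giving the per-mode mobility profiles; default is all non-zero modes,
    which equals the diagonal of the matrix pseudoinverse (times c, and
    traced over x,y,z for the ANM).
    """
    if mode_subset is None:
        ks = range(1, modes.n_modes + 1)
    else:
        for k in mode_subset:
            modes._check_mode(k)
        ks = mode_subset
    n = modes.n_nodes
    out = np.zeros(n)
    for k in ks:
        out += modes.per_node_square(k) / modes.eigenvalue(k)
    return modes.scale * out


def cross_correlations(modes: ModeSet) -> np.ndarray:
    """N x N fluctuation covariance <dR_i . dR_j>:
    C = c * sum_k u_k u_k^T / lambda_k, traced over x,y,z for the ANM.
    The diagonal equals :func:`msf_profile`."""
    lam = modes.eigenvalues
    u = modes.eigenvectors
    cov = (u / lam) @ u.T
    if modes.dof_per_node == 3:
        n = modes.n_nodes
        cov = cov.reshape(n, 3, n, 3)
        cov = np.einsum("iaja->ij", cov)
    return modes.scale * cov


def predict_bfactors(msf: np.ndarray,
                     experimental: np.ndarray) -> tuple[np.ndarray, float]:
    """B_i = (8 pi^2 / 3) <(dR_i)^2>, uniformly rescaled so the mean matches
    the experimental mean; returns (predicted B, Pearson correlation)."""
    msf = np.asarray(msf, dtype=float)
    experimental = np.asarray(experimental, dtype=float)
    if msf.shape != experimental.shape:
        raise ValueError("length mismatch between MSF and experimental B")
    valid = np.isfinite(experimental)
    if valid.sum() < 3:
        raise ValueError("need at least 3 nodes with experimental B-factors")
    raw = B_FACTOR_PREFACTOR * msf
    b_pred = raw * experimental[valid].mean() / raw[valid].mean()
    if np.ptp(experimental[valid]) == 0:
        raise ValueError(
            "correlation undefined: experimental B-factors all equal"
        )
    corr = float(np.corrcoef(b_pred[valid], experimental[valid])[0, 1])
    return b_pred, corr


def find_hinges(mode_vector: np.ndarray,
                chains: list[str] | None = None,
                window: int = 3,
                mobility_quantile: float = 0.10) -> list[int]:
    """Hinge nodes of a signed GNM mode shape.

    A hinge is reported (a) wherever the shape changes sign between
    sequence neighbours within one chain — the reported node is the one
    with the smaller |value|, ties going to the lower index — and (b) at
    local minima of the squared shape (within ``window`` nodes) whose
    mobility is below the given quantile.  A constant-sign mode yields [].
    """
    shape = np.asarray(mode_vector, dtype=float)
    n = shape.size
    if chains is None:
        chains = ["A"] * n
    hinges: set[int] = set()
    for i in range(n - 1):
        if chains[i] != chains[i + 1]:
            continue
        if shape[i] * shape[i + 1] < 0:
            a, b = abs(shape[i]), abs(shape[i + 1])
            hinges.add(i if a <= b else i + 1)
    if not hinges:
        return []          # constant-sign mode: no opposing motions
    sq = shape**2
    thresh = np.quantile(sq, mobility_quantile)
    for i in range(n):
        lo = max(0, i - window)
        hi = min(n, i + window + 1)
        same_chain = [j for j in range(lo, hi) if chains[j] == chains[i]]
        if sq[i] < thresh and sq[i] == min(sq[j] for j in same_chain):
            hinges.add(i)
    return sorted(hinges)


def map_gnm_to_anm(gnm: ModeSet, anm: ModeSet, n_modes: int) -> np.ndarray:
    """(n x n) Pearson correlations between GNM per-node squared shapes and
    ANM per-node squared displacements, mapping isotropic modes onto their
    directional counterparts."""
    if gnm.n_nodes != anm.n_nodes:
        raise ValueError("mode sets refer to different node counts")
    n_modes = min(n_modes, gnm.n_modes, anm.n_modes)
    out = np.empty((n_modes, n_modes))
    gnm_sq = [gnm.per_node_square(k + 1) for k in range(n_modes)]
    anm_sq = [anm.per_node_square(k + 1) for k in range(n_modes)]
    for k in range(n_modes):
        for l in range(n_modes):
            out[k, l] = np.corrcoef(gnm_sq[k], anm_sq[l])[0, 1]
    return out
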