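"""Synthetic coarse-grained structures with known dynamics.

These generators stand in for crystallographic input so that every stage
of the analysis — contact networks, normal modes, deformations,
communication, subsystem coupling — can be exercised against constructions
whose answers are known: a three-bead chain whose spectra are solvable by
hand, a dumbbell with a designed hinge at its bridge, and a C2-symmetric
two-chain dimer for symmetric mode profiles and mode-count checks.  Nodes
are decorated with a deterministic tetrahedron of pseudo heavy atoms
(4 per node within 1.5 Angstrom of the C-alpha) so that the atom-contact
affinity code paths run without real side chains.  All randomness is
Gaussian, isotropic and seeded; generators are bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .communication import MarkovModel
from .elastic_models import DEFAULT_ANM_CUTOFF, build_hessian, decompose
from .structure_io import CoarseModel, CoarseNode, write_coarse_pdb

__all__ = [
    "ToySpec",
    "make_toy",
    "deform_toy",
    "random_walk_oracle",
]

TOPOLOGIES = ("chain", "ring", "helix", "dumbbell", "two_chain_dimer")

# unit tetrahedron directions for pseudo-atom decoration
_TETRA = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / np.sqrt(3.0)


@dataclass(frozen=True)
class ToySpec:
    topology: str
    n: int                                # nodes (per chain for the dimer)
    spacing: float = 3.8                  # Angstrom between bonded nodes
    linker_length: int = 5                # dumbbell bridge nodes
    lobe_radius: float = 5.0              # dumbbell lobe size, Angstrom
    seed: int = 0
    decoration_atoms: int = 4             # pseudo heavy atoms per node
    decoration_radius: float = 1.2        # < 1.5 Angstrom from the C-alpha

    def __post_init__(self):
        if self.topology not in TOPOLOGIES:
            raise ValueError(
                f"unknown topology {self.topology!r}; choose from {TOPOLOGIES}"
            )
        if self.n < 2:
            raise ValueError("need at least 2 nodes")


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """Deterministic quasi-uniform points on a sphere."""
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    z = 1 - 2 * (i + 0.5) / n
    theta = 2 * np.pi * i / golden
    rho = np.sqrt(np.maximum(0.0, 1 - z**2))
    return radius * np.column_stack(
        [rho * np.cos(theta), rho * np.sin(theta), z]
    )


def _lobe(center: np.ndarray, n: int, radius: float) -> np.ndarray:
    """Compact blob: centre node, inner and outer quasi-uniform shells."""
    pts = [center]
    n_outer = max(1, (2 * (n - 1)) // 3)
    n_inner = n - 1 - n_outer
    if n_outer:
        pts.append(center + _fibonacci_sphere(n_outer, radius))
    if n_inner:
        pts.append(center + _fibonacci_sphere(n_inner, radius / 2))
    return np.vstack([np.atleast_2d(p) for p in pts])


def _helix(n: int, rise: float = 1.5, radius: float = 2.3,
           twist_deg: float = 100.0) -> np.ndarray:
    theta = np.deg2rad(twist_deg) * np.arange(n)
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta),
         rise * np.arange(n)]
    )


def _toy_geometry(spec: ToySpec) -> tuple[np.ndarray, list[str], dict]:
    meta: dict = {}
    if spec.topology == "chain":
        coords = np.column_stack(
            [spec.spacing * np.arange(spec.n), np.zeros(spec.n),
             np.zeros(spec.n)]
        )
        chains = ["A"] * spec.n
    elif spec.topology == "ring":
        radius = spec.spacing / (2 * np.sin(np.pi / spec.n))
        theta = 2 * np.pi * np.arange(spec.n) / spec.n
        coords = np.column_stack(
            [radius * np.cos(theta), radius * np.sin(theta),
             np.zeros(spec.n)]
        )
        chains = ["A"] * spec.n
    elif spec.topology == "helix":
        coords = _helix(spec.n)
        chains = ["A"] * spec.n
    elif spec.topology == "two_chain_dimer":
        offset = np.array([5.0, 0.0, 0.0])
        chain_a = _helix(spec.n) + offset
        # C2 rotation about the z axis
        chain_b = chain_a * np.array([-1.0, -1.0, 1.0])
        coords = np.vstack([chain_a, chain_b])
        chains = ["A"] * spec.n + ["B"] * spec.n
        meta["c2_axis"] = "z"
    elif spec.topology == "dumbbell":
        n_link = spec.linker_length
        if spec.n < n_link + 4:
            raise ValueError("dumbbell needs at least linker_length+4 nodes")
        n_lobe_a = (spec.n - n_link + 1) // 2
        n_lobe_b = spec.n - n_link - n_lobe_a
        half_span = spec.lobe_radius + (n_link + 1) * spec.spacing / 2
        center_a = np.array([-half_span, 0.0, 0.0])
        center_b = np.array([half_span, 0.0, 0.0])
        # mildly anisotropic lobes split the otherwise degenerate
        # bend-in-y / bend-in-z slow-mode pairs
        aniso = np.array([1.0, 1.25, 0.8])
        lobe_a = center_a + aniso * _lobe(np.zeros(3), n_lobe_a,
                                          spec.lobe_radius)
        lobe_b = center_b + aniso * _lobe(np.zeros(3), n_lobe_b,
                                          spec.lobe_radius)
        x0 = center_a[0] + spec.lobe_radius
        t = np.arange(1, n_link + 1)
        # gentle off-axis arc: an exactly straight linker would leave
        # zero-energy torsion mechanisms (lobe rotation about the axis
        # changes no pair distance), degenerating the ANM null space
        linker = np.column_stack(
            [x0 + spec.spacing * t,
             3.0 * np.sin(np.pi * t / (n_link + 1)),
             1.8 * np.sin(2 * np.pi * t / (n_link + 1))]
        )
        lobe_a = lobe_a[np.argsort(lobe_a[:, 0], kind="stable")]
        lobe_b = lobe_b[np.argsort(lobe_b[:, 0], kind="stable")]
        coords = np.vstack([lobe_a, linker, lobe_b])
        chains = ["A"] * spec.n
        meta["lobe_a"] = list(range(n_lobe_a))
        meta["linker"] = list(range(n_lobe_a, n_lobe_a + n_link))
        meta["lobe_b"] = list(range(n_lobe_a + n_link, spec.n))
        meta["bridge_index"] = n_lobe_a + n_link // 2
    else:  # pragma: no cover - guarded by ToySpec
        raise AssertionError
    return coords, chains, meta


def _decorate(coords: np.ndarray, chains: list[str],
              spec: ToySpec) -> list[CoarseNode]:
    centroid = coords.mean(axis=0)
    dist = np.linalg.norm(coords - centroid, axis=1)
    bfac = 15.0 + 0.5 * dist      # fabricated, mobility-like trend
    offsets = spec.decoration_radius * _TETRA[:spec.decoration_atoms]
    nodes = []
    counter: dict[str, int] = {}
    for i, (xyz, chain) in enumerate(zip(coords, chains)):
        counter[chain] = counter.get(chain, 0) + 1
        seq = counter[chain]
        heavy = tuple(tuple(c) for c in np.vstack([xyz, xyz + offsets]))
        nodes.append(
            CoarseNode(
                label=f"{chain}:GLY{seq}", chain=chain, seqid=seq,
                kind="residue", coord=tuple(xyz),
                b_factor=float(bfac[i]), heavy_coords=heavy,
            )
        )
    return nodes


def make_toy(spec: ToySpec, pdb: bool = False):
    """Build the toy model; with ``pdb=True`` also return PDB text.

    Dumbbell models carry ``meta['bridge_index']`` (the designed hinge) and
    the lobe/linker index sets; the dimer records its C2 axis.
    """
    coords, chains, meta = _toy_geometry(spec)
    model = CoarseModel(_decorate(coords, chains, spec), meta=meta)
    model.meta["spec"] = spec
    if pdb:
        return model, write_coarse_pdb(model)
    return model


def deform_toy(model: CoarseModel, mode: int = 1, amplitude: float = 1.0,
               noise: float = 0.0, seed: int = 0,
               cutoff: float = DEFAULT_ANM_CUTOFF) -> CoarseModel:
    """Synthetic "closed" form: displace along ANM mode ``mode`` of the
    model plus optional seeded isotropic Gaussian noise of width ``noise``
    (Angstrom) on every coordinate.  ``amplitude`` is the C-alpha RMSD of
    the displacement in Angstrom (direct scaling of the unit mode vector,
    independent of the eigenvalue, so even near-mechanism modes stay in
    the linear regime where mode recovery is well-posed)."""
    modes = decompose(build_hessian(model, cutoff=cutoff))
    disp = amplitude * np.sqrt(model.n_nodes) \
        * modes.mode(mode).reshape(-1, 3)
    coords = model.coords + disp
    if noise > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, noise, size=coords.shape)
    out = model.with_coords(coords)
    out.meta["deformed_along"] = mode
    return out


def random_walk_oracle(markov: MarkovModel, source: int, target: int,
                       n_walks: int = 20_000, seed: int = 0,
                       max_total_steps: int = 10_000_000
                       ) -> tuple[float, float]:
    """Empirical mean hitting time source -> target from seeded walks.

    Returns ``(mean, standard error)``.  Independent verification route for
    the closed-form hitting times; never used by the analysis itself.
    """
    if source == target:
        return 0.0, 0.0
    rng = np.random.default_rng(seed)
    cum = np.cumsum(markov.transition, axis=0)   # columns: P(j -> .)
    steps = np.zeros(n_walks, dtype=np.int64)
    current = np.full(n_walks, source, dtype=np.int64)
    active = np.ones(n_walks, dtype=bool)
    total = 0
    while active.any():
        idx = np.nonzero(active)[0]
        u = rng.random(idx.size)
        nxt = (cum[:, current[idx]] > u[None, :]).argmax(axis=0)
        current[idx] = nxt
        steps[idx] += 1
        active[idx] = nxt != target
        total += idx.size
        if total > max_total_steps:
            raise RuntimeError(
                f"target {target} not reached within {max_total_steps} steps"
            )
    mean = float(steps.mean())
    stderr = float(steps.std(ddof=1) / np.sqrt(n_walks)) if n_walks > 1 else 0.0
    return mean, stderr
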