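"""Structure input/output and the coarse-grained node model.

Every downstream stage (elastic networks, communication, subsystem
analysis) consumes an ordered :class:`CoarseModel`: one node per standard
residue, represented by its C-alpha, optionally extended with one node per
non-water hetero residue (bound ligands) represented by its heavy-atom
centroid.  Heavy atoms are retained per node because the residue-residue
affinity matrix counts atom-atom contacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "CoarseNode",
    "CoarseModel",
    "AlignmentMap",
    "StructureError",
    "read_structure",
    "read_structure_file",
    "build_coarse_model",
    "read_alignment_map",
    "write_alignment_map",
    "write_coarse_pdb",
]

#: Residue names treated as water and always removed.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


class StructureError(ValueError):
    """Raised for malformed or unusable structural input."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    pos: tuple[float, float, float]
    b_factor: float
    occupancy: float


@dataclass(frozen=True)
class Residue:
    chain: str
    seqid: int
    icode: str
    name: str
    hetero: bool
    atoms: tuple[Atom, ...]

    @property
    def label(self) -> str:
        icode = self.icode.strip()
        return f"{self.chain}:{self.name}{self.seqid}{icode}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element.upper() not in ("H", "D")]


@dataclass(frozen=True)
class Structure:
    chains: tuple[str, ...]
    residues: tuple[Residue, ...]

    def __post_init__(self):
        seen = set()
        for r in self.residues:
            key = (r.chain, r.seqid, r.icode)
            if key in seen:
                raise StructureError(f"duplicate residue identifier {key}")
            seen.add(key)
            for a in r.atoms:
                if not all(math.isfinite(c) for c in a.pos):
                    raise StructureError(f"non-finite coordinate in {r.label}")


@dataclass(frozen=True)
class CoarseNode:
    label: str
    chain: str
    seqid: int
    kind: str  # "residue" | "ligand"
    coord: tuple[float, float, float]
    b_factor: float | None
    heavy_coords: tuple[tuple[float, float, float], ...]


@dataclass
class CoarseModel:
    """Ordered network nodes; order is chain order then residue number."""

    nodes: list[CoarseNode]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.nodes) < 2:
            raise StructureError("coarse model needs at least 2 nodes")
        for n in self.nodes:
            if len(n.heavy_coords) == 0:
                raise StructureError(f"node {n.label} has no heavy atoms")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def labels(self) -> list[str]:
        return [n.label for n in self.nodes]

    @property
    def chains(self) -> list[str]:
        return [n.chain for n in self.nodes]

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) representative coordinates in Angstrom."""
        return np.array([n.coord for n in self.nodes], dtype=float)

    @property
    def b_factors(self) -> np.ndarray:
        """(N,) experimental B-factors; NaN where absent."""
        return np.array(
            [np.nan if n.b_factor is None else n.b_factor for n in self.nodes],
            dtype=float,
        )

    def with_coords(self, coords: np.ndarray) -> "CoarseModel":
        """Copy of the model with node (and rigidly shifted heavy-atom)
        coordinates replaced by ``coords`` (N,3 or 3N)."""
        coords = np.asarray(coords, dtype=float).reshape(self.n_nodes, 3)
        nodes = []
        for node, new in zip(self.nodes, coords):
            shift = new - np.asarray(node.coord)
            heavy = tuple(
                tuple(np.asarray(h) + shift) for h in node.heavy_coords
            )
            nodes.append(
                CoarseNode(
                    node.label, node.chain, node.seqid, node.kind,
                    tuple(new), node.b_factor, heavy,
                )
            )
        return CoarseModel(nodes, meta=dict(self.meta))


@dataclass(frozen=True)
class AlignmentMap:
    """One-to-one pairing of node indices between two models (0-based)."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        a_idx = [p[0] for p in self.pairs]
        b_idx = [p[1] for p in self.pairs]
        if len(set(a_idx)) != len(a_idx) or len(set(b_idx)) != len(b_idx):
            raise StructureError("mapping not one-to-one")
        if any(i < 0 for i in a_idx + b_idx):
            raise StructureError("negative node index in mapping")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def a_indices(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=int)

    @property
    def b_indices(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=int)

    def validate(self, n_a: int, n_b: int) -> None:
        if len(self.pairs) and (self.a_indices.max() >= n_a or self.b_indices.max() >= n_b):
            raise StructureError("mapping index out of range for model sizes")

    @classmethod
    def identity(cls, n: int) -> "AlignmentMap":
        return cls(tuple((i, i) for i in range(n)))


# ---------------------------------------------------------------------------
# Reading


def _convert_gemmi_model(model: "gemmi.Model") -> Structure:
    chains: list[str] = []
    residues: list[Residue] = []
    for chain in model:
        if chain.name not in chains:
            chains.append(chain.name)
        for res in chain:
            if res.name.strip().upper() in WATER_NAMES:
                continue
            # resolve altlocs: per atom name keep highest occupancy,
            # ties broken by file order
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for atom in res:
                prev = best.get(atom.name)
                if prev is None:
                    best[atom.name] = atom
                    order.append(atom.name)
                elif atom.occ > prev.occ:
                    best[atom.name] = atom
            atoms = tuple(
                Atom(
                    name=a.name,
                    element=a.element.name,
                    pos=(a.pos.x, a.pos.y, a.pos.z),
                    b_factor=a.b_iso,
                    occupancy=a.occ,
                )
                for a in (best[n] for n in order)
            )
            residues.append(
                Residue(
                    chain=chain.name,
                    seqid=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    name=res.name.strip(),
                    hetero=res.het_flag == "H",
                    atoms=atoms,
                )
            )
    if not residues:
        raise StructureError("no residues after filtering")
    return Structure(chains=tuple(chains), residues=tuple(residues))


def read_structure(text: str, model_index: int = 0) -> Structure:
    """Parse PDB-format ``text`` and return the requested model.

    Waters are excluded and alternate locations are resolved to the
    highest-occupancy conformer (ties -> first occurrence in the file).
    """
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # gemmi names the bad line
        raise StructureError(f"PDB parse error: {exc}") from exc
    if len(st) == 0:
        raise StructureError("no residues after filtering")
    if model_index < 0 or model_index >= len(st):
        raise StructureError(
            f"model {model_index} not present ({len(st)} model(s) in file)"
        )
    return _convert_gemmi_model(st[model_index])


def read_structure_file(path, model_index: int = 0) -> Structure:
    with open(path) as fh:
        return read_structure(fh.read(), model_index)


def build_coarse_model(
    structure: Structure,
    include_ligands: bool = False,
    chains: list[str] | None = None,
) -> CoarseModel:
    """One node per standard residue (C-alpha representative); optionally
    one node per non-water hetero residue (heavy-atom centroid)."""
    selected = [
        r for r in structure.residues if chains is None or r.chain in chains
    ]
    if not selected:
        raise StructureError("no residues in selected chains")

    chain_order = {c: i for i, c in
                   enumerate(dict.fromkeys(res.chain for res in selected))}
    selected = sorted(
        selected, key=lambda r: (chain_order[r.chain], r.seqid, r.icode)
    )

    missing_ca = [
        r.label for r in selected if not r.hetero and r.atom("CA") is None
    ]
    if missing_ca:
        raise StructureError(
            "residue(s) lacking a C-alpha atom: " + ", ".join(missing_ca)
        )

    nodes: list[CoarseNode] = []
    ligand_nodes: list[CoarseNode] = []
    for r in selected:
        heavy = r.heavy_atoms()
        if not heavy:
            raise StructureError(f"residue {r.label} has no heavy atoms")
        heavy_coords = tuple(a.pos for a in heavy)
        if r.hetero:
            if not include_ligands:
                continue
            centroid = tuple(np.mean(np.array(heavy_coords), axis=0))
            ligand_nodes.append(
                CoarseNode(r.label, r.chain, r.seqid, "ligand",
                           centroid, None, heavy_coords)
            )
        else:
            ca = r.atom("CA")
            nodes.append(
                CoarseNode(r.label, r.chain, r.seqid, "residue",
                           ca.pos, ca.b_factor, heavy_coords)
            )
    return CoarseModel(nodes + ligand_nodes)


def read_alignment_map(text: str, n_a: int | None = None,
                       n_b: int | None = None) -> AlignmentMap:
    """Parse a two-column whitespace-separated pair list ('#' comments)."""
    pairs: list[tuple[int, int]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 2:
            raise StructureError(
                f"line {lineno}: expected two columns, got {len(fields)}"
            )
        try:
            pairs.append((int(fields[0]), int(fields[1])))
        except ValueError as exc:
            raise StructureError(f"line {lineno}: non-integer index") from exc
    amap = AlignmentMap(tuple(pairs))
    if n_a is not None and n_b is not None:
        amap.validate(n_a, n_b)
    return amap


def write_alignment_map(amap: AlignmentMap, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for a, b in amap.pairs:
            fh.write(f"{a} {b}\n")


# ---------------------------------------------------------------------------
# Writing


def write_coarse_pdb(model: CoarseModel, coordinates: np.ndarray | None = None,
                     path=None) -> str:
    """Write a single-model PDB with one CA record per residue node (ligand
    nodes become single-atom HETATM records).  Returns the PDB text; also
    writes it to ``path`` when given.  Absent B-factors are written as 0.00.
    """
    if coordinates is None:
        coords = model.coords
    else:
        coordinates = np.asarray(coordinates, dtype=float)
        if coordinates.size != 3 * model.n_nodes:
            raise StructureError(
                f"coordinate length {coordinates.size} != 3N = {3 * model.n_nodes}"
            )
        coords = coordinates.reshape(model.n_nodes, 3)

    st = gemmi.Structure()
    st.name = "aakdyn"
    gm = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    for node, xyz in zip(model.nodes, coords):
        if node.chain not in chain_map:
            chain_map[node.chain] = gemmi.Chain(node.chain)
        chain = chain_map[node.chain]
        resname = node.label.split(":", 1)[1]
        resname = "".join(c for c in resname if c.isalpha())[:3] or "GLY"
        res = gemmi.Residue()
        res.name = resname if node.kind == "residue" else "LIG"
        res.seqid = gemmi.SeqId(node.seqid, " ")
        res.het_flag = "A" if node.kind == "residue" else "H"
        atom = gemmi.Atom()
        atom.name = "CA" if node.kind == "residue" else "C1"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*xyz)
        atom.occ = 1.0
        atom.b_iso = 0.0 if node.b_factor is None else float(node.b_factor)
        res.add_atom(atom)
        chain.add_residue(res)
    for chain in chain_map.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    text = st.make_pdb_string()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
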