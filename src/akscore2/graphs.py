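"""Graph featurization of pockets, ligands and complexes.

Nodes are heavy atoms carrying a 73-dimensional feature vector; edges
are covalent bonds (12-dimensional features) and, for complex graphs,
protein-ligand non-covalent contacts under 8 A (a further 12
dimensions, giving 24 in total).  All features depend only on element,
topology, perceived pharmacophore roles and interatomic distances, so
graphs are invariant under rigid motions of the complex.

Feature groups can be ablated: an ablated group is zero-filled, never
removed, so tensor shapes are stable across ablation experiments.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from rdkit import Chem
from rdkit.Chem import AllChem

from . import structio
from .structio import ComplexRecord, LigandPose, ProteinStructure

NODE_DIM = 73
EDGE_DIM_COVALENT = 12
EDGE_DIM_COMPLEX = 24
NONCOVALENT_CUTOFF = 8.0  # Angstrom, strict upper bound on contact edges

PHARMACOPHORE_CATEGORIES = ("aromatic", "ring", "hydrophobic", "donor",
                            "acceptor", "acidic", "basic")

_ROTATABLE = Chem.MolFromSmarts("[!$(*#*)&!D1]-&!@[!$(*#*)&!D1]")

_ELEMENTS = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B",
             "Se", "Fe", "Zn", "Mg", "Mn")  # +1 "other" slot = 16

_HYBRIDIZATIONS = (Chem.HybridizationType.S, Chem.HybridizationType.SP,
                   Chem.HybridizationType.SP2, Chem.HybridizationType.SP3,
                   Chem.HybridizationType.SP3D)  # +1 other = 6


class FeaturizationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# schema
# ---------------------------------------------------------------------------

NODE_GROUPS: List[Tuple[str, int]] = [
    ("element", 16),
    ("degree", 6),
    ("formal_charge", 6),
    ("hybridization", 6),
    ("aromatic", 1),
    ("in_ring", 1),
    ("ring_size", 6),
    ("pharmacophore", 7),
    ("valence_electrons", 8),
    ("h_count", 5),
    ("partial_charge", 1),
    ("is_ligand", 1),
    ("vdw_radius", 1),
    ("atomic_mass", 1),
    ("chirality", 3),
    ("ring_count", 4),
]

EDGE_GROUPS: List[Tuple[str, int]] = [
    # covalent block (12)
    ("bond_type", 4),
    ("conjugated", 1),
    ("bond_ring", 1),
    ("stereo", 3),
    ("bond_length", 1),
    ("rotatable", 1),
    ("covalent_flag", 1),
    # non-covalent block (12); zero on covalent-only graphs
    ("distance_bins", 8),
    ("inverse_distance", 1),
    ("protein_ligand_flag", 1),
    ("donor_acceptor_pair", 1),
    ("hydrophobic_pair", 1),
]

# convenience aliases for ablation experiments.  "pharmacophore" covers
# every channel computed from the pharmacophore perception: the node
# multi-hot plus the pair flags derived from it on contact edges.
GROUP_ALIASES = {
    "pharmacophore": ("pharmacophore", "donor_acceptor_pair",
                      "hydrophobic_pair"),
    "distance": ("distance_bins", "inverse_distance"),
    "atom_type": ("element",),
}


def _offsets(groups):
    out, pos = {}, 0
    for name, width in groups:
        out[name] = slice(pos, pos + width)
        pos += width
    return out, pos


_NODE_SLICES, _NODE_TOTAL = _offsets(NODE_GROUPS)
_EDGE_SLICES, _EDGE_TOTAL = _offsets(EDGE_GROUPS)
assert _NODE_TOTAL == NODE_DIM
assert _EDGE_TOTAL == EDGE_DIM_COMPLEX


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature groups with widths plus an ablation mask.

    Ablated groups stay in place but are zero-filled, keeping the
    73 / 24 / 12 widths (and hence trained tensor shapes) intact.
    """
    ablated: frozenset = frozenset()
    version: int = 1

    def __post_init__(self):
        valid = ({n for n, _ in NODE_GROUPS} | {n for n, _ in EDGE_GROUPS}
                 | set(GROUP_ALIASES))
        unknown = set(self.ablated) - valid
        if unknown:
            raise FeaturizationError(
                f"unknown feature group(s) {sorted(unknown)}; "
                f"valid groups: {sorted(valid)}")

    @property
    def ablated_resolved(self) -> frozenset:
        out = set()
        for name in self.ablated:
            out.update(GROUP_ALIASES.get(name, (name,)))
        return frozenset(out)

    def node_slice(self, group: str) -> slice:
        return _NODE_SLICES[group]

    def edge_slice(self, group: str) -> slice:
        return _EDGE_SLICES[group]

    def mask_nodes(self, x: np.ndarray) -> np.ndarray:
        for g in self.ablated_resolved:
            if g in _NODE_SLICES:
                x[:, _NODE_SLICES[g]] = 0.0
        return x

    def mask_edges(self, e: np.ndarray) -> np.ndarray:
        width = e.shape[1] if e.size else EDGE_DIM_COMPLEX
        for g in self.ablated_resolved:
            if g in _EDGE_SLICES and _EDGE_SLICES[g].stop <= width:
                e[:, _EDGE_SLICES[g]] = 0.0
        return e


# ---------------------------------------------------------------------------
# pharmacophore perception
# ---------------------------------------------------------------------------

def _load_pharmacophore_smarts() -> Dict[str, list]:
    text = (resources.files("akscore2") / "data" / "pharmacophores.yaml").read_text()
    spec = yaml.safe_load(text)
    patterns = {}
    for cat in PHARMACOPHORE_CATEGORIES:
        patterns[cat] = [Chem.MolFromSmarts(s) for s in spec["categories"][cat]]
        if any(p is None for p in patterns[cat]):
            raise FeaturizationError(f"bad SMARTS in category {cat}")
    return patterns


_PHARM_PATTERNS: Optional[Dict[str, list]] = None


def perceive_pharmacophores(mol: Chem.Mol) -> np.ndarray:
    """(N, 7) multi-hot of pharmacophore roles per heavy atom."""
    global _PHARM_PATTERNS
    if _PHARM_PATTERNS is None:
        _PHARM_PATTERNS = _load_pharmacophore_smarts()
    out = np.zeros((mol.GetNumAtoms(), len(PHARMACOPHORE_CATEGORIES)))
    for ci, cat in enumerate(PHARMACOPHORE_CATEGORIES):
        for patt in _PHARM_PATTERNS[cat]:
            for match in mol.GetSubstructMatches(patt, uniquify=True):
                out[match[0], ci] = 1.0
    return out


# ---------------------------------------------------------------------------
# node features
# ---------------------------------------------------------------------------

def _one_hot(value, choices, width):
    v = np.zeros(width)
    try:
        v[choices.index(value)] = 1.0
    except ValueError:
        v[width - 1] = 1.0  # "other" slot
    return v


def featurize_node(atom: Chem.Atom, pharm_row: np.ndarray,
                   is_ligand: bool, partial_charge: float = 0.0) -> np.ndarray:
    """73-dimensional feature vector for one heavy atom."""
    pt = Chem.GetPeriodicTable()
    mol = atom.GetOwningMol()
    ri = mol.GetRingInfo()
    idx = atom.GetIdx()
    parts = []
    parts.append(_one_hot(atom.GetSymbol(), list(_ELEMENTS), 16))
    parts.append(_one_hot(min(atom.GetDegree(), 5), [0, 1, 2, 3, 4, 5], 6))
    parts.append(_one_hot(atom.GetFormalCharge(), [-2, -1, 0, 1, 2], 6))
    parts.append(_one_hot(atom.GetHybridization(), list(_HYBRIDIZATIONS), 6))
    parts.append(np.array([1.0 if atom.GetIsAromatic() else 0.0]))
    parts.append(np.array([1.0 if atom.IsInRing() else 0.0]))
    parts.append(np.array([1.0 if atom.IsInRingSize(s) else 0.0
                           for s in range(3, 9)]))
    parts.append(np.asarray(pharm_row, dtype=float))
    n_val = pt.GetNOuterElecs(atom.GetAtomicNum())
    parts.append(_one_hot(min(max(n_val, 1), 8), list(range(1, 9)), 8))
    parts.append(_one_hot(min(atom.GetTotalNumHs(), 4), [0, 1, 2, 3, 4], 5))
    pc = partial_charge
    if not np.isfinite(pc):
        pc = 0.0
    parts.append(np.array([np.clip(pc, -2.0, 2.0) / 2.0]))
    parts.append(np.array([1.0 if is_ligand else 0.0]))
    parts.append(np.array([pt.GetRvdw(atom.GetAtomicNum()) / 2.5]))
    parts.append(np.array([atom.GetMass() / 100.0]))
    tag = atom.GetChiralTag()
    chir = np.zeros(3)
    if tag == Chem.ChiralType.CHI_TETRAHEDRAL_CW:
        chir[0] = 1.0
    elif tag == Chem.ChiralType.CHI_TETRAHEDRAL_CCW:
        chir[1] = 1.0
    else:
        chir[2] = 1.0
    parts.append(chir)
    parts.append(_one_hot(min(ri.NumAtomRings(idx), 3), [0, 1, 2, 3], 4))
    vec = np.concatenate(parts)
    if vec.shape[0] != NODE_DIM:
        raise FeaturizationError(
            f"node feature width {vec.shape[0]} != {NODE_DIM}")
    return vec


def _gasteiger(mol: Chem.Mol) -> np.ndarray:
    try:
        AllChem.ComputeGasteigerCharges(mol)
        q = np.array([float(a.GetProp("_GasteigerCharge"))
                      for a in mol.GetAtoms()])
    except Exception:  # noqa: BLE001 - charges are a soft feature
        q = np.zeros(mol.GetNumAtoms())
    q[~np.isfinite(q)] = 0.0
    return q


def featurize_mol_nodes(mol: Chem.Mol, is_ligand: bool) -> np.ndarray:
    """(N, 73) node features for every heavy atom of a molecule."""
    pharm = perceive_pharmacophores(mol)
    charges = _gasteiger(mol)
    rows = [featurize_node(atom, pharm[i], is_ligand, charges[i])
            for i, atom in enumerate(mol.GetAtoms())]
    if not rows:
        raise FeaturizationError("molecule has no heavy atoms")
    return np.vstack(rows)


# ---------------------------------------------------------------------------
# edges
# ---------------------------------------------------------------------------

def build_covalent_edges(mol: Chem.Mol,
                         coords: Optional[np.ndarray] = None,
                         width: int = EDGE_DIM_COVALENT
                         ) -> Tuple[np.ndarray, np.ndarray]:
    """Directed arc pairs and features for all covalent heavy-atom bonds.

    Each undirected bond is materialized as two directed arcs (the
    message-passing convention).  Feature block width 12; when `width`
    is 24 (complex graphs) the non-covalent half is zero-filled.
    """
    if coords is None and mol.GetNumConformers() > 0:
        conf = mol.GetConformer()
        coords = np.array([list(conf.GetAtomPosition(i))
                           for i in range(mol.GetNumAtoms())])
    rotatable = set()
    if mol.GetNumBonds() > 0:
        for i, j in mol.GetSubstructMatches(_ROTATABLE):
            rotatable.add(frozenset((i, j)))
    src, dst, feats = [], [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = np.zeros(width)
        bt = bond.GetBondType()
        order = {Chem.BondType.SINGLE: 0, Chem.BondType.DOUBLE: 1,
                 Chem.BondType.TRIPLE: 2, Chem.BondType.AROMATIC: 3}
        f[_EDGE_SLICES["bond_type"].start + order.get(bt, 0)] = 1.0
        f[_EDGE_SLICES["conjugated"].start] = 1.0 if bond.GetIsConjugated() else 0.0
        f[_EDGE_SLICES["bond_ring"].start] = 1.0 if bond.IsInRing() else 0.0
        stereo = bond.GetStereo()
        s = _EDGE_SLICES["stereo"].start
        if stereo in (Chem.BondStereo.STEREOE, Chem.BondStereo.STEREOTRANS):
            f[s + 1] = 1.0
        elif stereo in (Chem.BondStereo.STEREOZ, Chem.BondStereo.STEREOCIS):
            f[s + 2] = 1.0
        else:
            f[s] = 1.0
        if coords is not None:
            length = float(np.linalg.norm(coords[i] - coords[j]))
            f[_EDGE_SLICES["bond_length"].start] = length / 2.0
        f[_EDGE_SLICES["rotatable"].start] = (
            1.0 if frozenset((i, j)) in rotatable else 0.0)
        f[_EDGE_SLICES["covalent_flag"].start] = 1.0
        src += [i, j]
        dst += [j, i]
        feats += [f, f.copy()]
    if not src:
        return np.zeros((2, 0), dtype=np.intp), np.zeros((0, width))
    return (np.array([src, dst], dtype=np.intp), np.vstack(feats))


def build_noncovalent_edges(pocket_coords: np.ndarray,
                            ligand_coords: np.ndarray,
                            pocket_pharm: np.ndarray,
                            ligand_pharm: np.ndarray,
                            cutoff: float = NONCOVALENT_CUTOFF,
                            width: int = EDGE_DIM_COMPLEX
                            ) -> Tuple[np.ndarray, np.ndarray]:
    """Protein-ligand contact edges with distance strictly below `cutoff`.

    Node indices refer to the merged complex graph: pocket atoms first,
    then ligand atoms.  The distance is encoded as 1-A-wide bins over
    [0, 8) plus an inverse-distance channel; donor-acceptor and
    hydrophobic-pair flags come from the pharmacophore roles of the
    endpoints.  No protein-protein or ligand-ligand contact edges.
    """
    n_p = len(pocket_coords)
    if n_p == 0 or len(ligand_coords) == 0:
        return np.zeros((2, 0), dtype=np.intp), np.zeros((0, width))
    diff = pocket_coords[:, None, :] - ligand_coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    pi, li = np.nonzero(dist < cutoff)  # strict: "less than 8 A"
    if pi.size == 0:
        return np.zeros((2, 0), dtype=np.intp), np.zeros((0, width))
    d = dist[pi, li]
    feats = np.zeros((pi.size, width))
    bins = np.minimum(d.astype(int), 7)
    start = _EDGE_SLICES["distance_bins"].start
    feats[np.arange(pi.size), start + bins] = 1.0
    feats[:, _EDGE_SLICES["inverse_distance"].start] = 1.0 / np.maximum(d, 0.5)
    feats[:, _EDGE_SLICES["protein_ligand_flag"].start] = 1.0
    # donor on one side + acceptor on the other (either orientation)
    don_p, acc_p = pocket_pharm[pi, 3], pocket_pharm[pi, 4]
    don_l, acc_l = ligand_pharm[li, 3], ligand_pharm[li, 4]
    feats[:, _EDGE_SLICES["donor_acceptor_pair"].start] = np.clip(
        don_p * acc_l + don_l * acc_p, 0.0, 1.0)
    hyd_p, hyd_l = pocket_pharm[pi, 2], ligand_pharm[li, 2]
    feats[:, _EDGE_SLICES["hydrophobic_pair"].start] = hyd_p * hyd_l
    src = np.concatenate([pi, li + n_p])
    dst = np.concatenate([li + n_p, pi])
    feats = np.vstack([feats, feats])
    return np.array([src, dst], dtype=np.intp), feats


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------

@dataclass
class MolecularGraph:
    node_features: np.ndarray  # (N, 73)
    edge_index: np.ndarray     # (2, E) directed arcs
    edge_features: np.ndarray  # (E, 12) or (E, 24)
    coords: np.ndarray         # (N, 3)
    node_origin: np.ndarray    # (N,), 0 = protein, 1 = ligand
    schema: FeatureSchema = field(default_factory=FeatureSchema)

    def __post_init__(self):
        if self.node_features.shape[1] != NODE_DIM:
            raise FeaturizationError(
                f"node width {self.node_features.shape[1]} != {NODE_DIM}")
        if self.edge_features.shape[0] != self.edge_index.shape[1]:
            raise FeaturizationError("edge feature/index length mismatch")
        if self.edge_features.size and self.edge_features.shape[1] not in (
                EDGE_DIM_COVALENT, EDGE_DIM_COMPLEX):
            raise FeaturizationError(
                f"edge width {self.edge_features.shape[1]} not in (12, 24)")

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]

    @property
    def is_complex(self) -> bool:
        return (self.edge_features.shape[1] == EDGE_DIM_COMPLEX
                if self.edge_features.size else
                bool(self.node_origin.min() == 0 and self.node_origin.max() == 1))

    def save(self, path) -> None:
        np.savez_compressed(
            path, node_features=self.node_features,
            edge_index=self.edge_index, edge_features=self.edge_features,
            coords=self.coords, node_origin=self.node_origin,
            schema_version=np.array([self.schema.version]),
            ablated=np.array(sorted(self.schema.ablated), dtype="U32"))

    @classmethod
    def load(cls, path) -> "MolecularGraph":
        z = np.load(path, allow_pickle=False)
        schema = FeatureSchema(ablated=frozenset(str(s) for s in z["ablated"]),
                               version=int(z["schema_version"][0]))
        return cls(z["node_features"], z["edge_index"], z["edge_features"],
                   z["coords"], z["node_origin"], schema)


def pocket_to_mol(pocket: ProteinStructure) -> Chem.Mol:
    """Perceive a pocket's chemistry by round-tripping it through PDB.

    Raises FeaturizationError when RDKit cannot perceive the fragment
    (such pockets are reported and skipped upstream).
    """
    block = structio.pocket_pdb_block(pocket)
    mol = Chem.MolFromPDBBlock(block, removeHs=True, proximityBonding=True,
                               sanitize=False)
    if mol is None:
        raise FeaturizationError("RDKit could not parse the pocket")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # noqa: BLE001
        raise FeaturizationError(f"pocket perception failed: {exc}") from exc
    if mol.GetNumAtoms() != len(pocket):
        raise FeaturizationError("pocket atom count changed during perception")
    return mol


def ligand_graph(pose: LigandPose,
                 schema: Optional[FeatureSchema] = None) -> MolecularGraph:
    """Covalent-only ligand graph (node width 73, edge width 12)."""
    schema = schema or FeatureSchema()
    x = featurize_mol_nodes(pose.mol, is_ligand=True)
    ei, ef = build_covalent_edges(pose.mol, pose.coords)
    x = schema.mask_nodes(x)
    ef = schema.mask_edges(ef)
    return MolecularGraph(x, ei, ef, pose.coords,
                          np.ones(len(x), dtype=np.intp), schema)


def pocket_graph(pocket: ProteinStructure,
                 schema: Optional[FeatureSchema] = None,
                 mol: Optional[Chem.Mol] = None) -> MolecularGraph:
    """Covalent-only pocket graph (node width 73, edge width 12)."""
    schema = schema or FeatureSchema()
    mol = mol if mol is not None else pocket_to_mol(pocket)
    x = featurize_mol_nodes(mol, is_ligand=False)
    ei, ef = build_covalent_edges(mol, pocket.coords)
    x = schema.mask_nodes(x)
    ef = schema.mask_edges(ef)
    return MolecularGraph(x, ei, ef, pocket.coords,
                          np.zeros(len(x), dtype=np.intp), schema)


def complex_graph(record: ComplexRecord,
                  schema: Optional[FeatureSchema] = None,
                  cutoff: float = NONCOVALENT_CUTOFF,
                  pocket_mol: Optional[Chem.Mol] = None) -> MolecularGraph:
    """Merged pocket+ligand graph with covalent and contact edges (width 24)."""
    schema = schema or FeatureSchema()
    pmol = pocket_mol if pocket_mol is not None else pocket_to_mol(record.pocket)
    lmol = record.ligand.mol
    xp = featurize_mol_nodes(pmol, is_ligand=False)
    xl = featurize_mol_nodes(lmol, is_ligand=True)
    n_p = len(xp)
    pc, lc = record.pocket.coords, record.ligand.coords
    ei_p, ef_p = build_covalent_edges(pmol, pc, width=EDGE_DIM_COMPLEX)
    ei_l, ef_l = build_covalent_edges(lmol, lc, width=EDGE_DIM_COMPLEX)
    pharm_p = perceive_pharmacophores(pmol)
    pharm_l = perceive_pharmacophores(lmol)
    ei_nc, ef_nc = build_noncovalent_edges(pc, lc, pharm_p, pharm_l,
                                           cutoff=cutoff)
    ei = np.concatenate([ei_p, ei_l + n_p, ei_nc], axis=1)
    ef = np.vstack([ef_p, ef_l, ef_nc])
    x = np.vstack([xp, xl])
    x = schema.mask_nodes(x)
    ef = schema.mask_edges(ef)
    origin = np.concatenate([np.zeros(n_p, dtype=np.intp),
                             np.ones(len(xl), dtype=np.intp)])
    return MolecularGraph(x, ei, ef, np.vstack([pc, lc]), origin, schema)


class ComplexFeaturizer:
    """Featurizer with per-target / per-molecule caches.

    Node features and covalent edges depend only on chemistry (and, for
    bond lengths, on the rigid conformer), so they are computed once per
    pocket and once per ligand; per pose only the non-covalent contact
    edges are rebuilt.
    """

    def __init__(self, schema: Optional[FeatureSchema] = None,
                 cutoff: float = NONCOVALENT_CUTOFF):
        self.schema = schema or FeatureSchema()
        self.cutoff = cutoff
        self._pockets: dict = {}
        self._ligands: dict = {}

    def _pocket_entry(self, target_id: str, pocket: ProteinStructure):
        entry = self._pockets.get(target_id)
        if entry is None:
            mol = pocket_to_mol(pocket)
            x = featurize_mol_nodes(mol, is_ligand=False)
            ei, ef = build_covalent_edges(mol, pocket.coords,
                                          width=EDGE_DIM_COMPLEX)
            pharm = perceive_pharmacophores(mol)
            entry = (mol, x, ei, ef, pharm)
            self._pockets[target_id] = entry
        return entry

    def _ligand_entry(self, molecule_id: str, pose: LigandPose):
        entry = self._ligands.get(molecule_id)
        if entry is None:
            x = featurize_mol_nodes(pose.mol, is_ligand=True)
            ei, ef = build_covalent_edges(pose.mol, pose.coords,
                                          width=EDGE_DIM_COMPLEX)
            pharm = perceive_pharmacophores(pose.mol)
            entry = (x, ei, ef, pharm)
            self._ligands[molecule_id] = entry
        return entry

    def complex_graph(self, record: ComplexRecord) -> MolecularGraph:
        _, xp, ei_p, ef_p, pharm_p = self._pocket_entry(
            record.target_id, record.pocket)
        key = record.molecule_id or f"{record.target_id}/{record.pose_id}"
        xl, ei_l, ef_l, pharm_l = self._ligand_entry(key, record.ligand)
        n_p = len(xp)
        pc, lc = record.pocket.coords, record.ligand.coords
        ei_nc, ef_nc = build_noncovalent_edges(pc, lc, pharm_p, pharm_l,
                                               cutoff=self.cutoff)
        ei = np.concatenate([ei_p, ei_l + n_p, ei_nc], axis=1)
        ef = np.vstack([ef_p, ef_l, ef_nc])
        x = self.schema.mask_nodes(np.vstack([xp, xl]))
        ef = self.schema.mask_edges(ef)
        origin = np.concatenate([np.zeros(n_p, dtype=np.intp),
                                 np.ones(len(xl), dtype=np.intp)])
        return MolecularGraph(x, ei, ef, np.vstack([pc, lc]), origin,
                              self.schema)

    def nondock_graphs(self, record: ComplexRecord):
        mol, xp, ei_p, ef_p, _ = self._pocket_entry(
            record.target_id, record.pocket)
        pg = MolecularGraph(self.schema.mask_nodes(xp.copy()),
                            ei_p, self.schema.mask_edges(
                                ef_p[:, :EDGE_DIM_COVALENT].copy()),
                            record.pocket.coords,
                            np.zeros(len(xp), dtype=np.intp), self.schema)
        key = record.molecule_id or f"{record.target_id}/{record.pose_id}"
        xl, ei_l, ef_l, _ = self._ligand_entry(key, record.ligand)
        lg = MolecularGraph(self.schema.mask_nodes(xl.copy()),
                            ei_l, self.schema.mask_edges(
                                ef_l[:, :EDGE_DIM_COVALENT].copy()),
                            record.ligand.coords,
                            np.ones(len(xl), dtype=np.intp), self.schema)
        return pg, lg


def build_graphs(record: ComplexRecord, mode: str = "complex",
                 schema: Optional[FeatureSchema] = None,
                 cutoff: float = NONCOVALENT_CUTOFF,
                 pocket_mol: Optional[Chem.Mol] = None):
    """Spec entry point: `complex` -> one merged graph; `nondock` ->
    (pocket graph, ligand graph), both covalent-only."""
    if mode == "complex":
        return complex_graph(record, schema, cutoff, pocket_mol)
    if mode == "nondock":
        return (pocket_graph(record.pocket, schema, mol=pocket_mol),
                ligand_graph(record.ligand, schema))
    raise ValueError(f"unknown mode {mode!r}")
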