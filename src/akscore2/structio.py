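"""Molecular structure I/O: proteins, ligand poses, pockets, RMSD, manifests.

Proteins are read from PDB with Biopython (heavy atoms only, waters
stripped, altlocs resolved to the highest-occupancy conformer) and
written with gemmi.  Ligand poses come from multi-record V2000 SDF
(canonical) or MOL2 (read-only) via RDKit.  Dataset manifests are TSV
files binding complexes to their training-set tags and labels.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from rdkit import Chem
from rdkit.Chem import rdMolAlign

logger = logging.getLogger(__name__)

SET_TAGS = ("native", "conf_decoy", "cross_decoy", "random_decoy")

WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O", "TIP3", "SOL"}


class StructIOError(ValueError):
    """Base error for structure reading/validation problems."""


class EmptyStructureError(StructIOError):
    pass


class EmptyPocketError(StructIOError):
    pass


class IncompatiblePoseError(StructIOError):
    pass


class ManifestError(StructIOError):
    pass


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """One protein heavy atom."""
    element: str
    name: str
    res_id: int
    res_name: str
    chain: str
    coords: np.ndarray  # (3,) Angstrom

    def residue_key(self):
        return (self.chain, self.res_id)


@dataclass
class ProteinStructure:
    atoms: list  # of Atom

    def __post_init__(self):
        for a in self.atoms:
            if not np.all(np.isfinite(a.coords)):
                raise StructIOError(f"non-finite coordinates on atom {a.name}")

    @property
    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def residues(self) -> dict:
        """Atoms grouped by (chain, residue id), insertion order preserved."""
        out: dict = {}
        for a in self.atoms:
            out.setdefault(a.residue_key(), []).append(a)
        return out

    def __len__(self):
        return len(self.atoms)


@dataclass
class LigandPose:
    """A single heavy-atom ligand conformation with perceived chemistry."""
    mol: Chem.Mol  # sanitized, hydrogens removed, one conformer
    pose_id: int = 0
    source: str = ""
    record_index: int = 0

    @property
    def coords(self) -> np.ndarray:
        conf = self.mol.GetConformer()
        return np.array([list(conf.GetAtomPosition(i))
                         for i in range(self.mol.GetNumAtoms())], dtype=float)

    @property
    def elements(self) -> list:
        return [a.GetSymbol() for a in self.mol.GetAtoms()]

    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    def with_coords(self, coords: np.ndarray, pose_id: Optional[int] = None) -> "LigandPose":
        mol = Chem.Mol(self.mol)
        conf = mol.GetConformer()
        for i, xyz in enumerate(np.asarray(coords, dtype=float)):
            conf.SetAtomPosition(i, Chem.rdGeometry.Point3D(*xyz))
        return LigandPose(mol, self.pose_id if pose_id is None else pose_id,
                          self.source, self.record_index)


@dataclass
class ComplexRecord:
    """One pocket/pose pair with training-set provenance.

    set_tag routes the sample to its loss terms: natives carry an
    experimental affinity (R_true = 0 by definition), conformational
    decoys carry an RMSD from the native pose, cross-docked and random
    decoys carry neither label.
    """
    target_id: str
    pocket: ProteinStructure
    ligand: LigandPose
    set_tag: str
    E_true: Optional[float] = None
    R_true: Optional[float] = None
    molecule_id: str = ""
    pose_id: int = 0

    def __post_init__(self):
        validate_record_labels(self.set_tag, self.E_true, self.R_true)


def validate_record_labels(set_tag, E_true, R_true, row=None):
    where = "" if row is None else f" (manifest row {row})"
    if set_tag not in SET_TAGS:
        raise ManifestError(f"unknown set_tag {set_tag!r}{where}")
    if set_tag == "native":
        if E_true is None:
            raise ManifestError(f"native sample missing E_true{where}")
        if R_true not in (None, 0.0) and abs(R_true) > 1e-9:
            raise ManifestError(f"native sample must have R_true=0{where}")
    elif set_tag == "conf_decoy":
        if R_true is None:
            raise ManifestError(f"conf_decoy sample missing R_true{where}")
    else:  # cross/random decoys have no labels
        if E_true is not None or (R_true is not None):
            raise ManifestError(
                f"{set_tag} sample must not carry E_true/R_true{where}")


# ---------------------------------------------------------------------------
# protein reading / writing
# ---------------------------------------------------------------------------

def read_protein(path, keep_hetero: Sequence[str] = ()) -> ProteinStructure:
    """Read heavy protein atoms from a PDB file.

    Hydrogens and waters are always removed; HETATM residues are
    stripped unless named in `keep_hetero` (ions/cofactor allowlist).
    Altlocs resolve to the highest-occupancy conformer (Biopython's
    default selected child).
    """
    path = Path(path)
    if not path.exists():
        raise StructIOError(f"no such file: {path}")
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure("prot", str(path))
    except Exception as exc:  # noqa: BLE001 - surface as domain error
        raise StructIOError(f"cannot parse PDB {path}: {exc}") from exc

    atoms = []
    models = list(structure.get_models())
    if not models:
        raise EmptyStructureError(f"no heavy atoms in {path}")
    model = models[0]
    for chain in model:
        for residue in chain:
            hetflag = residue.id[0].strip()
            resname = residue.get_resname().strip()
            if resname in WATER_RESNAMES:
                continue
            if hetflag and hetflag != "" and resname not in keep_hetero:
                # HETATM record (hetflag like 'H_XYZ' or 'W')
                continue
            for atom in residue:
                # disordered atoms yield their highest-occupancy child
                element = (atom.element or "").strip().capitalize()
                if element in ("H", "D", ""):
                    continue
                atoms.append(Atom(element=element,
                                  name=atom.get_name(),
                                  res_id=residue.id[1],
                                  res_name=resname,
                                  chain=chain.id,
                                  coords=np.array(atom.coord, dtype=float)))
    if not atoms:
        raise EmptyStructureError(f"no heavy atoms in {path}")
    return ProteinStructure(atoms)


def write_protein(protein: ProteinStructure, path) -> None:
    """Write a ProteinStructure as a PDB file (gemmi backend)."""
    st = gemmi.Structure()
    st.name = "akscore2"
    model = gemmi.Model("1")
    chains: dict = {}
    for atom in protein.atoms:
        chain = chains.get(atom.chain)
        if chain is None:
            chain = gemmi.Chain(atom.chain)
            chains[atom.chain] = chain
        if (len(chain) == 0 or chain[-1].seqid.num != atom.res_id
                or chain[-1].name != atom.res_name):
            res = gemmi.Residue()
            res.name = atom.res_name
            res.het_flag = "A"  # emit ATOM records even for nonstandard names
            res.seqid = gemmi.SeqId(atom.res_id, " ")
            chain.add_residue(res)
        ga = gemmi.Atom()
        ga.name = atom.name
        ga.element = gemmi.Element(atom.element)
        ga.pos = gemmi.Position(*atom.coords)
        ga.occ = 1.0
        chain[-1].add_atom(ga)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def pocket_pdb_block(pocket: ProteinStructure) -> str:
    """PDB text for a pocket (used to hand pockets to RDKit perception)."""
    lines = []
    for i, atom in enumerate(pocket.atoms, start=1):
        name = atom.name[:4]
        lines.append(
            f"ATOM  {i:5d} {name:<4s}{atom.res_name:>4s} {atom.chain[:1]}"
            f"{atom.res_id:4d}    "
            f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {atom.element:>2s}")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# pocket extraction
# ---------------------------------------------------------------------------

def extract_pocket(protein: ProteinStructure, ligand: LigandPose,
                   cutoff: float = 5.0) -> ProteinStructure:
    """Residues with any heavy atom within `cutoff` (inclusive) of the ligand.

    Whole residues are returned, never partial ones.  5 A is the
    conventional binding-pocket radius around a crystallized ligand.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pc = protein.coords
    lc = ligand.coords
    if len(pc) == 0 or len(lc) == 0:
        raise EmptyPocketError("empty protein or ligand")
    d2 = ((pc[:, None, :] - lc[None, :, :]) ** 2).sum(axis=2)
    near = d2.min(axis=1) <= cutoff ** 2
    keep_residues = {a.residue_key() for a, flag in zip(protein.atoms, near) if flag}
    if not keep_residues:
        raise EmptyPocketError(f"no residue within {cutoff} A of the ligand")
    atoms = [a for a in protein.atoms if a.residue_key() in keep_residues]
    return ProteinStructure(atoms)


# ---------------------------------------------------------------------------
# ligand reading
# ---------------------------------------------------------------------------

def _prepare_mol(mol: Chem.Mol) -> Chem.Mol:
    mol = Chem.RemoveHs(mol)
    Chem.SanitizeMol(mol)
    return mol


def read_ligand_poses(path, sanitize_errors: str = "skip") -> list:
    """Read all poses from an SDF (multi-record V2000) or MOL2 file.

    Records RDKit fails to perceive are skipped with a warning (the
    index gap is visible through `record_index`), or raised if
    `sanitize_errors="raise"`.
    """
    path = Path(path)
    if not path.exists():
        raise StructIOError(f"no such file: {path}")
    poses = []
    if path.suffix.lower() == ".mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=True)
        mols = [mol]
    else:
        supplier = Chem.SDMolSupplier(str(path), removeHs=True, sanitize=True)
        mols = list(supplier)
    for idx, mol in enumerate(mols):
        if mol is None:
            msg = f"unparseable record {idx} in {path}"
            if sanitize_errors == "raise":
                raise StructIOError(msg)
            logger.warning(msg)
            continue
        try:
            mol = _prepare_mol(mol)
        except Exception as exc:  # noqa: BLE001
            if sanitize_errors == "raise":
                raise StructIOError(f"record {idx} in {path}: {exc}") from exc
            logger.warning("skipping record %d in %s: %s", idx, path, exc)
            continue
        poses.append(LigandPose(mol, pose_id=idx, source=str(path),
                                record_index=idx))
    return poses


def write_ligand_poses(poses: Iterable[LigandPose], path) -> None:
    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    for pose in poses:
        mol = Chem.Mol(pose.mol)
        mol.SetProp("_Name", f"pose_{pose.pose_id}")
        writer.write(mol)
    writer.close()


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def _same_molecule(a: LigandPose, b: LigandPose) -> bool:
    if a.n_atoms != b.n_atoms:
        return False
    if sorted(a.elements) != sorted(b.elements):
        return False
    return True


def ligand_rmsd(pose_a: LigandPose, pose_b: LigandPose,
                symmetry_aware: bool = True) -> float:
    """Heavy-atom RMSD between two poses of the same molecule, in Angstrom.

    Computed without re-superposition: docked poses share the receptor
    frame, so rigid displacement is part of the deviation.  With
    `symmetry_aware` the minimum over bond-graph automorphisms is
    returned (e.g. a benzene ring rotated by 60 degrees scores 0).
    """
    if not _same_molecule(pose_a, pose_b):
        raise IncompatiblePoseError(
            f"pose atom mismatch: {pose_a.n_atoms} vs {pose_b.n_atoms} atoms "
            f"or differing element composition")
    ca, cb = pose_a.coords, pose_b.coords
    if symmetry_aware:
        # automorphisms of the bond graph = self substructure matches
        query = Chem.Mol(pose_a.mol)
        matches = pose_a.mol.GetSubstructMatches(query, uniquify=False,
                                                 useChirality=False,
                                                 maxMatches=10000)
        if not matches:
            matches = [tuple(range(pose_a.n_atoms))]
        best = math.inf
        for perm in matches:
            d = ca[list(perm)] - cb
            best = min(best, float((d * d).sum()))
        return math.sqrt(best / pose_a.n_atoms)
    d = ca - cb
    return math.sqrt(float((d * d).sum()) / pose_a.n_atoms)


def rdkit_rms_reference(pose_a: LigandPose, pose_b: LigandPose) -> float:
    """Symmetry-aware, no-alignment RMSD via RDKit (cross-check path)."""
    return rdMolAlign.CalcRMS(Chem.Mol(pose_a.mol), Chem.Mol(pose_b.mol))


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["target_id", "ligand_file", "pose_index", "set_tag"]


@dataclass
class ManifestRow:
    target_id: str
    ligand_file: str
    pose_index: int          # record index within the ligand file
    set_tag: str
    E_true: Optional[float]
    R_true: Optional[float]
    molecule_id: str
    protein_file: str
    pose_id: int             # global pose number per (target, molecule)
    row: int


def read_manifest(path) -> list:
    """Read a dataset manifest TSV into validated rows.

    Required columns: target_id, ligand_file, pose_index, set_tag.
    Optional: E_true, R_true, molecule_id, protein_file.  Label
    invariants per set_tag are enforced; violations name the row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"target_id": str})
    if df.empty:
        logger.warning("empty manifest: %s", path)
        return []
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing columns {missing}")
    rows = []
    for i, rec in enumerate(df.itertuples(index=False)):
        E = getattr(rec, "E_true", None)
        R = getattr(rec, "R_true", None)
        E = None if E is None or (isinstance(E, float) and math.isnan(E)) else float(E)
        R = None if R is None or (isinstance(R, float) and math.isnan(R)) else float(R)
        validate_record_labels(rec.set_tag, E, R, row=i)
        pose_idx = int(rec.pose_index)
        rows.append(ManifestRow(
            target_id=str(rec.target_id),
            ligand_file=str(rec.ligand_file),
            pose_index=pose_idx,
            set_tag=str(rec.set_tag),
            E_true=E, R_true=R,
            molecule_id=str(getattr(rec, "molecule_id", "")),
            protein_file=str(getattr(rec, "protein_file", "")),
            pose_id=int(getattr(rec, "pose_id", pose_idx)),
            row=i))
    return rows


def load_complexes(manifest_path, pocket_cutoff: float = 5.0,
                   extract: bool = True) -> list:
    """Materialize ComplexRecords from a manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    rows = read_manifest(manifest_path)
    pose_cache: dict = {}
    protein_cache: dict = {}
    records = []
    for row in rows:
        pfile = row.protein_file or f"proteins/{row.target_id}.pdb"
        ppath = root / pfile
        if ppath not in protein_cache:
            protein_cache[ppath] = read_protein(ppath)
        lpath = root / row.ligand_file
        if lpath not in pose_cache:
            pose_cache[lpath] = {p.record_index: p
                                 for p in read_ligand_poses(lpath)}
        pose = pose_cache[lpath].get(row.pose_index)
        if pose is None:
            logger.warning("manifest row %d: pose %d missing from %s; skipped",
                           row.row, row.pose_index, lpath)
            continue
        protein = protein_cache[ppath]
        pocket = (extract_pocket(protein, pose, pocket_cutoff)
                  if extract else protein)
        records.append(ComplexRecord(
            target_id=row.target_id, pocket=pocket, ligand=pose,
            set_tag=row.set_tag, E_true=row.E_true, R_true=row.R_true,
            molecule_id=row.molecule_id or row.target_id,
            pose_id=row.pose_id))
    return records


def write_manifest(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, sep="\t", index=False)
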