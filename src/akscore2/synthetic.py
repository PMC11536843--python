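"""Self-contained synthetic complexes with a planted interaction energy.

The world emulates the four training sets of a docking-based pipeline:
native complexes with affinities, redocked conformational decoys with
RMSD labels, cross-docked decoys (other targets' ligands) and random
decoys (fresh ligands), plus a noisy surrogate for a physics docking
score.

The planted ground truth is a pharmacophore-complementarity energy

    E(pose) = - sum_{i in ligand, j in pocket} t_i^T W t_j * phi(d_ij)

where t are the 7-dimensional pharmacophore multi-hots the featurizer
itself perceives, W is a fixed symmetric complementarity matrix
(kcal/mol per contact) and phi is a Gaussian contact well centered at
3.5 A (width 1 A), well inside the 8 A edge cutoff.  Because the energy
is a function of exactly the information the graphs encode
(pharmacophore types and pairwise distances under 8 A), trained models
can in principle recover it, which is what makes parameter-recovery
tests meaningful.

Key construction choices: native ligands are composition-biased toward
their pocket's type profile and best-of-m selected, planting the signal
the interaction classifier must find; cross and random decoy poses are
placed by a *type-blind* packing optimizer, so actives and inactives
look equally "docked" geometrically and only complementarity separates
them (as docking programs pack every ligand they are given).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

RDLogger.DisableLog("rdApp.error")  # ligand generation retries are expected

from . import structio
from .graphs import perceive_pharmacophores
from .structio import Atom, ComplexRecord, LigandPose, ProteinStructure

logger = logging.getLogger(__name__)

PHARM_DIM = 7  # aromatic, ring, hydrophobic, donor, acceptor, acidic, basic

# Complementarity weights, kcal/mol per ideal contact.  Favorable:
# donor-acceptor, acid-base, hydrophobic and aromatic packing; repulsive:
# like-with-like polar contacts.  Symmetric by construction.
_W = np.zeros((PHARM_DIM, PHARM_DIM))
_AROMATIC, _RING, _HPHOB, _DON, _ACC, _ACID, _BASE = range(PHARM_DIM)
_W[_AROMATIC, _AROMATIC] = 0.30
_W[_RING, _RING] = 0.10
_W[_RING, _HPHOB] = _W[_HPHOB, _RING] = 0.08
_W[_HPHOB, _HPHOB] = 0.25
_W[_DON, _ACC] = _W[_ACC, _DON] = 0.60
_W[_ACID, _BASE] = _W[_BASE, _ACID] = 0.80
_W[_DON, _DON] = _W[_ACC, _ACC] = -0.30
_W[_ACID, _ACID] = _W[_BASE, _BASE] = -0.50
for _t in (_DON, _ACC, _ACID, _BASE):
    _W[_HPHOB, _t] = _W[_t, _HPHOB] = -0.10
assert np.allclose(_W, _W.T)

PHI_CENTER = 3.5  # A, ideal-contact distance
PHI_WIDTH = 1.0   # A, Gaussian width of the contact well
CONTACT_CUTOFF = 8.0

# rough per-element pharmacophore propensities, used only for the
# composition bias of native ligands (actual types come from perception)
_ELEMENT_TYPES = {
    "C": np.array([0, 0, 1.0, 0, 0, 0, 0.0]),
    "N": np.array([0, 0, 0, 0.8, 0.3, 0, 0.6]),
    "O": np.array([0, 0, 0, 0.5, 1.0, 0.2, 0]),
    "S": np.array([0, 0, 0.5, 0, 0.2, 0, 0]),
    "F": np.array([0, 0, 1.0, 0, 0, 0, 0]),
    "Cl": np.array([0, 0, 1.0, 0, 0, 0, 0]),
}
_BASE_FREQ = {"C": 0.55, "N": 0.15, "O": 0.18, "S": 0.04, "F": 0.04,
              "Cl": 0.04}
_MAX_DEGREE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1}


@dataclass(frozen=True)
class WorldSpec:
    """Generator parameters (the study conditions of every synthetic run)."""
    n_targets: int = 50
    n_residues: int = 8            # 3-atom pseudo-residues per pocket
    shell_radius: float = 8.0      # A, pocket shell around the site center
    ligand_atoms: Tuple[int, int] = (8, 22)
    n_conf_decoys: int = 6
    n_cross_decoys: int = 3
    n_random_decoys: int = 3
    sigma_affinity: float = 0.5    # kcal/mol noise on E_true
    sigma_physics: float = 2.0     # kcal/mol noise on the surrogate physics score
    native_candidates: int = 6     # best-of-m ligand selection per target
    composition_bias: float = 4.0  # strength of pocket-complementary bias
    energy_scale: float = 0.6      # calibrates E_true into a kcal/mol-like range


@dataclass
class PoseTruth:
    planted_energy: float
    physics_score: float


@dataclass
class SyntheticWorld:
    spec: WorldSpec
    seed: int
    records: List[ComplexRecord] = field(default_factory=list)
    truth: Dict[tuple, PoseTruth] = field(default_factory=dict)
    pockets: Dict[str, ProteinStructure] = field(default_factory=dict)
    natives: Dict[str, ComplexRecord] = field(default_factory=dict)

    def key(self, rec: ComplexRecord) -> tuple:
        return (rec.target_id, rec.molecule_id, rec.pose_id)

    @property
    def target_ids(self) -> list:
        return sorted(self.pockets)


# ---------------------------------------------------------------------------
# planted energy
# ---------------------------------------------------------------------------

def contact_well(d: np.ndarray) -> np.ndarray:
    """Gaussian contact well phi(d), zero beyond the 8 A cutoff."""
    phi = np.exp(-((d - PHI_CENTER) ** 2) / (2.0 * PHI_WIDTH ** 2))
    return np.where(d < CONTACT_CUTOFF, phi, 0.0)


def planted_energy(lig_coords: np.ndarray, lig_types: np.ndarray,
                   pocket_coords: np.ndarray, pocket_types: np.ndarray,
                   scale: float = 1.0) -> float:
    """E = -scale * sum t_i^T W t_j phi(d_ij) over ligand-pocket pairs."""
    d = np.sqrt(((lig_coords[:, None, :] - pocket_coords[None, :, :]) ** 2
                 ).sum(axis=2))
    comp = lig_types @ _W @ pocket_types.T   # (n_lig, n_pocket)
    return float(-scale * (comp * contact_well(d)).sum())


def packing_score(lig_coords: np.ndarray, pocket_coords: np.ndarray) -> float:
    """Type-blind burial score (more negative = better packed)."""
    d = np.sqrt(((lig_coords[:, None, :] - pocket_coords[None, :, :]) ** 2
                 ).sum(axis=2))
    return float(-contact_well(d).sum())


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])


def rigid_transform(coords: np.ndarray, rot: np.ndarray,
                    trans: np.ndarray) -> np.ndarray:
    center = coords.mean(axis=0)
    return (coords - center) @ rot.T + center + trans


def _damped_rotation(rng, frac: float) -> np.ndarray:
    rot = frac * _random_rotation(rng) + (1.0 - frac) * np.eye(3)
    u, _, vt = np.linalg.svd(rot)
    return u @ vt


def _optimize_pose(coords: np.ndarray, objective, rng,
                   n_starts: int = 64, site_radius: float = 7.0,
                   refine_stages=(1.0, 0.5, 0.25, 0.1, 0.05, 0.02),
                   n_per_stage: int = 50) -> np.ndarray:
    """Random-restart rigid search, then staged greedy refinement with
    decaying move sizes, so the returned pose is a tight local optimum."""
    center = coords - coords.mean(axis=0)
    best, best_e = None, math.inf
    for _ in range(n_starts):
        rot = _random_rotation(rng)
        trans = rng.normal(size=3)
        trans *= (site_radius * rng.random() ** (1.0 / 3)) / np.linalg.norm(trans)
        cand = center @ rot.T + trans
        e = objective(cand)
        if e < best_e:
            best, best_e = cand, e
    for step in refine_stages:
        for _ in range(n_per_stage):
            rot = _damped_rotation(rng, min(step, 0.5))
            cand = rigid_transform(best, rot, rng.normal(scale=step, size=3))
            e = objective(cand)
            if e < best_e:
                best, best_e = cand, e
    return best


# ---------------------------------------------------------------------------
# pockets
# ---------------------------------------------------------------------------

_RESIDUE_TEMPLATES = [("C", "C", "C"), ("C", "C", "O"), ("C", "C", "N"),
                      ("C", "C", "S"), ("C", "O", "C"), ("C", "N", "C"),
                      ("O", "C", "O"), ("N", "C", "N"), ("O", "C", "N")]


def _make_pocket(rng, spec: WorldSpec) -> ProteinStructure:
    """Rigid pseudo-residues (3 bonded heavy atoms) on a shell around the
    binding site, far enough apart that proximity bonding keeps them
    separate fragments."""
    centers = []
    attempts = 0
    while len(centers) < spec.n_residues and attempts < 2000:
        attempts += 1
        v = rng.normal(size=3)
        v *= spec.shell_radius / np.linalg.norm(v)
        if all(np.linalg.norm(v - c) > 4.5 for c in centers):
            centers.append(v)
    atoms = []
    # per-pocket template distribution (Dirichlet) so pockets differ in
    # character — some donor-rich, some hydrophobic, some basic — which
    # is what makes pocket-conditional complementarity learnable
    weights = rng.dirichlet(0.4 * np.ones(len(_RESIDUE_TEMPLATES)))
    for ri, center in enumerate(centers):
        template = _RESIDUE_TEMPLATES[
            rng.choice(len(_RESIDUE_TEMPLATES), p=weights)]
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        perp = np.cross(axis, rng.normal(size=3))
        perp /= np.linalg.norm(perp)
        positions = [center - 1.5 * axis, center,
                     center + 1.5 * (0.3 * axis + 0.95 * perp)]
        seen: dict = {}
        for el, pos in zip(template, positions):
            seen[el] = seen.get(el, 0) + 1
            atoms.append(Atom(element=el, name=f"{el}{seen[el]}",
                              res_id=ri + 1, res_name="PSR", chain="A",
                              coords=np.asarray(pos, dtype=float)))
    return ProteinStructure(atoms)


def _pocket_types(pocket: ProteinStructure) -> np.ndarray:
    from .graphs import pocket_to_mol
    return perceive_pharmacophores(pocket_to_mol(pocket))


# ---------------------------------------------------------------------------
# ligands
# ---------------------------------------------------------------------------

def _element_probs(pocket_types: Optional[np.ndarray],
                   beta: float) -> Tuple[list, np.ndarray]:
    elements = list(_BASE_FREQ)
    base = np.array([_BASE_FREQ[e] for e in elements])
    if pocket_types is None or beta == 0.0:
        return elements, base / base.sum()
    profile = pocket_types.mean(axis=0)
    scores = np.array([_ELEMENT_TYPES[e] @ _W @ profile for e in elements])
    spread = scores.std()
    if spread > 1e-9:  # z-score so beta sets the real concentration
        scores = (scores - scores.mean()) / spread
    p = base * np.exp(beta * scores)
    return elements, p / p.sum()


def random_ligand(rng, spec: WorldSpec,
                  pocket_types: Optional[np.ndarray] = None,
                  biased: bool = False, max_tries: int = 30) -> LigandPose:
    """A random drug-like heavy-atom graph with an embedded 3D conformer.

    Built as a random tree under valence caps with occasional ring
    closures, an optional benzene ring seed and carbonyl conversion;
    `biased` skews element composition toward pocket complementarity.
    """
    elements, probs = _element_probs(pocket_types if biased else None,
                                     spec.composition_bias)
    lo, hi = spec.ligand_atoms
    for _ in range(max_tries):
        try:
            n_atoms = int(rng.integers(lo, hi + 1))
            mol = Chem.RWMol()
            if n_atoms >= 9 and rng.random() < 0.5:
                ring = Chem.MolFromSmiles("c1ccccc1")
                mol = Chem.RWMol(ring)
            else:
                mol.AddAtom(Chem.Atom("C"))
            while mol.GetNumAtoms() < n_atoms:
                el = elements[rng.choice(len(elements), p=probs)]
                open_atoms = [a.GetIdx() for a in mol.GetAtoms()
                              if a.GetDegree() < _MAX_DEGREE.get(
                                  a.GetSymbol(), 4)
                              and not (a.GetIsAromatic()
                                       and a.GetDegree() >= 3)]
                if not open_atoms:
                    break
                parent = open_atoms[rng.integers(len(open_atoms))]
                idx = mol.AddAtom(Chem.Atom(el))
                mol.AddBond(parent, idx, Chem.BondType.SINGLE)
            # occasional carbonyl: O(degree 1) on a C with spare valence
            for atom in mol.GetAtoms():
                if (atom.GetSymbol() == "O" and atom.GetDegree() == 1
                        and rng.random() < 0.35):
                    nb = atom.GetNeighbors()[0]
                    if nb.GetSymbol() == "C" and nb.GetDegree() <= 3 \
                            and not nb.GetIsAromatic():
                        mol.GetBondBetweenAtoms(
                            atom.GetIdx(), nb.GetIdx()).SetBondType(
                                Chem.BondType.DOUBLE)
            # occasional ring closure between distant open atoms
            if mol.GetNumAtoms() >= 5 and rng.random() < 0.35:
                dm = Chem.GetDistanceMatrix(mol, force=True)
                cands = [(i, j) for i in range(mol.GetNumAtoms())
                         for j in range(i + 1, mol.GetNumAtoms())
                         if 2 <= dm[i, j] <= 6
                         and mol.GetAtomWithIdx(i).GetDegree()
                         < _MAX_DEGREE.get(mol.GetAtomWithIdx(i).GetSymbol(), 4)
                         and mol.GetAtomWithIdx(j).GetDegree()
                         < _MAX_DEGREE.get(mol.GetAtomWithIdx(j).GetSymbol(), 4)
                         and not mol.GetAtomWithIdx(i).GetIsAromatic()
                         and not mol.GetAtomWithIdx(j).GetIsAromatic()]
                if cands:
                    i, j = cands[rng.integers(len(cands))]
                    mol.AddBond(int(i), int(j), Chem.BondType.SINGLE)
            m = mol.GetMol()
            Chem.SanitizeMol(m)
            m = Chem.AddHs(m)
            if AllChem.EmbedMolecule(
                    m, randomSeed=int(rng.integers(1, 2 ** 31 - 1))) != 0:
                continue
            m = Chem.RemoveHs(m)
            return LigandPose(m)
        except Exception as exc:  # noqa: BLE001 - retry on any chemistry hiccup
            logger.debug("ligand retry: %s", exc)
    raise RuntimeError("could not generate a valid ligand")


# ---------------------------------------------------------------------------
# world generation
# ---------------------------------------------------------------------------

def generate_world(spec: WorldSpec, seed: int,
                   out_dir=None) -> SyntheticWorld:
    """Generate the four-set synthetic world; optionally write it out as
    PDB/SDF structure files plus manifest and physics TSVs."""
    rng = np.random.default_rng(seed)
    world = SyntheticWorld(spec=spec, seed=seed)
    target_ids = [f"T{i:04d}" for i in range(spec.n_targets)]
    pocket_data = {}
    for tid in target_ids:
        pocket = _make_pocket(rng, spec)
        ptypes = _pocket_types(pocket)
        world.pockets[tid] = pocket
        pocket_data[tid] = (pocket, ptypes)

    def lig_types(pose: LigandPose) -> np.ndarray:
        return perceive_pharmacophores(pose.mol)

    scale = spec.energy_scale

    def add(rec: ComplexRecord, e_planted: float):
        world.records.append(rec)
        e_phys = e_planted + rng.normal(scale=spec.sigma_physics)
        world.truth[world.key(rec)] = PoseTruth(e_planted, e_phys)

    # natives: composition-biased candidates are pre-screened by perceived
    # type complementarity, the most complementary ones docked, and the
    # best-scoring pose kept — true binders are chemically matched to
    # their pocket, not merely well-placed
    for tid in target_ids:
        pocket, ptypes = pocket_data[tid]
        pc = pocket.coords
        profile = ptypes.mean(axis=0)
        candidates = []
        for _ in range(spec.native_candidates):
            cand = random_ligand(rng, spec, ptypes, biased=True)
            ct = lig_types(cand)
            comp = float((ct @ _W @ profile).mean())
            candidates.append((comp, cand, ct))
        candidates.sort(key=lambda t: -t[0])
        best = None
        for _, cand, ct in candidates[:max(2, spec.native_candidates // 3)]:
            coords = _optimize_pose(
                cand.coords,
                lambda c: planted_energy(c, ct, pc, ptypes, scale), rng)
            e = planted_energy(coords, ct, pc, ptypes, scale)
            if best is None or e < best[2]:
                best = (cand.with_coords(coords, pose_id=0), ct, e)
        native_pose, ntypes, e_nat = best
        e_true = e_nat + rng.normal(scale=spec.sigma_affinity)
        rec = ComplexRecord(target_id=tid, pocket=pocket, ligand=native_pose,
                            set_tag="native", E_true=e_true, R_true=0.0,
                            molecule_id=f"{tid}:lig", pose_id=0)
        world.natives[tid] = rec
        add(rec, e_nat)

    # conformational decoys: rigid perturbations of the native pose
    for tid in target_ids:
        pocket, ptypes = pocket_data[tid]
        native = world.natives[tid]
        ntypes = lig_types(native.ligand)
        for k in range(1, spec.n_conf_decoys + 1):  # native holds pose 0
            rot_full = _random_rotation(rng)
            frac = rng.uniform(0.05, 1.0)
            rot = frac * rot_full + (1 - frac) * np.eye(3)
            u, _, vt = np.linalg.svd(rot)
            rot = u @ vt
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            trans = direction * rng.uniform(0.2, 8.0)
            coords = rigid_transform(native.ligand.coords, rot, trans)
            decoy = native.ligand.with_coords(coords, pose_id=k)
            r_true = structio.ligand_rmsd(native.ligand, decoy)
            rec = ComplexRecord(target_id=tid, pocket=pocket, ligand=decoy,
                                set_tag="conf_decoy", E_true=native.E_true,
                                R_true=r_true, molecule_id=f"{tid}:lig",
                                pose_id=k)
            add(rec, planted_energy(coords, ntypes, pocket.coords, ptypes,
                                    scale))

    # cross decoys: other targets' native ligands, packing-placed
    for ti, tid in enumerate(target_ids):
        pocket, ptypes = pocket_data[tid]
        pc = pocket.coords
        others = [t for t in target_ids if t != tid]
        for k in range(spec.n_cross_decoys):
            src = others[rng.integers(len(others))] if others else tid
            lig = world.natives[src].ligand
            coords = _optimize_pose(lig.coords,
                                    lambda c: packing_score(c, pc), rng,
                                    n_starts=24,
                                    refine_stages=(0.8, 0.3, 0.1),
                                    n_per_stage=25)
            decoy = lig.with_coords(coords, pose_id=k)
            rec = ComplexRecord(target_id=tid, pocket=pocket, ligand=decoy,
                                set_tag="cross_decoy",
                                molecule_id=f"{src}:lig", pose_id=k)
            add(rec, planted_energy(coords, lig_types(decoy), pc, ptypes,
                                    scale))

    # random decoys: fresh unbiased ligands, packing-placed
    for tid in target_ids:
        pocket, ptypes = pocket_data[tid]
        pc = pocket.coords
        for k in range(spec.n_random_decoys):
            lig = random_ligand(rng, spec)
            coords = _optimize_pose(lig.coords,
                                    lambda c: packing_score(c, pc), rng,
                                    n_starts=24,
                                    refine_stages=(0.8, 0.3, 0.1),
                                    n_per_stage=25)
            decoy = lig.with_coords(coords, pose_id=k)
            rec = ComplexRecord(target_id=tid, pocket=pocket, ligand=decoy,
                                set_tag="random_decoy",
                                molecule_id=f"rnd:{tid}:{k}", pose_id=k)
            add(rec, planted_energy(coords, lig_types(decoy), pc, ptypes,
                                    scale))

    if out_dir is not None:
        write_world(world, out_dir)
    return world


def generate_screening_set(world: SyntheticWorld,
                           target_ids: Sequence[str],
                           n_inactives: int, seed: int
                           ) -> Tuple[List[ComplexRecord], Dict[tuple, float]]:
    """A forward-screening task over the given targets: the native pose
    is the single active, plus fresh packing-placed inactive ligands.
    Returns records and their surrogate physics scores."""
    rng = np.random.default_rng(seed)
    records, physics = [], {}
    for tid in target_ids:
        pocket = world.pockets[tid]
        ptypes = _pocket_types(pocket)
        pc = pocket.coords
        native = world.natives[tid]
        records.append(native)
        physics[world.key(native)] = world.truth[world.key(native)].physics_score
        for k in range(n_inactives):
            lig = random_ligand(rng, world.spec)
            coords = _optimize_pose(lig.coords,
                                    lambda c: packing_score(c, pc), rng,
                                    n_starts=24,
                                    refine_stages=(0.8, 0.3, 0.1),
                                    n_per_stage=25)
            decoy = lig.with_coords(coords, pose_id=k)
            rec = ComplexRecord(target_id=tid, pocket=pocket, ligand=decoy,
                                set_tag="random_decoy",
                                molecule_id=f"scr:{tid}:{k}", pose_id=k)
            records.append(rec)
            e = planted_energy(coords, perceive_pharmacophores(decoy.mol),
                               pc, ptypes, world.spec.energy_scale)
            physics[(rec.target_id, rec.molecule_id, rec.pose_id)] = \
                e + rng.normal(scale=world.spec.sigma_physics)
    return records, physics


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_world(world: SyntheticWorld, out_dir) -> None:
    """Write proteins/, ligands/, manifest.tsv and physics.tsv."""
    out = Path(out_dir)
    (out / "proteins").mkdir(parents=True, exist_ok=True)
    (out / "ligands").mkdir(exist_ok=True)
    for tid, pocket in world.pockets.items():
        structio.write_protein(pocket, out / "proteins" / f"{tid}.pdb")
    by_file: Dict[str, list] = {}
    for rec in world.records:
        fname = f"ligands/{rec.target_id}_{rec.set_tag}.sdf"
        by_file.setdefault(fname, []).append(rec)
    manifest_rows, physics_rows = [], []
    for fname, recs in by_file.items():
        recs = sorted(recs, key=lambda r: r.pose_id)
        structio.write_ligand_poses([r.ligand for r in recs], out / fname)
        for idx, rec in enumerate(recs):
            truth = world.truth[world.key(rec)]
            manifest_rows.append({
                "target_id": rec.target_id, "ligand_file": fname,
                "pose_index": idx, "set_tag": rec.set_tag,
                "E_true": "" if rec.E_true is None else rec.E_true,
                "R_true": "" if rec.R_true is None else rec.R_true,
                "molecule_id": rec.molecule_id,
                "protein_file": f"proteins/{rec.target_id}.pdb",
                "pose_id": rec.pose_id})
            physics_rows.append({
                "target_id": rec.target_id, "molecule_id": rec.molecule_id,
                "pose_id": rec.pose_id, "energy": truth.physics_score})
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.tsv", sep="\t",
                                       index=False)
    pd.DataFrame(physics_rows).to_csv(out / "physics.tsv", sep="\t",
                                      index=False)


def world_statistics(world: SyntheticWorld) -> pd.DataFrame:
    """Per-set counts and planted-energy / RMSD summaries."""
    if not world.records:
        return pd.DataFrame()
    rows = []
    for rec in world.records:
        truth = world.truth[world.key(rec)]
        rows.append({"set_tag": rec.set_tag,
                     "planted_energy": truth.planted_energy,
                     "physics_score": truth.physics_score,
                     "R_true": math.nan if rec.R_true is None else rec.R_true})
    df = pd.DataFrame(rows)
    return df.groupby("set_tag").agg(
        count=("set_tag", "size"),
        mean_planted_energy=("planted_energy", "mean"),
        mean_rmsd=("R_true", "mean")).reset_index()
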