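"""Geometric context of a P450 structure for variant classification.

Parses a PDB file (protein chain + heme, optionally a bound substrate) and
exposes the predicates the classifier needs: minimum side-chain distance to
the heme/ligand atoms, a "pointing towards" orientation test, relative
side-chain solvent exposure, and membership in the POR (P450 oxidoreductase)
interaction surface.

The POR core set is the nine charged residues of the canonical redox-partner
interface of microsomal P450s: R124, E140, E320, R341, R356, R366, R369,
R431 and R444 (CYP21A2 numbering).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.SASA import ShrakeRupley

logger = logging.getLogger(__name__)

#: Canonical POR-interface residues (redox-partner docking surface).
POR_CORE_SET = frozenset({124, 140, 320, 341, 356, 366, 369, 431, 444})

#: Backbone heavy-atom names; everything else heavy is side chain.
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: Theoretical maximum accessible surface areas (Å^2), Tien et al. 2013.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


class IncompleteResidueError(ValueError):
    """A geometric predicate was asked about a residue lacking side-chain atoms."""


@dataclass(frozen=True)
class GeometryConfig:
    """Cutoffs for the geometric predicates (all distances in Å).

    ``heme_contact_cutoff``: a residue within this distance of heme/ligand
    atoms (and oriented towards them) is a heme/ligand contact.
    ``orientation_max_angle``: maximum Cα-centred angle (degrees) between the
    side-chain direction and the direction to the nearest heme/ligand atom
    for the residue to count as "pointing towards" it.
    ``por_proximity_cutoff`` / ``exposure_threshold``: a charged (Arg/Glu)
    residue this close to the POR core set, at least this exposed, and on the
    same face, joins the POR interface.
    """

    heme_contact_cutoff: float = 5.0
    por_proximity_cutoff: float = 8.0
    exposure_threshold: float = 0.25
    orientation_max_angle: float = 90.0

    def __post_init__(self) -> None:
        for name in ("heme_contact_cutoff", "por_proximity_cutoff",
                     "exposure_threshold", "orientation_max_angle"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ResidueRecord:
    number: int
    name: str
    atoms: dict  # atom name -> (3,) ndarray, heavy atoms only
    sidechain_atoms: list  # atom names
    incomplete: bool = False

    def sidechain_coords(self) -> np.ndarray:
        """Side-chain heavy-atom coordinates; Cα proxy for glycine."""
        if self.sidechain_atoms:
            return np.array([self.atoms[a] for a in self.sidechain_atoms])
        if self.name == "GLY" and "CA" in self.atoms:
            return self.atoms["CA"][None, :]
        raise IncompleteResidueError(
            f"residue {self.name}{self.number} has no side-chain atoms"
        )

    def sidechain_centroid(self) -> np.ndarray:
        return self.sidechain_coords().mean(axis=0)


@dataclass
class Evidence:
    """Audit trail for one geometric decision."""

    rule: str
    distance: Optional[float] = None
    angle_deg: Optional[float] = None
    nearest_atom: Optional[str] = None
    exposure: Optional[float] = None
    detail: str = ""


@dataclass
class StructureContext:
    residues: dict  # residue number -> ResidueRecord
    heme_atoms: np.ndarray  # (n, 3), possibly empty
    heme_atom_names: list
    ligand_atoms: np.ndarray
    ligand_atom_names: list
    exposure: dict  # residue number -> float in [0, 1]
    por_core_set: frozenset = POR_CORE_SET
    source: str = ""

    def contact_atoms(self) -> tuple[np.ndarray, list]:
        """Union of heme and ligand atoms."""
        parts, names = [], []
        if len(self.heme_atoms):
            parts.append(self.heme_atoms)
            names += [f"HEM:{n}" for n in self.heme_atom_names]
        if len(self.ligand_atoms):
            parts.append(self.ligand_atoms)
            names += [f"LIG:{n}" for n in self.ligand_atom_names]
        if not parts:
            return np.empty((0, 3)), []
        return np.vstack(parts), names

    def center(self) -> np.ndarray:
        """Centre of geometry over all protein heavy atoms."""
        coords = [c for r in self.residues.values() for c in r.atoms.values()]
        return np.array(coords).mean(axis=0)


def _compute_exposure(structure, chain_id: str) -> dict:
    """Relative solvent accessibility per residue, clamped to [0, 1].

    Shrake-Rupley accessible surface of the whole first model (heme and
    ligand included, so atoms they bury count as buried), normalised by the
    theoretical maximum ASA of the residue type.
    """
    sr = ShrakeRupley()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sr.compute(structure[0], level="R")
    exposure = {}
    for residue in structure[0][chain_id]:
        if residue.id[0] != " ":
            continue
        max_asa = MAX_ASA.get(residue.get_resname())
        if max_asa is None:
            continue
        exposure[residue.id[1]] = float(min(1.0, residue.sasa / max_asa))
    return exposure


def load_structure(
    path: Union[str, Path],
    chain: str = "A",
    heme_resnames: frozenset = frozenset({"HEM"}),
    ligand_resnames: frozenset = frozenset(),
) -> StructureContext:
    """Parse a PDB file into a :class:`StructureContext`.

    ATOM records of ``chain`` populate the residue list (heavy atoms only;
    the first model of multi-model files). HETATM records whose residue name
    is in ``heme_resnames`` / ``ligand_resnames`` populate the heme and
    ligand atom sets. A missing heme produces a logged warning and an empty
    set, under which the heme predicates answer False.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ctx", str(path))
    model = structure[0]
    if chain not in [c.id for c in model]:
        raise ValueError(f"chain {chain!r} not present in {path}")

    residues: dict[int, ResidueRecord] = {}
    heme_xyz, heme_names = [], []
    ligand_xyz, ligand_names = [], []
    for ch in model:
        for residue in ch:
            hetflag, resnum, _ = residue.id
            resname = residue.get_resname()
            if hetflag != " ":
                hetname = hetflag.replace("H_", "").strip() or resname
                target = None
                if hetname in heme_resnames or resname in heme_resnames:
                    target = (heme_xyz, heme_names)
                elif hetname in ligand_resnames or resname in ligand_resnames:
                    target = (ligand_xyz, ligand_names)
                if target is not None:
                    for atom in residue:
                        if atom.element != "H":
                            target[0].append(atom.coord.astype(float))
                            target[1].append(atom.get_name())
                continue
            if ch.id != chain:
                continue
            atoms = {
                a.get_name(): a.coord.astype(float)
                for a in residue
                if a.element != "H"
            }
            sidechain = [n for n in atoms if n not in BACKBONE_ATOMS]
            incomplete = not sidechain and resname != "GLY"
            residues[resnum] = ResidueRecord(
                resnum, resname, atoms, sidechain, incomplete
            )
            if incomplete:
                logger.warning(
                    "residue %s%d has no side-chain atoms; geometric "
                    "predicates on it will raise", resname, resnum,
                )
    if not heme_xyz:
        logger.warning("no heme heteroatoms found in %s; heme predicates "
                       "will answer False", path)
    exposure = _compute_exposure(structure, chain)
    return StructureContext(
        residues=residues,
        heme_atoms=np.array(heme_xyz) if heme_xyz else np.empty((0, 3)),
        heme_atom_names=heme_names,
        ligand_atoms=np.array(ligand_xyz) if ligand_xyz else np.empty((0, 3)),
        ligand_atom_names=ligand_names,
        exposure=exposure,
        source=str(path),
    )


def _get_residue(ctx: StructureContext, position: int) -> ResidueRecord:
    try:
        return ctx.residues[position]
    except KeyError:
        raise KeyError(f"residue {position} not present in the structure") from None


def min_sidechain_distance(
    ctx: StructureContext, residue_position: int, atom_set: np.ndarray
) -> float:
    """Minimum heavy-atom distance (Å) from a residue's side chain to ``atom_set``."""
    atom_set = np.asarray(atom_set, dtype=float)
    if atom_set.size == 0:
        raise ValueError("atom_set must be non-empty")
    sc = _get_residue(ctx, residue_position).sidechain_coords()
    diff = sc[:, None, :] - atom_set[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).min())


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def is_heme_or_ligand_contact(
    ctx: StructureContext,
    residue_position: int,
    cfg: GeometryConfig = GeometryConfig(),
) -> tuple[bool, Evidence]:
    """Is the residue within the contact cutoff of heme/ligand and pointing at it?

    "Pointing towards" is the Cα-centred angle between (Cα → side-chain
    centroid) and (Cα → nearest heme/ligand atom) being at most
    ``cfg.orientation_max_angle``. Distance at exactly the cutoff counts as
    contact.
    """
    atoms, names = ctx.contact_atoms()
    if len(atoms) == 0:
        return False, Evidence(rule="no_heme_or_ligand_atoms")
    residue = _get_residue(ctx, residue_position)
    sc = residue.sidechain_coords()
    diff = sc[:, None, :] - atoms[None, :, :]
    dists = np.sqrt((diff ** 2).sum(axis=2))
    distance = float(dists.min())
    nearest_idx = int(np.unravel_index(np.argmin(dists), dists.shape)[1])
    nearest = atoms[nearest_idx]
    if "CA" in residue.atoms:
        ca = residue.atoms["CA"]
        angle = _angle_deg(residue.sidechain_centroid() - ca, nearest - ca)
    else:
        angle = 0.0  # no Cα: orientation test vacuously passes
    hit = distance <= cfg.heme_contact_cutoff and angle <= cfg.orientation_max_angle
    return hit, Evidence(
        rule="heme_or_ligand_contact",
        distance=distance,
        angle_deg=angle,
        nearest_atom=names[nearest_idx],
    )


def is_por_interface(
    ctx: StructureContext,
    residue_position: int,
    residue_name: Optional[str] = None,
    cfg: GeometryConfig = GeometryConfig(),
) -> tuple[bool, Evidence]:
    """Does the residue belong to the POR interaction surface?

    True when the position is one of the nine core interface residues, or
    when a charged residue (Arg/Glu) sits close to the core set (side-chain
    minimum distance <= ``por_proximity_cutoff``), is solvent exposed
    (>= ``exposure_threshold``) and faces outward on the same surface as the
    core set.
    """
    if residue_position in ctx.por_core_set:
        return True, Evidence(rule="por_core", detail="core interface residue")
    residue = ctx.residues.get(residue_position)
    if residue is None:
        return False, Evidence(rule="not_in_structure")
    name = (residue_name or residue.name).upper()
    if name in {"R", "E"}:
        name = {"R": "ARG", "E": "GLU"}[name]
    if name not in {"ARG", "GLU"}:
        return False, Evidence(rule="not_charged", detail=name)
    core = [ctx.residues[p] for p in ctx.por_core_set if p in ctx.residues]
    if not core:
        return False, Evidence(rule="core_set_absent")
    core_coords = np.vstack([r.sidechain_coords() for r in core])
    distance = min_sidechain_distance(ctx, residue_position, core_coords)
    exposure = ctx.exposure.get(residue_position, 0.0)
    center = ctx.center()
    out_vec = residue.sidechain_centroid() - center
    core_out = np.mean([r.sidechain_centroid() - center for r in core], axis=0)
    same_face = float(np.dot(out_vec, core_out)) > 0.0
    hit = (
        distance <= cfg.por_proximity_cutoff
        and exposure >= cfg.exposure_threshold
        and same_face
    )
    return hit, Evidence(
        rule="por_proximal_charged",
        distance=distance,
        exposure=exposure,
        detail=f"same_face={same_face}",
    )
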