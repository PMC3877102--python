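"""Molecular structures, docking poses and the standard-format readers behind them.

Proteins come in as PDB, ligands/poses as SDF, Mol2 or SMILES.  A pose-set
manifest (JSON) groups multi-record pose files by the docking tool that
produced them, so the downstream pipeline never needs to run a docking
engine itself.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException
from rdkit import Chem

from .errors import EmptyStructureError, FormatError, NeedsEmbeddingError

logger = logging.getLogger(__name__)

#: Symbols recognised as chemical elements (subset sufficient for biomolecules
#: and drug-like ligands; extend as needed).
KNOWN_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Mn Fe Co Ni Cu Zn "
    "Ga Ge As Se Br Kr Mo Ru Rh Pd Ag Cd Sn Sb Te I Xe Pt Au Hg Pb".split()
)


@dataclass
class MolecularStructure:
    """Atoms of one molecule or one partner of a complex.

    Coordinates are Å in the frame of the source file (no re-centering);
    atom indexing is 0-based.  ``coords`` is None for connectivity-only
    input (SMILES) that still needs 3D embedding.
    """

    id: str
    elements: list[str]
    coords: np.ndarray | None  # (n, 3) float64, Å
    is_hetero: np.ndarray | None = None  # bool mask: waters + HETATM records
    role: str = "ligand"  # "protein" | "ligand"
    needs_embedding: bool = False
    mol: "Chem.Mol | None" = field(default=None, repr=False)  # RDKit mol for ligands

    def __post_init__(self) -> None:
        if len(self.elements) == 0:
            raise EmptyStructureError(f"structure {self.id!r} has no atoms")
        for sym in self.elements:
            if sym not in KNOWN_ELEMENTS:
                raise FormatError(f"structure {self.id!r}: unrecognized element {sym!r}")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (len(self.elements), 3):
                raise FormatError(
                    f"structure {self.id!r}: coords shape {self.coords.shape} "
                    f"!= ({len(self.elements)}, 3)"
                )
            if not np.all(np.isfinite(self.coords)):
                raise FormatError(f"structure {self.id!r}: non-finite coordinates")
        if self.is_hetero is None:
            self.is_hetero = np.zeros(len(self.elements), dtype=bool)
        else:
            self.is_hetero = np.asarray(self.is_hetero, dtype=bool)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def require_coords(self) -> np.ndarray:
        if self.coords is None or self.needs_embedding:
            raise NeedsEmbeddingError(
                f"structure {self.id!r} has no 3D coordinates; embed it before "
                "pose-dependent operations"
            )
        return self.coords

    def polymer_view(self) -> "MolecularStructure":
        """Drop waters and hetero atoms: the polymer side used for contact counting."""
        keep = ~self.is_hetero
        if not keep.any():
            raise EmptyStructureError(f"structure {self.id!r}: no polymer atoms remain")
        return MolecularStructure(
            id=self.id,
            elements=[e for e, k in zip(self.elements, keep) if k],
            coords=None if self.coords is None else self.coords[keep],
            is_hetero=np.zeros(int(keep.sum()), dtype=bool),
            role=self.role,
        )


@dataclass
class Pose:
    """One ligand binding mode: a conformer plus its provenance."""

    ligand: MolecularStructure
    tool: str
    native_score: float | None = None
    rank_in_tool: int = 1

    def __post_init__(self) -> None:
        if self.ligand.role != "ligand":
            raise ValueError(f"pose ligand role must be 'ligand', got {self.ligand.role!r}")
        if self.rank_in_tool < 1:
            raise ValueError(f"rank_in_tool must be >= 1, got {self.rank_in_tool}")


# ---------------------------------------------------------------------------
# PDB proteins
# ---------------------------------------------------------------------------

_PDB_NAME_ELEMENTS = sorted(KNOWN_ELEMENTS, key=len, reverse=True)


def _element_from_atom_name(name: str) -> str | None:
    """Heuristic used when the PDB element column is blank (pre-v3 files)."""
    stripped = name.strip().lstrip("0123456789")
    for sym in (stripped[:2].capitalize(), stripped[:1].upper()):
        if sym in KNOWN_ELEMENTS:
            return sym
    return None


def read_protein(path: str | Path) -> MolecularStructure:
    """Read a PDB file as the protein partner of a complex.

    Hydrogens are retained; water and HETATM records are kept but flagged
    ``is_hetero`` so featurization can exclude them explicitly rather than
    silently.  Only altloc A (or blank) is kept.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc

    elements: list[str] = []
    coords: list[tuple[float, float, float]] = []
    hetero: list[bool] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                het_flag = residue.id[0].strip() != ""  # "W" for water, "H_xxx" for hetero
                for atom in residue:
                    if atom.get_altloc() not in (" ", "A"):
                        logger.debug("dropping altloc %r of %s", atom.get_altloc(), atom)
                        continue
                    sym = (atom.element or "").strip().capitalize()
                    if sym not in KNOWN_ELEMENTS:
                        sym = _element_from_atom_name(atom.get_name()) or ""
                        if sym:
                            logger.info(
                                "element column missing for atom %r in %s; "
                                "inferred %s from atom name",
                                atom.get_name(), path.name, sym,
                            )
                    if sym not in KNOWN_ELEMENTS:
                        raise FormatError(
                            f"{path}: cannot assign an element to atom record "
                            f"{atom.get_name()!r} in residue {residue.get_resname()!r}"
                        )
                    elements.append(sym)
                    coords.append(tuple(atom.coord))
                    hetero.append(het_flag)
        break  # first model only

    if not elements:
        raise EmptyStructureError(f"{path}: no atoms parsed")
    return MolecularStructure(
        id=path.stem,
        elements=elements,
        coords=np.asarray(coords, dtype=float),
        is_hetero=np.asarray(hetero, dtype=bool),
        role="protein",
    )


# ---------------------------------------------------------------------------
# Ligands: SDF / Mol2 / SMILES
# ---------------------------------------------------------------------------


def _structure_from_mol(mol: Chem.Mol, mol_id: str, needs_embedding: bool) -> MolecularStructure:
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    coords = None
    if not needs_embedding and mol.GetNumConformers() > 0:
        coords = np.asarray(mol.GetConformer().GetPositions(), dtype=float)
    return MolecularStructure(
        id=mol_id,
        elements=elements,
        coords=coords,
        role="ligand",
        needs_embedding=needs_embedding or coords is None,
        mol=mol,
    )


def split_mol2_blocks(text: str) -> list[str]:
    """Split a multi-record Mol2 file into per-molecule blocks."""
    marker = "@<TRIPOS>MOLECULE"
    parts = text.split(marker)
    return [marker + p for p in parts[1:]]


def read_ligands(path: str | Path, fmt: str) -> list[MolecularStructure]:
    """Read every record of an SDF/Mol2 file (ordered), or one SMILES.

    SMILES yields a connectivity-only structure flagged ``needs_embedding``;
    pose-dependent stages will refuse it rather than silently embed.
    """
    path = Path(path)
    fmt = fmt.lower()
    out: list[MolecularStructure] = []
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                raise FormatError(f"{path}: SDF record {i} failed to parse")
            out.append(_structure_from_mol(mol, mol.GetProp("_Name") or f"{path.stem}:{i}", False))
    elif fmt == "mol2":
        blocks = split_mol2_blocks(path.read_text())
        if not blocks:
            raise FormatError(f"{path}: no @<TRIPOS>MOLECULE records found")
        for i, block in enumerate(blocks):
            mol = Chem.MolFromMol2Block(block, removeHs=False, sanitize=True)
            if mol is None:
                raise FormatError(f"{path}: Mol2 record {i} failed to parse")
            out.append(_structure_from_mol(mol, f"{path.stem}:{i}", False))
    elif fmt == "smiles":
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            mol = Chem.MolFromSmiles(fields[0])
            if mol is None:
                raise FormatError(f"{path}: SMILES on line {i + 1} failed to parse")
            name = fields[1] if len(fields) > 1 else f"{path.stem}:{i}"
            out.append(_structure_from_mol(mol, name, needs_embedding=True))
    else:
        raise ValueError(f"unsupported ligand format {fmt!r}")
    if not out:
        raise EmptyStructureError(f"{path}: no molecules read")
    return out


def read_ligand(path: str | Path, fmt: str) -> MolecularStructure:
    """First (or only) record of a ligand file; see :func:`read_ligands`."""
    return read_ligands(path, fmt)[0]


def ligand_from_smiles(smiles: str, mol_id: str = "ligand") -> MolecularStructure:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FormatError(f"SMILES {smiles!r} failed to parse")
    return _structure_from_mol(mol, mol_id, needs_embedding=True)


# ---------------------------------------------------------------------------
# Pose-set manifests
# ---------------------------------------------------------------------------


@dataclass
class PoseSetManifest:
    """Points at a protein file and one pose file per docking tool.

    The binding site is either an explicit sphere (center + radius) or
    derived from the native ligand; it is carried as metadata, docking
    itself being out of scope.
    """

    protein_path: Path
    tool_files: dict[str, tuple[Path, str]]  # tool -> (path, format)
    binding_site: dict | None = None

    def __post_init__(self) -> None:
        if not self.tool_files:
            raise ValueError("manifest must reference at least one docking tool")

    @classmethod
    def from_json(cls, path: str | Path) -> "PoseSetManifest":
        path = Path(path)
        doc = json.loads(path.read_text())
        base = path.parent
        tools = {
            tool: (base / spec["path"], spec.get("format", "sdf"))
            for tool, spec in doc["tools"].items()
        }
        return cls(
            protein_path=base / doc["protein"],
            tool_files=tools,
            binding_site=doc.get("binding_site"),
        )


@dataclass
class PoseSet:
    """Poses grouped by tool, each list ordered by rank; absent tools listed."""

    poses: dict[str, list[Pose]]
    absent_tools: list[str]

    @property
    def n_poses(self) -> int:
        return sum(len(v) for v in self.poses.values())


def _pose_metadata(struct: MolecularStructure, default_rank: int) -> tuple[int, float | None]:
    """Rank and native score from SDF properties when present, else file order."""
    rank, score = default_rank, None
    mol = struct.mol
    if mol is not None:
        if mol.HasProp("rank_in_tool"):
            rank = int(mol.GetProp("rank_in_tool"))
        if mol.HasProp("native_score"):
            score = float(mol.GetProp("native_score"))
    return rank, score


def read_pose_set(manifest: PoseSetManifest) -> PoseSet:
    """Load every tool's poses, sorted by rank_in_tool regardless of file layout.

    A tool whose file is missing is reported in ``absent_tools``, not
    returned as an empty list.
    """
    poses: dict[str, list[Pose]] = {}
    absent: list[str] = []
    for tool, (path, fmt) in manifest.tool_files.items():
        if not Path(path).exists():
            logger.warning("pose file for tool %s missing: %s", tool, path)
            absent.append(tool)
            continue
        structs = read_ligands(path, fmt)
        tool_poses = []
        for i, struct in enumerate(structs):
            rank, score = _pose_metadata(struct, default_rank=i + 1)
            tool_poses.append(Pose(ligand=struct, tool=tool, native_score=score, rank_in_tool=rank))
        tool_poses.sort(key=lambda p: p.rank_in_tool)
        poses[tool] = tool_poses
    return PoseSet(poses=poses, absent_tools=absent)


# ---------------------------------------------------------------------------
# Plain-text writers (used by the synthetic-fixture generator and tests)
# ---------------------------------------------------------------------------


def write_pdb(struct: MolecularStructure, path: str | Path) -> None:
    """Write a minimal PDB file (ATOM/HETATM records, single chain)."""
    coords = struct.require_coords()
    lines = []
    for i, (sym, (x, y, z), het) in enumerate(
        zip(struct.elements, coords, struct.is_hetero), start=1
    ):
        record = "HETATM" if het else "ATOM"
        resname = "HOH" if het else "GLY"
        name = sym.upper()
        lines.append(
            f"{record:<6s}{i:5d} {name:^4s} {resname:>3s} A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {sym.upper():>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_poses_sdf(poses: Sequence[Pose], path: str | Path) -> None:
    """Write poses as a multi-record SDF with rank/score carried as properties."""
    writer = Chem.SDWriter(str(path))
    try:
        for pose in poses:
            mol = pose.ligand.mol
            if mol is None:
                mol = _point_cloud_to_mol(pose.ligand)
            mol = Chem.Mol(mol)
            mol.SetProp("rank_in_tool", str(pose.rank_in_tool))
            if pose.native_score is not None:
                mol.SetProp("native_score", repr(pose.native_score))
            writer.write(mol)
    finally:
        writer.close()


def _point_cloud_to_mol(struct: MolecularStructure) -> Chem.Mol:
    """Bond-less RDKit mol from an element-labelled point cloud."""
    coords = struct.require_coords()
    rw = Chem.RWMol()
    for sym in struct.elements:
        atom = Chem.Atom(sym)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    conf = Chem.Conformer(len(struct.elements))
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
    mol = rw.GetMol()
    mol.AddConformer(conf)
    mol.SetProp("_Name", struct.id)
    return mol
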