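"""Molecule model, structure I/O, partial charges and template alignment.

Field-based 3D QSAR assumes a congeneric series: compounds sharing a common
scaffold, rigidly superposed on a reference so that grid points are comparable
across the set.  This module provides the :class:`Molecule` container used by
every downstream stage, readers for SMILES/SDF and activity tables,
Gasteiger-Marsili (PEOE) charge assignment, least-squares template alignment
and RMSD-based congener selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.rdPartialCharges import ComputeGasteigerCharges

logger = logging.getLogger(__name__)

DEFAULT_EMBED_SEED = 42
DEFAULT_MINIMIZE_ITERATIONS = 500
DEFAULT_PEOE_ITERATIONS = 6
DEFAULT_RMSD_CUTOFF = 1.0  # Angstrom


class MoleculeError(ValueError):
    """Raised for unreadable or chemically invalid molecule input."""


@dataclass
class Molecule:
    """A small molecule with a single 3D conformer.

    Wraps an RDKit molecule (which owns elements, bonds, formal charges and
    coordinates) and adds a stable identifier plus, once assigned, PEOE
    partial charges in elementary-charge units aligned with atom order.
    """

    id: str
    rdmol: Chem.Mol
    partial_charges: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.rdmol.GetNumConformers() == 0:
            raise MoleculeError(f"molecule {self.id!r} has no 3D conformer")
        coords = self.coords
        if not np.all(np.isfinite(coords)):
            raise MoleculeError(f"molecule {self.id!r} has non-finite coordinates")
        if self.partial_charges is not None:
            self.partial_charges = np.asarray(self.partial_charges, dtype=float)
            if len(self.partial_charges) != self.num_atoms:
                raise MoleculeError(
                    f"molecule {self.id!r}: {len(self.partial_charges)} charges "
                    f"for {self.num_atoms} atoms"
                )
            net = float(self.partial_charges.sum())
            formal = float(Chem.GetFormalCharge(self.rdmol))
            if abs(net - formal) > 1e-3:
                raise MoleculeError(
                    f"molecule {self.id!r}: charges sum to {net:.5f}, "
                    f"formal charge is {formal:g}"
                )

    # -- views -------------------------------------------------------------
    @property
    def num_atoms(self) -> int:
        return self.rdmol.GetNumAtoms()

    @property
    def elements(self) -> list[str]:
        return [a.GetSymbol() for a in self.rdmol.GetAtoms()]

    @property
    def coords(self) -> np.ndarray:
        """Atom coordinates in Angstrom, shape (n_atoms, 3)."""
        return np.array(self.rdmol.GetConformer().GetPositions(), dtype=float)

    @property
    def bonds(self) -> list[tuple[int, int, float]]:
        return [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in self.rdmol.GetBonds()
        ]

    @property
    def formal_charges(self) -> list[int]:
        return [a.GetFormalCharge() for a in self.rdmol.GetAtoms()]

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        """Return a copy with replaced atomic coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.num_atoms, 3):
            raise MoleculeError("coordinate array shape mismatch")
        mol = Chem.Mol(self.rdmol)
        conf = mol.GetConformer()
        for i, xyz in enumerate(coords):
            conf.SetAtomPosition(i, [float(x) for x in xyz])
        return Molecule(self.id, mol, None if self.partial_charges is None
                        else self.partial_charges.copy())

    def copy(self) -> "Molecule":
        return Molecule(self.id, Chem.Mol(self.rdmol),
                        None if self.partial_charges is None
                        else self.partial_charges.copy())


@dataclass(frozen=True)
class ActivityRecord:
    """Measured inhibitory potency of one compound.

    ``pic50`` is -log10 of the IC50 in molar units; higher means more potent.
    """

    compound_id: str
    pic50: float
    ic50: float | None = None

    def __post_init__(self) -> None:
        if self.ic50 is not None:
            implied = -math.log10(self.ic50)
            if abs(implied - self.pic50) > 1e-6:
                raise ValueError(
                    f"{self.compound_id}: pIC50 {self.pic50} inconsistent with "
                    f"IC50 {self.ic50} M (implies {implied:.6f})"
                )

    @classmethod
    def from_ic50(cls, compound_id: str, ic50_molar: float) -> "ActivityRecord":
        if ic50_molar <= 0:
            raise ValueError(f"{compound_id}: IC50 must be positive")
        return cls(compound_id, -math.log10(ic50_molar), ic50_molar)


@dataclass
class AlignmentResult:
    """Outcome of superposing a molecule's template atoms onto a reference."""

    molecule: Molecule | None
    template_match: list[tuple[int, int]] | None
    rmsd: float
    matched: bool = True

    @classmethod
    def no_match(cls, mol: Molecule) -> "AlignmentResult":
        res = cls(molecule=None, template_match=None, rmsd=math.inf, matched=False)
        res.source_id = mol.id
        return res


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _embed_3d(mol: Chem.Mol, seed: int, minimize_iterations: int) -> Chem.Mol:
    """Deterministic single-conformer 3D embedding (ETKDG) + MMFF relaxation."""
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    if AllChem.EmbedMolecule(molh, params) != 0:
        # fall back to random coordinates, still seeded
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(molh, params) != 0:
            raise MoleculeError("3D embedding failed")
    if minimize_iterations > 0:
        try:
            AllChem.MMFFOptimizeMolecule(molh, maxIters=int(minimize_iterations))
        except Exception:  # pragma: no cover - MMFF missing parameters
            AllChem.UFFOptimizeMolecule(molh, maxIters=int(minimize_iterations))
    return Chem.RemoveHs(molh)


def read_molecules(
    path: str | Path,
    fmt: str | None = None,
    *,
    embed_seed: int = DEFAULT_EMBED_SEED,
    minimize_iterations: int = DEFAULT_MINIMIZE_ITERATIONS,
) -> list[Molecule]:
    """Read molecules from a SMILES (.smi, one per line, optional tab-separated
    id) or SDF V2000 file.

    SMILES records are embedded in 3D with a deterministic seed and relaxed
    with MMFF for a fixed iteration cap, so repeated reads give identical
    coordinates.  Ids come from the record name (SDF title / second SMILES
    column) or are generated as ``mol_<i>``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() in {".sdf", ".mol", ".sd"} else "smiles"
    fmt = fmt.lower()
    mols: list[Molecule] = []
    if fmt == "smiles":
        lines = [ln.strip() for ln in path.read_text().splitlines()]
        records = [ln for ln in lines if ln and not ln.startswith("#")]
        if not records:
            raise MoleculeError(f"{path}: no SMILES records")
        for i, rec in enumerate(records):
            parts = rec.split(None, 1) if "\t" not in rec else rec.split("\t")
            smi = parts[0].strip()
            name = parts[1].strip() if len(parts) > 1 and parts[1].strip() else f"mol_{i}"
            rd = Chem.MolFromSmiles(smi)
            if rd is None:
                raise MoleculeError(f"{path}: unparsable SMILES at record {i}: {smi!r}")
            rd = _embed_3d(rd, embed_seed + i, minimize_iterations)
            mols.append(Molecule(name, rd))
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        n = len(supplier)
        if n == 0:
            raise MoleculeError(f"{path}: empty SDF")
        for i in range(n):
            rd = supplier[i]
            if rd is None:
                raise MoleculeError(f"{path}: unparsable SDF record {i}")
            name = rd.GetProp("_Name").strip() if rd.HasProp("_Name") else ""
            if rd.GetNumConformers() == 0 or not rd.GetConformer().Is3D():
                rd = _embed_3d(rd, embed_seed + i, minimize_iterations)
            mols.append(Molecule(name or f"mol_{i}", rd))
    else:
        raise ValueError(f"unsupported format {fmt!r} (use 'smiles' or 'sdf')")
    return mols


def molecule_from_smiles(
    smiles: str,
    mol_id: str = "mol_0",
    *,
    embed_seed: int = DEFAULT_EMBED_SEED,
    minimize_iterations: int = DEFAULT_MINIMIZE_ITERATIONS,
) -> Molecule:
    """Parse one SMILES string and embed a deterministic 3D conformer."""
    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise MoleculeError(f"unparsable SMILES: {smiles!r}")
    return Molecule(mol_id, _embed_3d(rd, embed_seed, minimize_iterations))


def write_sdf(mols: Iterable[Molecule], path: str | Path) -> None:
    """Write molecules (with conformers and any charges) as SDF V2000."""
    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    for m in mols:
        rd = Chem.Mol(m.rdmol)
        rd.SetProp("_Name", m.id)
        if m.partial_charges is not None:
            rd.SetProp("partial_charges",
                       " ".join(f"{q:.6f}" for q in m.partial_charges))
        writer.write(rd)
    writer.close()


def read_activities(path: str | Path) -> list[ActivityRecord]:
    """Read an activity CSV with header ``compound_id,ic50_nM`` or
    ``compound_id,pic50``."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "compound_id" not in cols:
        raise ValueError(f"{path}: missing 'compound_id' column")
    records: list[ActivityRecord] = []
    for _, row in df.iterrows():
        cid = str(row[cols["compound_id"]])
        if "pic50" in cols and not np.isnan(row[cols["pic50"]]):
            records.append(ActivityRecord(cid, float(row[cols["pic50"]])))
        elif "ic50_nm" in cols:
            records.append(ActivityRecord.from_ic50(cid, float(row[cols["ic50_nm"]]) * 1e-9))
        else:
            raise ValueError(f"{path}: need a 'pic50' or 'ic50_nM' column")
    return records


# ---------------------------------------------------------------------------
# PEOE charges
# ---------------------------------------------------------------------------

def assign_peoe_charges(mol: Molecule, iterations: int = DEFAULT_PEOE_ITERATIONS) -> Molecule:
    """Assign Gasteiger-Marsili PEOE partial charges.

    Hydrogens are made explicit first (with coordinates), so the returned
    molecule carries all atoms that later enter the field grid.  The PEOE
    scheme equalises orbital electronegativities iteratively with a geometric
    damping factor of (1/2)^n per iteration.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rd = Chem.AddHs(Chem.Mol(mol.rdmol), addCoords=True)
    try:
        ComputeGasteigerCharges(rd, nIter=int(iterations), throwOnParamFailure=True)
    except ValueError as exc:
        raise ValueError(f"molecule {mol.id!r}: {exc}") from exc
    charges = np.array(
        [a.GetDoubleProp("_GasteigerCharge") + a.GetDoubleProp("_GasteigerHCharge")
         for a in rd.GetAtoms()],
        dtype=float,
    )
    if not np.all(np.isfinite(charges)):
        raise ValueError(f"molecule {mol.id!r}: non-finite PEOE charges")
    return Molecule(mol.id, rd, charges)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def kabsch(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``moving`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``moving @ rotation.T + translation`` best fits ``target``.
    Proper rotation enforced (no reflection).
    """
    moving = np.asarray(moving, float)
    target = np.asarray(target, float)
    if moving.shape != target.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    mc = moving.mean(axis=0)
    tc = target.mean(axis=0)
    H = (moving - mc).T @ (target - tc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    moved = moving @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return R, t, rmsd


def _as_query(template: str | Chem.Mol) -> Chem.Mol:
    if isinstance(template, Chem.Mol):
        return template
    q = Chem.MolFromSmarts(template)
    if q is None or q.GetNumAtoms() == 0:
        q = Chem.MolFromSmiles(template)
    if q is None:
        raise ValueError(f"unparsable template pattern: {template!r}")
    return q


def align_to_template(
    mol: Molecule,
    template: str | Chem.Mol,
    reference: Molecule,
) -> AlignmentResult:
    """Rigidly superpose ``mol``'s template atoms onto the reference's.

    Among all substructure matches of the template in ``mol`` the one giving
    the lowest post-superposition RMSD is kept; the rigid transform is applied
    to the whole molecule.  A molecule that does not contain the template
    yields an explicit no-match result rather than an exception.
    """
    query = _as_query(template)
    ref_matches = reference.rdmol.GetSubstructMatches(query, uniquify=True)
    if not ref_matches:
        raise ValueError(f"reference {reference.id!r} does not match the template")
    ref_idx = list(ref_matches[0])
    ref_coords = reference.coords[ref_idx]

    matches = mol.rdmol.GetSubstructMatches(query, uniquify=True, maxMatches=64)
    if not matches:
        return AlignmentResult.no_match(mol)

    best: tuple[float, np.ndarray, np.ndarray, tuple[int, ...]] | None = None
    coords = mol.coords
    for match in matches:
        R, t, rmsd = kabsch(coords[list(match)], ref_coords)
        if best is None or rmsd < best[0] - 1e-12:
            best = (rmsd, R, t, match)
    rmsd, R, t, match = best  # type: ignore[misc]
    aligned = mol.with_coords(coords @ R.T + t)
    pairs = list(zip(match, ref_idx))
    return AlignmentResult(molecule=aligned, template_match=pairs, rmsd=rmsd)


def select_congeners(
    mols: Sequence[Molecule],
    template: str | Chem.Mol,
    reference: Molecule,
    rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF,
) -> list[AlignmentResult]:
    """Align a candidate set to the reference and keep congeners whose
    template RMSD is within the cutoff, sorted ascending by RMSD.

    Molecules lacking the template core are excluded and logged.
    """
    if rmsd_cutoff <= 0:
        raise ValueError("rmsd_cutoff must be > 0")
    survivors: list[AlignmentResult] = []
    for mol in mols:
        res = align_to_template(mol, template, reference)
        if not res.matched:
            logger.info("congener selection: %s does not match the template", mol.id)
            continue
        if res.rmsd <= rmsd_cutoff:
            survivors.append(res)
        else:
            logger.info("congener selection: %s rejected (RMSD %.3f > %.3f)",
                        mol.id, res.rmsd, rmsd_cutoff)
    if not survivors:
        raise ValueError(
            f"no molecules within RMSD cutoff {rmsd_cutoff} of the reference; "
            "consider increasing the cutoff"
        )
    survivors.sort(key=lambda r: r.rmsd)
    return survivors
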