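"""CoMFA-style probe-interaction fields on a rectangular grid.

For each aligned molecule, three interaction energies are evaluated at every
grid point with an sp3-carbon probe of charge +1 e:

* steric: Lennard-Jones 6-12 against a per-element parameter table,
* electrostatic: Coulomb, ``332.063 q_i q_probe / (eps * r)`` kcal/mol with a
  constant dielectric (default 1.0),
* hydrophobic: Gaussian-damped Crippen atomic hydrophobicity contributions.

Steric and electrostatic energies are truncated to +/- 30 kcal/mol (the usual
CoMFA convention) so that points inside atoms stay finite.  Columns are named
``S_<i>``, ``E_<i>``, ``H_<i>`` by linear grid index; the descriptor matrix
orders all steric columns first, then electrostatic, then hydrophobic.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit.Chem import rdMolDescriptors

from .chem import ActivityRecord, Molecule

logger = logging.getLogger(__name__)

COULOMB_CONSTANT = 332.063  # kcal mol^-1 A e^-2
DEFAULT_CUTOFF = 30.0  # kcal/mol truncation for steric and electrostatic
DEFAULT_DIELECTRIC = 1.0
DEFAULT_MARGIN = 5.0  # A
DEFAULT_SPACING = 2.0  # A
DEFAULT_HYDRO_SIGMA = 1.5  # A, Gaussian damping width of the hydrophobic field

#: Lennard-Jones parameters per element: (r_min/2 in A, epsilon in kcal/mol).
#: Tripos-style values adequate for organic ligands.
VDW_PARAMS: dict[str, tuple[float, float]] = {
    "H": (1.50, 0.042),
    "C": (1.70, 0.107),
    "N": (1.55, 0.095),
    "O": (1.52, 0.116),
    "F": (1.47, 0.109),
    "P": (1.80, 0.314),
    "S": (1.80, 0.314),
    "Cl": (1.75, 0.314),
    "Br": (1.85, 0.434),
    "I": (1.98, 0.623),
}

FIELD_PREFIXES = {"steric": "S", "electrostatic": "E", "hydrophobic": "H"}
FIELD_ORDER = ("steric", "electrostatic", "hydrophobic")


@dataclass(frozen=True)
class ProbeParameters:
    """Interaction probe: sp3 carbon with unit positive charge by default."""

    element: str = "C"
    charge: float = 1.0

    @property
    def lj(self) -> tuple[float, float]:
        return VDW_PARAMS[self.element]


DEFAULT_PROBE = ProbeParameters()


@dataclass(frozen=True)
class GridSpec:
    """Rectangular grid: origin corner, uniform spacing, point counts."""

    origin: tuple[float, float, float]
    spacing: float
    counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if any(c < 1 for c in self.counts):
            raise ValueError("counts must be >= 1")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.counts
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All grid points, shape (n_points, 3), in linear-index order
        (x slowest, z fastest: ``idx = (ix*ny + iy)*nz + iz``)."""
        nx, ny, nz = self.counts
        ax = np.arange(nx) * self.spacing + self.origin[0]
        ay = np.arange(ny) * self.spacing + self.origin[1]
        az = np.arange(nz) * self.spacing + self.origin[2]
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def point(self, index: int) -> np.ndarray:
        nx, ny, nz = self.counts
        if not 0 <= index < self.n_points:
            raise IndexError(f"grid index {index} out of range")
        ix, rem = divmod(index, ny * nz)
        iy, iz = divmod(rem, nz)
        return np.array(self.origin) + self.spacing * np.array([ix, iy, iz])

    def to_json(self) -> str:
        return json.dumps({"origin": list(self.origin), "spacing": self.spacing,
                           "counts": list(self.counts)})

    @classmethod
    def from_json(cls, text: str) -> "GridSpec":
        d = json.loads(text)
        return cls(tuple(d["origin"]), float(d["spacing"]), tuple(d["counts"]))


_NAME_RE = re.compile(r"^([SEH])_(\d+)$")
_PREFIX_TO_TYPE = {v: k for k, v in FIELD_PREFIXES.items()}


def parse_descriptor_name(name: str) -> tuple[str, int]:
    """``"E_86" -> ("electrostatic", 86)``."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"not a field descriptor name: {name!r}")
    return _PREFIX_TO_TYPE[m.group(1)], int(m.group(2))


@dataclass(frozen=True)
class FieldDescriptor:
    """One grid-field descriptor: a field type evaluated at one grid point."""

    name: str
    field_type: str
    grid_point: tuple[float, float, float]

    def __post_init__(self) -> None:
        ftype, _ = parse_descriptor_name(self.name)
        if ftype != self.field_type:
            raise ValueError(f"name {self.name!r} does not encode {self.field_type!r}")


@dataclass
class DescriptorMatrix:
    """Compounds x grid-field descriptors, with aligned activities.

    ``X`` is indexed by compound id with descriptor-name columns (kcal/mol);
    ``y`` holds pIC50 values on the same index.
    """

    X: pd.DataFrame
    y: pd.Series
    descriptors: list[FieldDescriptor] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValueError("activities not aligned with compound ids")
        if self.descriptors and len(self.descriptors) != self.X.shape[1]:
            raise ValueError("descriptor metadata does not match matrix width")
        if not np.all(np.isfinite(self.X.to_numpy())):
            raise ValueError("descriptor matrix contains non-finite values")

    @property
    def compound_ids(self) -> list[str]:
        return list(self.X.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, ids: Sequence[str]) -> "DescriptorMatrix":
        missing = [i for i in ids if i not in self.X.index]
        if missing:
            raise KeyError(f"unknown compound ids: {missing}")
        return DescriptorMatrix(self.X.loc[list(ids)], self.y.loc[list(ids)],
                                self.descriptors)

    def to_csv(self, path: str | Path) -> None:
        out = self.X.copy()
        out.insert(0, "pic50", self.y)
        out.index.name = "compound_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DescriptorMatrix":
        df = pd.read_csv(path, index_col="compound_id")
        y = df.pop("pic50")
        return cls(df, y)


# ---------------------------------------------------------------------------
# Grid construction and field evaluation
# ---------------------------------------------------------------------------

def build_grid(
    aligned: Sequence[Molecule],
    margin: float = DEFAULT_MARGIN,
    spacing: float = DEFAULT_SPACING,
) -> GridSpec:
    """Grid covering the union bounding box of all atoms, extended by
    ``margin`` on every side; counts per axis are ``ceil(extent/spacing)+1``."""
    if not aligned:
        raise ValueError("need at least one molecule to build a grid")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    coords = np.vstack([m.coords for m in aligned])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    extent = hi - lo
    counts = tuple(int(np.ceil(e / spacing)) + 1 for e in extent)
    return GridSpec(tuple(float(v) for v in lo), float(spacing), counts)


def compute_fields(
    mol: Molecule,
    grid: GridSpec,
    probe: ProbeParameters = DEFAULT_PROBE,
    *,
    dielectric: float = DEFAULT_DIELECTRIC,
    cutoff: float = DEFAULT_CUTOFF,
    hydro_sigma: float = DEFAULT_HYDRO_SIGMA,
    points: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Evaluate steric, electrostatic and hydrophobic fields of one molecule.

    Returns arrays of length ``grid.n_points`` (or ``len(points)`` when an
    explicit point subset is given) keyed by field type.
    """
    if mol.partial_charges is None:
        raise ValueError(f"molecule {mol.id!r} has no partial charges; "
                         "run assign_peoe_charges first")
    pts = grid.points() if points is None else np.asarray(points, float)
    coords = mol.coords
    elements = mol.elements
    unknown = sorted({e for e in elements if e not in VDW_PARAMS})
    if unknown:
        raise ValueError(f"no Lennard-Jones parameters for element(s): {unknown}")

    # pairwise distances (n_points, n_atoms); floor avoids division blow-up,
    # truncation below caps the energies anyway
    diff = pts[:, None, :] - coords[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=2))
    r = np.maximum(r, 1e-6)

    rp, ep = probe.lj
    rmin = np.array([VDW_PARAMS[e][0] for e in elements]) + rp
    eps = np.sqrt(np.array([VDW_PARAMS[e][1] for e in elements]) * ep)
    ratio6 = (rmin[None, :] / r) ** 6
    steric = np.sum(eps[None, :] * (ratio6 * ratio6 - 2.0 * ratio6), axis=1)

    electro = COULOMB_CONSTANT * probe.charge * np.sum(
        mol.partial_charges[None, :] / r, axis=1) / dielectric

    logp = np.array([c[0] for c in rdMolDescriptors._CalcCrippenContribs(mol.rdmol)])
    hydro = np.sum(logp[None, :] * np.exp(-(r * r) / (2.0 * hydro_sigma ** 2)), axis=1)

    steric = np.clip(steric, -cutoff, cutoff)
    electro = np.clip(electro, -cutoff, cutoff)
    hydro = np.clip(hydro, -cutoff, cutoff)
    return {"steric": steric, "electrostatic": electro, "hydrophobic": hydro}


def grid_descriptors(grid: GridSpec) -> list[FieldDescriptor]:
    """All descriptors of a grid in canonical column order (S, then E, then H,
    each by ascending linear grid index)."""
    pts = grid.points()
    out: list[FieldDescriptor] = []
    for ftype in FIELD_ORDER:
        prefix = FIELD_PREFIXES[ftype]
        for i in range(grid.n_points):
            out.append(FieldDescriptor(f"{prefix}_{i}", ftype,
                                       tuple(float(v) for v in pts[i])))
    return out


def assemble_descriptor_matrix(
    aligned: Sequence[Molecule],
    activities: Sequence[ActivityRecord],
    grid: GridSpec,
    probe: ProbeParameters = DEFAULT_PROBE,
    *,
    dielectric: float = DEFAULT_DIELECTRIC,
    cutoff: float = DEFAULT_CUTOFF,
    hydro_sigma: float = DEFAULT_HYDRO_SIGMA,
) -> DescriptorMatrix:
    """Evaluate all three fields for every molecule and stack them into a
    compounds x descriptors matrix with aligned pIC50 values."""
    act = {a.compound_id: a.pic50 for a in activities}
    missing = [m.id for m in aligned if m.id not in act]
    if missing:
        raise ValueError(f"no activity record for compound(s): {missing}")
    rows = []
    for m in aligned:
        f = compute_fields(m, grid, probe, dielectric=dielectric,
                           cutoff=cutoff, hydro_sigma=hydro_sigma)
        rows.append(np.concatenate([f[ftype] for ftype in FIELD_ORDER]))
    descriptors = grid_descriptors(grid)
    X = pd.DataFrame(np.vstack(rows), index=[m.id for m in aligned],
                     columns=[d.name for d in descriptors])
    y = pd.Series([act[m.id] for m in aligned], index=X.index, name="pic50")
    return DescriptorMatrix(X, y, descriptors)


def compute_descriptor_values(
    mol: Molecule,
    grid: GridSpec,
    names: Sequence[str],
    probe: ProbeParameters = DEFAULT_PROBE,
    **field_kwargs,
) -> dict[str, float]:
    """Evaluate only the named descriptors for one molecule (used when
    predicting activities of screened compounds on the training grid)."""
    by_type: dict[str, list[tuple[str, int]]] = {}
    for name in names:
        ftype, idx = parse_descriptor_name(name)
        by_type.setdefault(ftype, []).append((name, idx))
    out: dict[str, float] = {}
    for ftype, entries in by_type.items():
        pts = np.array([grid.point(idx) for _, idx in entries])
        fields = compute_fields(mol, grid, probe, points=pts, **field_kwargs)
        for (name, _), v in zip(entries, fields[ftype]):
            out[name] = float(v)
    return out


def filter_invariant_columns(
    m: DescriptorMatrix,
    variance_cutoff: float = 0.1,
) -> DescriptorMatrix:
    """Drop descriptor columns whose sample variance falls below the cutoff.

    Mirrors the usual QSAR-worksheet pre-processing step in which invariable
    grid columns carry no structure-activity signal; removed column names are
    logged.  Order of survivors is preserved.
    """
    if variance_cutoff < 0:
        raise ValueError("variance_cutoff must be >= 0")
    var = m.X.var(axis=0, ddof=1)
    keep = var >= variance_cutoff
    removed = [c for c, k in zip(m.X.columns, keep) if not k]
    if not keep.any():
        raise ValueError("variance filter removed every column; lower the cutoff")
    if removed:
        logger.info("variance filter removed %d of %d columns",
                    len(removed), m.X.shape[1])
        logger.debug("removed columns: %s", removed)
    desc = [d for d, k in zip(m.descriptors, keep) if k] if m.descriptors else []
    return DescriptorMatrix(m.X.loc[:, keep], m.y, desc)
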