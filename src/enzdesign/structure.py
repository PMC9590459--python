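"""Structure parsing, solvent accessibility, and residue environment classes.

Solvent-accessible surface area uses the Shrake-Rupley point-counting scheme
on a Fibonacci lattice.  Relative accessibility divides each residue's summed
atom SASA by the theoretical maximum for its residue type (Tien et al.
theoretical values), and residues are binned into surface / semi-exposed /
buried bands plus an active-pocket flag based on heavy-atom distance to any
bound ligand atom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from scipy.spatial import cKDTree

from enzdesign.errors import InputError, ParameterError

logger = logging.getLogger(__name__)

#: Van der Waals radii (Å) by element symbol.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "FE": 2.00,
    "SE": 1.90,
}
DEFAULT_VDW = 1.70

#: Theoretical maximum accessible surface area per residue type (Å²),
#: Tien et al. theoretical values.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

DEFAULT_LIGAND_NAMES = frozenset({"HEM"})


class Atom(NamedTuple):
    serial: int
    name: str
    element: str
    residue_name: str
    chain: str
    residue_number: int
    coord: tuple[float, float, float]
    is_ligand: bool


@dataclass
class Structure:
    """Flat heavy-atom list from the first model of a PDB file."""

    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise InputError("structure has no atoms")
        coords = self.coords()
        if not np.isfinite(coords).all():
            raise InputError("non-finite coordinates")

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def radii(self, probe_extra: float = 0.0) -> np.ndarray:
        return np.array(
            [VDW_RADII.get(a.element.upper(), DEFAULT_VDW) + probe_extra for a in self.atoms]
        )

    @property
    def ligand_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_ligand]

    @property
    def protein_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_ligand]


@dataclass
class ResidueEnvironment:
    """Burial and pocket annotation for one residue."""

    residue_number: int
    chain: str
    residue_name: str
    rsa: float
    burial_class: str  # surface | semi-exposed | buried
    pocket: bool
    min_ligand_distance: float


def _element_from_name(name: str) -> str:
    stripped = name.strip()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "C"


def read_structure(path: str, ligand_names: Iterable[str] | None = None) -> Structure:
    """Parse a PDB file into a heavy-atom :class:`Structure`.

    Only the first model is used; only altloc '' or 'A' atoms are kept;
    hydrogens are dropped.  HETATM residues whose name is in ``ligand_names``
    (default ``{"HEM"}``) are flagged as ligand atoms; waters are skipped.
    """
    lig_set = set(DEFAULT_LIGAND_NAMES if ligand_names is None else ligand_names)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            model = next(parser.get_structure("s", path).get_models())
        except (StopIteration, Exception) as exc:  # noqa: B014 - Bio.PDB raises bare Exception
            raise InputError(f"failed to parse PDB file {path}: {exc}") from exc

    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            hetflag, resnum, _ = residue.id
            resname = residue.get_resname().strip()
            if resname in ("HOH", "WAT"):
                continue
            is_het = hetflag.strip() != ""
            is_lig = is_het and resname in lig_set
            if is_het and not is_lig:
                continue
            for atom in residue:
                if atom.get_altloc() not in (" ", "", "A"):
                    continue
                element = (atom.element or "").strip().upper()
                if not element:
                    element = _element_from_name(atom.get_name())
                    logger.warning(
                        "atom %s in %s %d: element inferred as %s from name",
                        atom.get_name(), resname, resnum, element,
                    )
                if element == "H":
                    continue
                atoms.append(
                    Atom(
                        serial=atom.get_serial_number() or len(atoms) + 1,
                        name=atom.get_name(),
                        element=element,
                        residue_name=resname,
                        chain=chain.id,
                        residue_number=int(resnum),
                        coord=tuple(float(x) for x in atom.get_coord()),
                        is_ligand=is_lig,
                    )
                )
    if not any(not a.is_ligand for a in atoms):
        raise InputError(f"no protein ATOM records in {path}")
    return Structure(atoms=atoms)


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (golden-angle lattice)."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (1.0 + 5.0**0.5) * k
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def atom_sasa(
    s: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    exclude_ligand_occluders: bool = True,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake-Rupley.

    For each atom, the fraction of ``n_points`` lattice points on its
    probe-expanded sphere not buried inside any occluder's expanded sphere,
    times the sphere area.  By default ligand atoms do not occlude (protein-
    only accessibility); they still receive their own SASA values.
    """
    if probe <= 0:
        raise ParameterError("probe radius must be positive")
    if n_points < 100:
        raise ParameterError("n_points must be >= 100")
    coords = s.coords()
    radii = s.radii() + probe
    n_atoms = len(s.atoms)
    sphere = fibonacci_sphere(n_points)

    occ_mask = np.ones(n_atoms, dtype=bool)
    if exclude_ligand_occluders:
        occ_mask = np.array([not a.is_ligand for a in s.atoms])
    occ_coords = coords[occ_mask]
    occ_radii = radii[occ_mask]
    occ_index = np.nonzero(occ_mask)[0]
    tree = cKDTree(occ_coords)
    r_max = float(occ_radii.max())

    areas = np.empty(n_atoms)
    for i in range(n_atoms):
        ri = radii[i]
        pts = coords[i] + ri * sphere
        nbr = tree.query_ball_point(coords[i], ri + r_max)
        nbr = [k for k in nbr if occ_index[k] != i]
        if nbr:
            nc = occ_coords[nbr]
            nr = occ_radii[nbr]
            d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nr**2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * ri * ri
    return areas


def residue_rsa(s: Structure, atom_areas: np.ndarray) -> dict[tuple[str, int], float]:
    """Relative accessibility per protein residue, keyed by (chain, number).

    Residues whose type is missing from the reference table are skipped with
    a warning.
    """
    if len(atom_areas) != len(s.atoms):
        raise InputError("atom_areas does not match structure atoms")
    sums: dict[tuple[str, int], float] = {}
    names: dict[tuple[str, int], str] = {}
    for atom, area in zip(s.atoms, atom_areas):
        if atom.is_ligand:
            continue
        key = (atom.chain, atom.residue_number)
        sums[key] = sums.get(key, 0.0) + float(area)
        names[key] = atom.residue_name
    rsa: dict[tuple[str, int], float] = {}
    for key, total in sums.items():
        ref = MAX_ASA.get(names[key])
        if ref is None:
            logger.warning("residue %s %s has no reference ASA; excluded", names[key], key)
            continue
        rsa[key] = total / ref
    return rsa


def classify_residues(
    s: Structure,
    rsa: dict[tuple[str, int], float],
    surface_min: float = 0.25,
    buried_max: float = 0.05,
    pocket_cutoff: float = 6.0,
) -> list[ResidueEnvironment]:
    """Bin residues into surface / semi-exposed / buried and flag the pocket.

    ``pocket`` is true when any heavy atom of the residue lies within
    ``pocket_cutoff`` Å of any ligand atom; with no ligand present, all
    distances are infinite and no residue is in the pocket.
    """
    if surface_min <= buried_max:
        raise ParameterError("surface_min must exceed buried_max")
    lig = s.ligand_atoms
    lig_tree = cKDTree(np.array([a.coord for a in lig])) if lig else None

    by_res: dict[tuple[str, int], list[Atom]] = {}
    for atom in s.protein_atoms:
        by_res.setdefault((atom.chain, atom.residue_number), []).append(atom)

    out: list[ResidueEnvironment] = []
    for key in sorted(by_res, key=lambda k: (k[0], k[1])):
        if key not in rsa:
            continue
        value = rsa[key]
        if value >= surface_min:
            burial = "surface"
        elif value <= buried_max:
            burial = "buried"
        else:
            burial = "semi-exposed"
        if lig_tree is not None:
            pts = np.array([a.coord for a in by_res[key]])
            dmin = float(lig_tree.query(pts)[0].min())
        else:
            dmin = float("inf")
        out.append(
            ResidueEnvironment(
                residue_number=key[1],
                chain=key[0],
                residue_name=by_res[key][0].residue_name,
                rsa=float(value),
                burial_class=burial,
                pocket=dmin <= pocket_cutoff,
                min_ligand_distance=dmin,
            )
        )
    return out


def write_environment_tsv(envs: list[ResidueEnvironment], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("residue_number\tchain\tresidue_name\trsa\tburial_class\tpocket\tmin_ligand_distance\n")
        for e in envs:
            dist = f"{e.min_ligand_distance:.3f}" if np.isfinite(e.min_ligand_distance) else "inf"
            fh.write(
                f"{e.residue_number}\t{e.chain}\t{e.residue_name}\t{e.rsa:.4f}\t"
                f"{e.burial_class}\t{int(e.pocket)}\t{dist}\n"
            )
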