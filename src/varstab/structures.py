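"""Protein structure handling: PDB parsing, chain preparation, coverage, Kabsch.

Crystal structures arrive as fixed-width PDB text.  Parsing is delegated to
Bio.PDB and the result converted into lightweight containers that carry van
der Waals radii (needed by the accessibility layer).  Waters and heteroatoms
are dropped, only the first MODEL is read, and for alternate locations the
highest-occupancy conformer is kept (ties broken by file order).

The superposition used for ensemble RMSD reporting pairs Cα atoms by residue
number and solves the least-squares rigid transform with the Kabsch SVD
construction, constraining the rotation to be proper (det = +1).
"""

from __future__ import annotations

import io
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from .variants import AA_1TO3, CANONICAL_AA

log = logging.getLogger(__name__)

#: default van der Waals radii in Å (Chothia-like); hydrogens are parsed but
#: ignored by the accessibility layer since crystal structures rarely
#: resolve them.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
}
_FALLBACK_RADIUS = 1.70

_AA_3TO1_UPPER = {k.upper(): v for k, v in
                  {v3: a1 for a1, v3 in AA_1TO3.items()}.items()}
# i.e. {"ALA": "A", ...}


class StructureError(ValueError):
    """Base class for structure-layer errors."""


class PdbParseError(StructureError):
    """Raised when PDB text cannot be parsed."""


class EmptyStructureError(StructureError):
    """Raised when no polymer ATOM records survive parsing/filtering."""


class DegenerateGeometryError(StructureError):
    """Raised when superposition points are coincident or collinear."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray          # shape (3,), Å
    radius: float               # van der Waals radius, Å
    occupancy: float = 1.0
    altloc: Optional[str] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: bad coordinates")
        if self.radius <= 0:
            raise StructureError(f"atom {self.name}: radius must be > 0")


@dataclass
class Residue:
    seq_number: int             # author numbering from the PDB file
    aa: str                     # one-letter code, "X" if nonstandard
    atoms: list[Atom]
    insertion_code: Optional[str] = None
    nonstandard: bool = False

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(f"residue {self.seq_number}: no atoms")
        if self.aa not in CANONICAL_AA and not self.nonstandard:
            raise StructureError(
                f"residue {self.seq_number}: {self.aa!r} not canonical and "
                "not flagged nonstandard")


@dataclass
class ProteinStructure:
    structure_id: str
    chains: dict[str, list[Residue]]     # chain id -> ordered residues
    resolution: Optional[float] = None

    def __post_init__(self) -> None:
        for cid, residues in self.chains.items():
            keys = [(r.seq_number, r.insertion_code) for r in residues]
            if len(keys) != len(set(keys)):
                raise StructureError(
                    f"{self.structure_id} chain {cid}: duplicate residue numbers")

    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def iter_atoms(self):
        for cid, residues in self.chains.items():
            for res in residues:
                for atom in res.atoms:
                    yield cid, res, atom

    def chain(self, chain_id: str) -> "ProteinStructure":
        """A copy containing a single chain."""
        if chain_id not in self.chains:
            raise StructureError(f"no chain {chain_id!r} in {self.structure_id}")
        return ProteinStructure(
            structure_id=self.structure_id,
            chains={chain_id: self.chains[chain_id]},
            resolution=self.resolution,
        )


def infer_element(atom_name: str) -> str:
    """Infer the element from a PDB atom name when the element column is blank."""
    stripped = atom_name.strip()
    if not stripped:
        raise StructureError("empty atom name")
    # Standard PDB names start digits for hydrogens (e.g. 1HB); else the
    # first alphabetic character is the element for C/N/O/S/H organics.
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise StructureError(f"cannot infer element from atom name {atom_name!r}")


_WATER_NAMES = {"HOH", "WAT", "DOD"}


def read_pdb(
    source: Union[str, io.TextIOBase],
    structure_id: str = "struct",
    radii: Optional[Mapping[str, float]] = None,
    keep_nonstandard: bool = False,
) -> ProteinStructure:
    """Parse PDB text into a :class:`ProteinStructure`.

    HETATM records and waters are excluded, only the first MODEL is used,
    and the highest-occupancy alternate location is retained per atom.
    """
    radii = dict(DEFAULT_VDW_RADII if radii is None else radii)
    if isinstance(source, str):
        handle: io.TextIOBase = io.StringIO(source) if "\n" in source else open(source)
    else:
        handle = source
    parser = PDBParser(QUIET=True)
    try:
        bio_structure = parser.get_structure(structure_id, handle)
    except (PDBConstructionException, ValueError) as exc:
        raise PdbParseError(f"{structure_id}: {exc}") from exc
    finally:
        if isinstance(source, str) and "\n" not in source:
            handle.close()

    try:
        model = next(iter(bio_structure))
    except StopIteration:
        raise EmptyStructureError(f"{structure_id}: no models in PDB input")

    chains: dict[str, list[Residue]] = {}
    for bio_chain in model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            hetflag, seq_number, icode = bio_res.id
            if hetflag != " " or bio_res.resname.strip() in _WATER_NAMES:
                continue
            resname = bio_res.resname.strip().upper()
            aa = _AA_3TO1_UPPER.get(resname)
            nonstandard = aa is None
            if nonstandard and not keep_nonstandard:
                log.warning("%s: skipping nonstandard residue %s %s%s",
                            structure_id, resname, seq_number, icode.strip())
                continue
            atoms: list[Atom] = []
            for bio_atom in bio_res:
                if bio_atom.is_disordered():
                    best = None
                    for alt in bio_atom.disordered_get_list():
                        occ = alt.get_occupancy() or 0.0
                        if best is None or occ > (best.get_occupancy() or 0.0):
                            best = alt
                    bio_atom = best
                element = (bio_atom.element or "").strip().upper()
                if not element:
                    element = infer_element(bio_atom.get_name())
                atoms.append(Atom(
                    name=bio_atom.get_name(),
                    element=element,
                    coords=np.array(bio_atom.get_coord(), dtype=float),
                    radius=radii.get(element, _FALLBACK_RADIUS),
                    occupancy=bio_atom.get_occupancy() or 1.0,
                    altloc=(bio_atom.get_altloc().strip() or None),
                ))
            if atoms:
                residues.append(Residue(
                    seq_number=seq_number,
                    aa=aa if aa is not None else "X",
                    atoms=atoms,
                    insertion_code=icode.strip() or None,
                    nonstandard=nonstandard,
                ))
        if residues:
            chains[bio_chain.id] = residues
    if not chains:
        raise EmptyStructureError(
            f"{structure_id}: no polymer ATOM records after filtering")
    return ProteinStructure(structure_id=structure_id, chains=chains)


def write_pdb(structure: ProteinStructure) -> str:
    """Serialize to fixed-width PDB ATOM records (3-decimal coordinates)."""
    lines = []
    serial = 1
    one_to_three = {v: k for k, v in _AA_3TO1_UPPER.items()}
    for cid in structure.chains:
        for res in structure.chains[cid]:
            resname = one_to_three.get(res.aa, "UNK")
            for atom in res.atoms:
                name = atom.name
                # column alignment: 1-letter elements start in column 14
                name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial:5d} {name_field}{'':1s}{resname:>3s} "
                    f"{cid:1s}{res.seq_number:4d}{res.insertion_code or '':1s}"
                    f"   {x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}"
                    f"{0.0:6.2f}          {atom.element:>2s}  ")
                serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def strip_nonnative(
    structure: ProteinStructure, native_range: tuple[int, int]
) -> ProteinStructure:
    """Remove residues outside ``native_range`` (e.g. purification tags)."""
    lo, hi = native_range
    if lo > hi:
        raise StructureError(f"invalid native range [{lo}, {hi}]")
    chains = {}
    for cid, residues in structure.chains.items():
        kept = [r for r in residues if lo <= r.seq_number <= hi]
        if kept:
            chains[cid] = kept
    return ProteinStructure(
        structure_id=structure.structure_id,
        chains=chains,
        resolution=structure.resolution,
    )


def coverage_map(
    ensemble: Sequence[tuple[str, str, ProteinStructure]],
) -> dict[int, list[tuple[str, str]]]:
    """Which ensemble members resolve each residue position.

    Members are ``(structure_id, chain_id, structure)`` triples sharing one
    numbering scheme.  Positions resolved by no member are absent from the
    result.  Insertion codes are rejected to keep positions integral.
    """
    coverage: dict[int, list[tuple[str, str]]] = {}
    for sid, cid, structure in ensemble:
        if cid not in structure.chains:
            raise StructureError(f"no chain {cid!r} in {sid}")
        for res in structure.chains[cid]:
            if res.insertion_code:
                raise StructureError(
                    f"{sid} chain {cid}: insertion code at residue "
                    f"{res.seq_number} not supported by coverage_map")
            coverage.setdefault(res.seq_number, []).append((sid, cid))
    return dict(sorted(coverage.items()))


def ca_coordinates(structure: ProteinStructure, chain_id: str) -> dict[int, np.ndarray]:
    """Cα coordinates keyed by residue number for one chain."""
    out = {}
    for res in structure.chain(chain_id).chains[chain_id]:
        for atom in res.atoms:
            if atom.name.strip() == "CA":
                out[res.seq_number] = atom.coords
                break
    return out


def kabsch_superpose(
    mobile: Sequence[Sequence[float]],
    reference: Sequence[Sequence[float]],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired point sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` in the
    least-squares sense.  The rotation is proper (det = +1); reflections are
    corrected by flipping the smallest singular vector.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise StructureError("point lists must be equal-length lists of 3-vectors")
    n = P.shape[0]
    if n < 3:
        raise StructureError("need at least 3 point pairs for superposition")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # degenerate when either set is (near-)collinear or coincident
    for M, which in ((Pc, "mobile"), (Qc, "reference")):
        s = np.linalg.svd(M, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise DegenerateGeometryError(
                f"{which} points are coincident or collinear")
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    fitted = Pc @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - Qc) ** 2, axis=1))))
    return R, t, rmsd


def ensemble_rmsd(
    ensemble: Sequence[tuple[str, str, ProteinStructure]],
    reference: tuple[str, str, ProteinStructure],
) -> dict[tuple[str, str], float]:
    """Cα RMSD of every ensemble member against a reference chain.

    Pairing is by residue-number intersection, mirroring how a structural
    ensemble of one protein is compared across crystal forms.
    """
    ref_ca = ca_coordinates(reference[2], reference[1])
    out = {}
    for sid, cid, structure in ensemble:
        mob_ca = ca_coordinates(structure, cid)
        shared = sorted(set(ref_ca) & set(mob_ca))
        if len(shared) < 3:
            log.warning("%s/%s: fewer than 3 shared Cα positions; skipped", sid, cid)
            continue
        mobile = [mob_ca[p] for p in shared]
        ref = [ref_ca[p] for p in shared]
        _, _, rmsd = kabsch_superpose(mobile, ref)
        out[(sid, cid)] = rmsd
    return out
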