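"""Solvent accessibility: Shrake–Rupley SASA, RSA normalization, burial.

The accessible surface of each atom is sampled with a deterministic
golden-spiral point set on the solvent-expanded sphere (atom radius plus a
1.4 Å water probe); a sample point counts as exposed when it lies outside
every other atom's expanded sphere.  Per-residue areas are the sums over the
residue's atoms.  Relative solvent accessibility (RSA) divides the mean
residue area across representative structures by the residue type's
theoretical maximum area (Tien et al. scale); residues with RSA < 0.2 are
treated as buried.  RSA may exceed 1.0 (observed area above the theoretical
maximum) and is reported uncapped.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures import ProteinStructure, StructureError

log = logging.getLogger(__name__)

#: theoretical maximum accessible surface areas (Å²) per residue type,
#: transcribed from the Tien et al. theoretical scale.
MAX_ASA_TIEN: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

DEFAULT_PROBE_RADIUS = 1.4     # Å, water probe
DEFAULT_N_POINTS = 960         # sphere sample points per atom
DEFAULT_BURIED_THRESHOLD = 0.2


class SasaError(ValueError):
    """Raised on invalid accessibility inputs."""


@dataclass
class SasaResult:
    """Per-atom and per-residue solvent-accessible areas for one structure."""

    per_atom: dict[tuple[str, int, str], float]       # (chain, resnum, atom name) -> Å²
    per_residue: dict[tuple[str, int], float]         # (chain, resnum) -> Å²
    residue_aa: dict[tuple[str, int], str]
    probe_radius: float
    n_sphere_points: int

    def total(self) -> float:
        return float(sum(self.per_residue.values()))


@dataclass
class RsaProfile:
    """Relative solvent accessibility per residue position.

    ``rsa`` holds the mean absolute area across the contributing structures
    divided by the residue type's theoretical maximum; ``n_structures``
    counts the contributing ensemble members per position.
    """

    rsa: dict[int, float]
    mean_asa: dict[int, float]
    aa: dict[int, str]
    n_structures: dict[int, int]
    buried_threshold: float = DEFAULT_BURIED_THRESHOLD

    def buried(self, position: int) -> bool:
        return is_buried(self.rsa[position], self.buried_threshold)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "position": pos,
            "aa": self.aa[pos],
            "mean_asa_A2": self.mean_asa[pos],
            "rsa": self.rsa[pos],
            "n_structures": self.n_structures[pos],
            "buried": self.buried(pos),
        } for pos in sorted(self.rsa)]
        return pd.DataFrame(rows)

    def to_tsv(self, path: Union[str, io.TextIOBase]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, source: Union[str, io.TextIOBase],
                 buried_threshold: float = DEFAULT_BURIED_THRESHOLD) -> "RsaProfile":
        df = pd.read_csv(source, sep="\t")
        required = {"position", "aa", "mean_asa_A2", "rsa", "n_structures"}
        missing = required - set(df.columns)
        if missing:
            raise SasaError(f"RSA TSV missing columns: {sorted(missing)}")
        return cls(
            rsa={int(r.position): float(r.rsa) for r in df.itertuples()},
            mean_asa={int(r.position): float(r.mean_asa_A2) for r in df.itertuples()},
            aa={int(r.position): str(r.aa) for r in df.itertuples()},
            n_structures={int(r.position): int(r.n_structures) for r in df.itertuples()},
            buried_threshold=buried_threshold,
        )


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit sphere sampling (Fibonacci spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack((
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ))


def _canonical_frame(xyz: np.ndarray) -> np.ndarray:
    """Rotation that maps coordinates onto their principal axes.

    The sample grid is fixed, so areas would otherwise depend slightly on
    the structure's orientation in the lab frame.  Expressing coordinates in
    a frame derived from the structure itself (covariance eigenvectors,
    signs fixed by the first off-plane atom so the frame co-rotates with the
    data) makes the computed areas invariant under rigid motion for generic
    structures.  Falls back to the identity when there are too few atoms.
    """
    if len(xyz) < 3:
        return np.eye(3)
    centered = xyz - xyz.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1]                       # descending variance
    scale = max(float(np.abs(centered).max()), 1.0)
    for k in range(2):
        for row in centered:                   # first atom clearly off-plane
            proj = float(row @ vecs[:, k])
            if abs(proj) > 1e-9 * scale:
                if proj < 0:
                    vecs[:, k] = -vecs[:, k]
                break
    vecs[:, 2] = np.cross(vecs[:, 0], vecs[:, 1])   # right-handed
    return vecs


def shrake_rupley(
    structure: ProteinStructure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    include_hydrogens: bool = False,
    orient: bool = True,
) -> SasaResult:
    """Sample-based solvent-accessible surface area of a structure.

    Each atom's area is ``(exposed points / n_points) * 4π(r + probe)²``
    with a fixed golden-spiral point set, so the result is deterministic.
    With ``orient=True`` (default) coordinates are first expressed in the
    structure's own principal-axis frame, which makes the result
    independent of the structure's orientation in space; ``orient=False``
    keeps the raw frame, under which adding atoms can only remove exposed
    sample points (exact occlusion monotonicity).
    """
    if n_points < 16:
        raise SasaError("n_points must be at least 16")
    if probe_radius < 0:
        raise SasaError("probe radius must be non-negative")

    keys: list[tuple[str, int, str]] = []
    res_keys: list[tuple[str, int]] = []
    coords: list[np.ndarray] = []
    radii: list[float] = []
    residue_aa: dict[tuple[str, int], str] = {}
    for cid, res, atom in structure.iter_atoms():
        if not include_hydrogens and atom.element == "H":
            continue
        keys.append((cid, res.seq_number, atom.name))
        res_keys.append((cid, res.seq_number))
        coords.append(atom.coords)
        radii.append(atom.radius)
        residue_aa[(cid, res.seq_number)] = res.aa
    if not coords:
        raise SasaError("structure has no heavy atoms")

    xyz = np.asarray(coords)
    if orient:
        xyz = (xyz - xyz.mean(axis=0)) @ _canonical_frame(xyz)
    expanded = np.asarray(radii) + probe_radius
    unit = golden_spiral_points(n_points)

    # neighbour lists: only atoms whose expanded spheres can overlap matter
    tree = cKDTree(xyz)
    max_reach = 2.0 * expanded.max()
    per_atom: dict[tuple[str, int, str], float] = {}
    per_residue: dict[tuple[str, int], float] = {}
    for i in range(len(xyz)):
        r_i = expanded[i]
        neighbours = [j for j in tree.query_ball_point(xyz[i], r_i + expanded.max())
                      if j != i and np.linalg.norm(xyz[j] - xyz[i]) < r_i + expanded[j]]
        points = xyz[i] + r_i * unit
        if neighbours:
            nb_xyz = xyz[neighbours]                       # (k, 3)
            nb_r = expanded[neighbours]                    # (k,)
            d2 = ((points[:, None, :] - nb_xyz[None, :, :]) ** 2).sum(axis=2)
            buried_pts = (d2 < nb_r[None, :] ** 2).any(axis=1)
            n_exposed = int((~buried_pts).sum())
        else:
            n_exposed = n_points
        area = (n_exposed / n_points) * 4.0 * math.pi * r_i ** 2
        per_atom[keys[i]] = area
        per_residue[res_keys[i]] = per_residue.get(res_keys[i], 0.0) + area
    return SasaResult(
        per_atom=per_atom,
        per_residue=per_residue,
        residue_aa=residue_aa,
        probe_radius=probe_radius,
        n_sphere_points=n_points,
    )


def restrict_to_chain(result: SasaResult, chain_id: str) -> SasaResult:
    """The areas of one chain, computed in the context they were sampled in.

    For interface analysis the complex is sampled whole (so partner chains
    occlude) and then restricted to the chain of interest before profiling.
    """
    return SasaResult(
        per_atom={k: v for k, v in result.per_atom.items() if k[0] == chain_id},
        per_residue={k: v for k, v in result.per_residue.items()
                     if k[0] == chain_id},
        residue_aa={k: v for k, v in result.residue_aa.items()
                    if k[0] == chain_id},
        probe_radius=result.probe_radius,
        n_sphere_points=result.n_sphere_points,
    )


def rsa_profile(
    members: Sequence[tuple[ProteinStructure, SasaResult]],
    scale: Mapping[str, float] = MAX_ASA_TIEN,
    chain_ids: Optional[Mapping[int, str]] = None,
    buried_threshold: float = DEFAULT_BURIED_THRESHOLD,
) -> RsaProfile:
    """Average residue areas across representative structures, then normalize.

    Every chain of every member contributes one observation per residue
    position.  The mean absolute area per position is divided by the
    theoretical maximum for that residue type to give RSA.  Positions
    resolved by no member are absent.
    """
    if not members:
        raise SasaError("need at least one structure for an RSA profile")
    asa_obs: dict[int, list[float]] = {}
    aa_at: dict[int, str] = {}
    for structure, result in members:
        for (cid, pos), area in result.per_residue.items():
            aa = result.residue_aa[(cid, pos)]
            prev = aa_at.setdefault(pos, aa)
            if prev != aa:
                log.warning("position %d: residue type differs across members "
                            "(%s vs %s); keeping first", pos, prev, aa)
            asa_obs.setdefault(pos, []).append(area)
    rsa: dict[int, float] = {}
    mean_asa: dict[int, float] = {}
    n_structures: dict[int, int] = {}
    for pos, areas in asa_obs.items():
        aa = aa_at[pos]
        if aa not in scale:
            raise SasaError(
                f"position {pos}: residue type {aa!r} missing from max-ASA scale")
        mean_asa[pos] = float(np.mean(areas))
        rsa[pos] = mean_asa[pos] / scale[aa]
        n_structures[pos] = len(areas)
    return RsaProfile(rsa=rsa, mean_asa=mean_asa, aa=aa_at,
                      n_structures=n_structures,
                      buried_threshold=buried_threshold)


def is_buried(rsa_value: float, threshold: float = DEFAULT_BURIED_THRESHOLD) -> bool:
    """Strictly below-threshold RSA counts as buried (solvent-inaccessible)."""
    if rsa_value < 0:
        raise SasaError("RSA cannot be negative")
    return rsa_value < threshold


def delta_rsa(
    complex_profile: RsaProfile, isolated_profile: RsaProfile
) -> dict[int, float]:
    """Per-position RSA(complex) − RSA(isolated); binding can only occlude,
    so interface positions come out negative.  Positions missing from either
    profile are absent."""
    shared = set(complex_profile.rsa) & set(isolated_profile.rsa)
    return {pos: complex_profile.rsa[pos] - isolated_profile.rsa[pos]
            for pos in sorted(shared)}
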