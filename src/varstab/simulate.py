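"""Synthetic cohorts and toy structures for offline, end-to-end runs.

The cohort generator emulates the statistical structure of a curated
missense-variant study on a 610-residue protein: a pathogenic group whose
latent (true) ΔΔG is Normal(5.06, 4.25²) kcal/mol and a benign group at
Normal(1.13, 1.46²); per-structure ΔΔG observations add Normal(0, 0.8²)
force-field noise; most variants are resolved by the full 31-chain ensemble
while a small remainder is covered by a single chain; pathogenic positions
are burial-skewed in RSA; and a REVEL-like score increases with the latent
ΔΔG.  Everything is driven by one seeded generator, so a fixed seed gives
byte-identical tables.

Toy structures are ideal α-helices (1.5 Å rise, 100°/residue, 2.3 Å radius)
of Cα plus one pseudo side-chain sphere per residue, written as fixed-width
PDB text; a second chain can be placed in contact to create a genuine
interface for ΔRSA/ΔΔΔG fixtures.  No claim of physical realism is made —
see docs/methods.md for what these fixtures do and do not exercise.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .sasa import MAX_ASA_TIEN
from .variants import VARIANT_TSV_COLUMNS

_AA = np.array(sorted(MAX_ASA_TIEN))            # 20 canonical residues
_BASES = np.array(list("ACGT"))


class SyntheticError(ValueError):
    """Raised on invalid generator configuration."""


@dataclass
class SyntheticConfig:
    """Generative parameters for the synthetic cohort.

    Group means/SDs and the force-field noise follow the study conditions
    the generator emulates; ``full_coverage_fraction`` controls how many
    variants are resolved by every chain of the ensemble (the rest are
    covered by a single chain).
    """

    n_pathogenic: int = 161
    n_benign: int = 161
    ddg_mean_path: float = 5.06       # kcal/mol
    ddg_sd_path: float = 4.25
    ddg_mean_benign: float = 1.13
    ddg_sd_benign: float = 1.46
    buried_fraction_path: float = 0.863
    n_structures: int = 31
    per_structure_noise_sd: float = 0.8
    full_coverage_fraction: float = 0.95
    revel_noise_sd: float = 0.15
    protein_length: int = 610
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ddg_sd_path", "ddg_sd_benign", "per_structure_noise_sd",
                     "revel_noise_sd"):
            if getattr(self, name) <= 0:
                raise SyntheticError(f"{name} must be > 0")
        for name in ("buried_fraction_path", "full_coverage_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise SyntheticError(f"{name} must be in [0, 1]")
        if self.n_pathogenic < 0 or self.n_benign < 0:
            raise SyntheticError("group sizes must be non-negative")
        if self.n_structures < 1:
            raise SyntheticError("need at least one structure")


@dataclass
class SyntheticCohort:
    """Generated tables, all satisfying the pipeline's input contracts.

    ``variants``: the variant TSV layout; ``ddg``: per-structure-chain ΔΔG
    records; ``rsa``: a position-level RSA profile table; ``truth``: the
    latent per-variant values the observations were generated from (not a
    pipeline input — kept for oracle checks).
    """

    variants: pd.DataFrame
    ddg: pd.DataFrame
    rsa: pd.DataFrame
    truth: pd.DataFrame
    config: SyntheticConfig

    def write(self, out_dir) -> dict[str, str]:
        import os
        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        for name, df in (("variants", self.variants), ("ddg", self.ddg),
                         ("rsa", self.rsa), ("truth", self.truth)):
            path = os.path.join(str(out_dir), f"{name}.tsv")
            df.to_csv(path, sep="\t", index=False, na_rep=".",
                      float_format="%.6g")
            paths[name] = path
        return paths


def generate_cohort(cfg: SyntheticConfig) -> SyntheticCohort:
    """Draw a two-group variant cohort with per-structure ΔΔG observations.

    Deterministic given ``cfg.seed``.  Positions are drawn uniformly along
    the protein, so a realistic handful of positions carry both a benign
    and a pathogenic variant (multiallelic sites); the reference residue is
    a fixed property of the position.
    """
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_pathogenic + cfg.n_benign
    groups = np.array(["pathogenic"] * cfg.n_pathogenic
                      + ["benign"] * cfg.n_benign)

    # reference sequence: residue type is a property of the position
    sequence = rng.choice(_AA, size=cfg.protein_length)

    positions = rng.integers(1, cfg.protein_length + 1, size=n_total)
    ref = sequence[positions - 1]
    alt = np.empty(n_total, dtype=ref.dtype)
    taken: dict[int, set[str]] = {}
    if n_total > 19 * cfg.protein_length:
        raise SyntheticError(
            f"{n_total} distinct substitutions cannot fit on "
            f"{cfg.protein_length} residues (19 per position); "
            "increase protein_length")
    for i in range(n_total):
        pos = int(positions[i])
        used = taken.setdefault(pos, {str(sequence[pos - 1])})
        # a position holds at most 19 alternate residues; walk on when full
        while len(used) == 20:
            pos = pos % cfg.protein_length + 1
            used = taken.setdefault(pos, {str(sequence[pos - 1])})
        positions[i] = pos
        ref[i] = sequence[pos - 1]
        choices = [a for a in _AA if a not in used]
        alt[i] = rng.choice(np.array(choices))
        used.add(str(alt[i]))

    # latent (true) per-variant stability change
    latent = np.where(
        groups == "pathogenic",
        rng.normal(cfg.ddg_mean_path, cfg.ddg_sd_path, size=n_total),
        rng.normal(cfg.ddg_mean_benign, cfg.ddg_sd_benign, size=n_total),
    )

    # position-level RSA: burial-skewed where a pathogenic variant occurs
    unique_pos = np.unique(positions)
    pos_is_path = {int(p): bool(np.any((positions == p)
                                       & (groups == "pathogenic")))
                   for p in unique_pos}
    rsa_at: dict[int, float] = {}
    for p in unique_pos:
        if pos_is_path[int(p)] and rng.random() < cfg.buried_fraction_path:
            rsa_at[int(p)] = float(rng.beta(2.0, 8.0))
        else:
            rsa_at[int(p)] = float(rng.uniform(0.0, 1.0))
    rsa_values = np.array([rsa_at[int(p)] for p in positions])

    # REVEL-like score: logistic in the standardized latent ΔΔG, plus noise
    z = (latent - latent.mean()) / latent.std(ddof=0)
    revel = 1.0 / (1.0 + np.exp(-2.0 * z))
    revel = np.clip(revel + rng.normal(0.0, cfg.revel_noise_sd, size=n_total),
                    0.0, 1.0)

    # population allele frequency: benign only, decreasing with latent ΔΔG
    log10_af = (-2.5 - 0.6 * np.clip(latent, 0.0, None)
                + rng.normal(0.0, 0.7, size=n_total))
    af = np.where(groups == "benign",
                  10.0 ** np.clip(log10_af, -7.0, -1.7), np.nan)

    # coverage: most variants resolved by the full ensemble, the rest by one
    n_full = int(round(cfg.full_coverage_fraction * n_total))
    fully_covered = np.zeros(n_total, dtype=bool)
    fully_covered[rng.choice(n_total, size=n_full, replace=False)] = True
    single_chain = rng.integers(0, cfg.n_structures, size=n_total)

    in_sgcd = (groups == "benign") & (rng.random(n_total) < 0.3)

    variants = pd.DataFrame({
        "id": [f"v{i + 1:04d}" for i in range(n_total)],
        "position": positions,
        "ref_aa": ref,
        "alt_aa": alt,
        "in_hgmd_dm": groups == "pathogenic",
        "in_gnomad": groups == "benign",
        "in_sgcd": in_sgcd,
        "allele_frequency": af,
        "revel": revel,
        "cdna_notation": [
            f"c.{3 * int(p) - 1}{rng.choice(_BASES)}>{rng.choice(_BASES)}"
            for p in positions],
    })[VARIANT_TSV_COLUMNS]

    chain_names = [f"TOY{k + 1:02d}" for k in range(cfg.n_structures)]
    rows = {"structure_id": [], "chain_id": [], "position": [],
            "ref_aa": [], "alt_aa": [], "ddg_kcal_mol": []}
    for i in range(n_total):
        members = (range(cfg.n_structures) if fully_covered[i]
                   else [int(single_chain[i])])
        noise = rng.normal(0.0, cfg.per_structure_noise_sd, size=len(members))
        for k, eps in zip(members, noise):
            rows["structure_id"].append(chain_names[k])
            rows["chain_id"].append("A")
            rows["position"].append(int(positions[i]))
            rows["ref_aa"].append(str(ref[i]))
            rows["alt_aa"].append(str(alt[i]))
            rows["ddg_kcal_mol"].append(latent[i] + eps)
    ddg = pd.DataFrame(rows)

    rsa_rows = []
    for p in sorted(rsa_at):
        aa = str(sequence[p - 1])
        rsa_rows.append({
            "position": p, "aa": aa,
            "mean_asa_A2": rsa_at[p] * MAX_ASA_TIEN[aa],
            "rsa": rsa_at[p], "n_structures": 7,
            "buried": rsa_at[p] < 0.2,
        })
    rsa = pd.DataFrame(rsa_rows)

    truth = pd.DataFrame({
        "id": variants["id"], "position": positions, "ref_aa": ref,
        "alt_aa": alt, "group": groups, "true_ddg": latent,
        "rsa": rsa_values, "revel": revel,
        "n_structures": np.where(fully_covered, cfg.n_structures, 1),
    })
    return SyntheticCohort(variants=variants, ddg=ddg, rsa=rsa, truth=truth,
                           config=cfg)


# ---------------------------------------------------------------------------
# toy structures

_HELIX_RISE = 1.5          # Å per residue
_HELIX_TURN = 100.0        # degrees per residue
_HELIX_RADIUS = 2.3        # Å, Cα distance from the helix axis
_SIDE_CHAIN_OFFSET = 1.5   # Å, pseudo side-chain sphere beyond the Cα shell
#: axis-to-axis spacing (Å) that brings two helices' side-chain shells into
#: contact: 2·(2.3 + 1.5) + ~0.4 Å gap, well inside solvent-probe reach.
_CONTACT_SPACING = 8.0


def generate_toy_structure(
    n_residues: int,
    chain_ids: Sequence[str] = ("A",),
    seed: int = 0,
    contact_spacing: float = _CONTACT_SPACING,
) -> str:
    """Fixed-width PDB text for one or more ideal α-helical toy chains.

    Each residue contributes a Cα carbon on the helix plus one pseudo
    side-chain sphere ("CB", carbon) pointing away from the axis.  With two
    or more chains, helix axes are laid out along x at ``contact_spacing``
    so adjacent chains occlude one another — by construction the complex
    buries surface relative to the isolated chains.
    """
    if n_residues < 3:
        raise SyntheticError("toy helix needs at least 3 residues")
    rng = np.random.default_rng(seed)
    sequence = rng.choice(_AA, size=n_residues)
    lines = []
    serial = 1
    for c_index, cid in enumerate(chain_ids):
        x0 = c_index * contact_spacing
        for i in range(n_residues):
            theta = math.radians(_HELIX_TURN * i)
            # mirror alternate chains so side chains face each other
            direction = -1.0 if c_index % 2 else 1.0
            ca = np.array([
                x0 + direction * _HELIX_RADIUS * math.cos(theta),
                _HELIX_RADIUS * math.sin(theta),
                _HELIX_RISE * i,
            ])
            outward = np.array([direction * math.cos(theta),
                                math.sin(theta), 0.0])
            cb = ca + _SIDE_CHAIN_OFFSET * outward
            aa3 = _ONE_TO_THREE[str(sequence[i])]
            for name, xyz in (("CA", ca), ("CB", cb)):
                # fixed columns: name 13-16, altloc 17, resname 18-20,
                # chain 22, resseq 23-26, icode 27, x from 31
                lines.append(
                    f"ATOM  {serial:5d}  {name:<3s} {aa3:>3s} {cid:1s}"
                    f"{i + 1:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"  1.00  0.00           C  ")
                serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "E": "GLU", "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
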