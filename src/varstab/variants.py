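"""Missense variant ingestion, grouping, renumbering and deduplication.

Variants are amino-acid substitutions on the 610-residue menin isoform
(numbering of transcript NM_130799).  Group labels derive from database
membership: a variant reported as an HGMD "disease mutation" but absent from
the population databases (gnomAD, SGCD) is treated as pathogenic; a variant
seen in the population databases but never as a disease mutation is treated
as benign; a variant in both is of uncertain significance.  Database queries
themselves are out of scope — membership arrives as boolean columns in the
variant TSV.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Union

import pandas as pd

log = logging.getLogger(__name__)

AA_3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Glu": "E", "Gln": "Q", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}
CANONICAL_AA = frozenset(AA_3TO1.values())

#: first and last residue (inclusive) of the 5-residue insertion present in
#: the 615-residue minor isoform, taken as inserted after residue 148.
#: Configurable because the exact register of the insertion is a convention.
INSERTION_REGION_615 = (149, 153)


class Group(str, Enum):
    """Variant group label used throughout the pipeline."""

    PATHOGENIC = "pathogenic"
    BENIGN = "benign"
    UNCERTAIN = "uncertain"
    NOVEL = "novel"
    UNLABELED = "unlabeled"


#: severity order used when merged nucleotide records disagree on group
_GROUP_SEVERITY = [Group.PATHOGENIC, Group.UNCERTAIN, Group.NOVEL,
                   Group.BENIGN, Group.UNLABELED]


class VariantError(ValueError):
    """Base class for variant-layer errors."""


class HgvsParseError(VariantError):
    """Raised on malformed or non-missense protein HGVS notation."""


class NoEquivalentPositionError(VariantError):
    """Raised when a 615-isoform position falls inside the insertion."""


class MergeConflictError(VariantError):
    """Raised when records merged at one position disagree on the reference."""


@dataclass(frozen=True)
class GroupMembership:
    """Database membership flags for one variant."""

    in_hgmd_dm: bool
    in_gnomad: bool
    in_sgcd: bool


@dataclass
class MissenseVariant:
    """One amino-acid substitution with its group label and annotations.

    ``position`` is 1-based on the 610-residue isoform.  ``allele_frequency``
    and ``revel`` are optional annotations in [0, 1]; ``cdna_notation`` keeps
    the originating nucleotide change(s) for provenance.
    """

    id: str
    position: int
    ref_aa: str
    alt_aa: str
    group: Group = Group.UNLABELED
    allele_frequency: Optional[float] = None
    revel: Optional[float] = None
    cdna_notation: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref_aa not in CANONICAL_AA:
            raise VariantError(f"non-canonical reference residue {self.ref_aa!r}")
        if self.alt_aa not in CANONICAL_AA:
            raise VariantError(f"non-canonical variant residue {self.alt_aa!r}")
        if self.ref_aa == self.alt_aa:
            raise VariantError(
                f"{self.id}: reference and variant residues are identical "
                f"({self.ref_aa}{self.position}{self.alt_aa})")
        if self.position < 1:
            raise VariantError(f"{self.id}: position must be >= 1")
        self.group = Group(self.group)
        for name in ("allele_frequency", "revel"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise VariantError(f"{self.id}: {name}={v} outside [0, 1]")

    @property
    def key(self) -> tuple[int, str, str]:
        """Protein-level identity: (position, ref_aa, alt_aa)."""
        return (self.position, self.ref_aa, self.alt_aa)

    @property
    def label(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


def assign_group(m: GroupMembership) -> Group:
    """Map database membership to a group label.

    Pathogenic: disease-mutation class and absent from both population
    databases.  Benign: present in a population database, never flagged as a
    disease mutation.  Uncertain: both.  Unlabeled: reported nowhere.
    """
    in_population = m.in_gnomad or m.in_sgcd
    if m.in_hgmd_dm and not in_population:
        return Group.PATHOGENIC
    if not m.in_hgmd_dm and in_population:
        return Group.BENIGN
    if m.in_hgmd_dm and in_population:
        return Group.UNCERTAIN
    return Group.UNLABELED


def renumber_615_to_610(
    position_615: int,
    insertion_region: tuple[int, int] = INSERTION_REGION_615,
) -> int:
    """Convert a 615-isoform residue number to 610-isoform numbering.

    The minor isoform carries five extra residues inserted after residue 148
    (taken here to occupy positions 149-153).  Positions before the insertion
    are unchanged, positions after it shift down by five, and positions
    inside it have no equivalent in the major isoform.
    """
    lo, hi = insertion_region
    n_inserted = hi - lo + 1
    if not 1 <= position_615 <= 610 + n_inserted:
        raise VariantError(
            f"position {position_615} outside the 615-isoform range [1, 615]")
    if position_615 < lo:
        return position_615
    if position_615 > hi:
        return position_615 - n_inserted
    raise NoEquivalentPositionError(
        f"position {position_615} lies inside the isoform-specific insertion "
        f"({lo}-{hi}); no equivalent residue in the 610-residue isoform")


_HGVS_3 = re.compile(r"^p\.\(?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})\)?$")
_HGVS_1 = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_protein_hgvs(text: str) -> tuple[str, int, str]:
    """Parse ``p.(His46Pro)`` or ``H46P`` into ``(ref, position, alt)``.

    Only simple missense substitutions are accepted; frameshift, stop and
    deletion notations raise :class:`HgvsParseError`.
    """
    text = text.strip()
    m = _HGVS_3.match(text)
    if m:
        ref3, pos, alt3 = m.groups()
        if ref3 not in AA_3TO1 or alt3 not in AA_3TO1:
            raise HgvsParseError(f"{text!r}: not a canonical missense substitution")
        return AA_3TO1[ref3], int(pos), AA_3TO1[alt3]
    m = _HGVS_1.match(text)
    if m:
        ref1, pos, alt1 = m.groups()
        if ref1 not in CANONICAL_AA or alt1 not in CANONICAL_AA:
            raise HgvsParseError(f"{text!r}: not a canonical missense substitution")
        return ref1, int(pos), alt1
    raise HgvsParseError(f"cannot parse protein HGVS {text!r} as a missense change")


def dedupe_protein_variants(
    variants: Iterable[MissenseVariant],
) -> list[MissenseVariant]:
    """Collapse nucleotide-level records that encode the same protein change.

    Distinct nucleotide substitutions producing the same substitution are a
    single missense variant: allele frequencies are summed over the merged
    alleles and REVEL scores averaged over them.  Records at the same
    position must agree on the reference residue.
    """
    by_key: dict[tuple[int, str, str], list[MissenseVariant]] = {}
    ref_at_pos: dict[int, str] = {}
    order: list[tuple[int, str, str]] = []
    for v in variants:
        seen_ref = ref_at_pos.setdefault(v.position, v.ref_aa)
        if seen_ref != v.ref_aa:
            raise MergeConflictError(
                f"position {v.position}: conflicting reference residues "
                f"{seen_ref!r} vs {v.ref_aa!r}")
        if v.key not in by_key:
            order.append(v.key)
        by_key.setdefault(v.key, []).append(v)

    out: list[MissenseVariant] = []
    for key in order:
        group = by_key[key]
        if len(group) == 1:
            out.append(group[0])
            continue
        freqs = [v.allele_frequency for v in group if v.allele_frequency is not None]
        revels = [v.revel for v in group if v.revel is not None]
        labels = {v.group for v in group}
        merged_group = group[0].group
        if len(labels) > 1:
            merged_group = next(g for g in _GROUP_SEVERITY if g in labels)
            log.warning("merged records for %s disagree on group %s; keeping %s",
                        group[0].label, sorted(g.value for g in labels),
                        merged_group.value)
        cdnas = [v.cdna_notation for v in group if v.cdna_notation]
        out.append(replace(
            group[0],
            group=merged_group,
            allele_frequency=min(sum(freqs), 1.0) if freqs else None,
            revel=sum(revels) / len(revels) if revels else None,
            cdna_notation=";".join(cdnas) if cdnas else None,
        ))
    return out


# ---------------------------------------------------------------------------
# TSV interface
#
# Columns: id, position, ref_aa, alt_aa, in_hgmd_dm, in_gnomad, in_sgcd,
# allele_frequency, revel, cdna_notation.  "." marks a missing value.  An
# optional `group` column, when present, overrides the membership-derived
# label (this is how "novel" clinical variants, absent from every database,
# are tagged).

VARIANT_TSV_COLUMNS = [
    "id", "position", "ref_aa", "alt_aa", "in_hgmd_dm", "in_gnomad",
    "in_sgcd", "allele_frequency", "revel", "cdna_notation",
]

_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "t": True, "f": False, "yes": True, "no": False}


def _parse_bool(x: object) -> bool:
    if isinstance(x, bool):
        return x
    s = str(x).strip().lower()
    if s in _BOOL:
        return _BOOL[s]
    raise VariantError(f"cannot interpret {x!r} as a boolean")


def read_variant_tsv(
    source: Union[str, io.TextIOBase],
    numbering: str = "610",
    dedupe: bool = False,
) -> list[MissenseVariant]:
    """Read a variant table, optionally renumbering from the 615 isoform.

    ``numbering`` selects the coordinate system of the *input* positions
    ("610" or "615"); output positions are always 610-isoform.  615-isoform
    positions inside the insertion raise (they have no 610 equivalent).
    """
    if numbering not in ("610", "615"):
        raise VariantError(f"numbering must be '610' or '615', got {numbering!r}")
    df = pd.read_csv(source, sep="\t", dtype=str, na_values=["."],
                     keep_default_na=False)
    missing = [c for c in VARIANT_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise VariantError(f"variant TSV missing columns: {missing}")
    variants = []
    for row in df.itertuples(index=False):
        position = int(row.position)
        if numbering == "615":
            position = renumber_615_to_610(position)
        membership = GroupMembership(
            in_hgmd_dm=_parse_bool(row.in_hgmd_dm),
            in_gnomad=_parse_bool(row.in_gnomad),
            in_sgcd=_parse_bool(row.in_sgcd),
        )
        group = assign_group(membership)
        if "group" in df.columns and isinstance(row.group, str) and row.group:
            group = Group(row.group)
        variants.append(MissenseVariant(
            id=row.id,
            position=position,
            ref_aa=row.ref_aa,
            alt_aa=row.alt_aa,
            group=group,
            allele_frequency=(float(row.allele_frequency)
                              if isinstance(row.allele_frequency, str)
                              and row.allele_frequency else None),
            revel=(float(row.revel)
                   if isinstance(row.revel, str) and row.revel else None),
            cdna_notation=(row.cdna_notation
                           if isinstance(row.cdna_notation, str)
                           and row.cdna_notation else None),
        ))
    if dedupe:
        variants = dedupe_protein_variants(variants)
    return variants


def variants_to_frame(variants: Iterable[MissenseVariant]) -> pd.DataFrame:
    """Tabulate variants (one row each) with the group label resolved."""
    rows = []
    for v in variants:
        rows.append({
            "id": v.id, "position": v.position, "ref_aa": v.ref_aa,
            "alt_aa": v.alt_aa, "group": v.group.value,
            "allele_frequency": v.allele_frequency, "revel": v.revel,
            "cdna_notation": v.cdna_notation,
        })
    return pd.DataFrame(rows)
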