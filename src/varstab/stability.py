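"""ΔΔG bookkeeping: per-structure records, ensemble aggregation, thresholds.

Predicted stability changes come from an external empirical force field
(e.g. FoldX BuildModel) run once per structure chain; positive ΔΔG means the
substitution destabilizes the fold.  A variant's assessment is the mean ΔΔG
over all chains resolving its position — variants covered by no structure
are omitted rather than scored.  The conventional calls are "strongly
destabilizing" above 3 kcal/mol and a more conservative call above
4 kcal/mol; both use a strict inequality here (the configurable choice is
logged at the boundary).  The force field's quoted error of ±0.8 kcal/mol is
carried as an annotation, not propagated statistically.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .variants import CANONICAL_AA, Group, MissenseVariant

log = logging.getLogger(__name__)

#: quoted uncertainty of the external force field's ΔΔG predictions, kcal/mol
FOLDX_ERROR_KCAL_MOL = 0.8

DDG_TSV_COLUMNS = ["structure_id", "chain_id", "position", "ref_aa",
                   "alt_aa", "ddg_kcal_mol"]


class StabilityError(ValueError):
    """Base class for stability-layer errors."""


class DdgParseError(StabilityError):
    """Raised on malformed ΔΔG input tables."""


class RefConflictError(StabilityError):
    """Raised when records disagree on the reference residue at a position."""


@dataclass(frozen=True)
class DdgRecord:
    """One per-structure-chain ΔΔG measurement for one substitution."""

    structure_id: str
    chain_id: str
    position: int
    ref_aa: str
    alt_aa: str
    ddg: float                  # kcal/mol; may be negative (stabilizing)

    def __post_init__(self) -> None:
        if not math.isfinite(self.ddg):
            raise StabilityError(
                f"{self.structure_id}/{self.chain_id} "
                f"{self.ref_aa}{self.position}{self.alt_aa}: non-finite ddg")
        if self.ref_aa not in CANONICAL_AA or self.alt_aa not in CANONICAL_AA:
            raise StabilityError("non-canonical residue in ΔΔG record")

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref_aa, self.alt_aa)


@dataclass
class VariantAssessment:
    """Ensemble-aggregate stability assessment of one variant."""

    variant: MissenseVariant
    mean_ddg: float
    sd_ddg: float
    n_structures: int
    mean_rsa: Optional[float] = None
    buried: Optional[bool] = None
    call_3: bool = False
    call_4: bool = False

    def __post_init__(self) -> None:
        if self.n_structures < 1:
            raise StabilityError("assessment requires at least one record")
        if self.call_4 and not self.call_3:
            raise StabilityError("call_4 implies call_3 (threshold monotonicity)")

    @property
    def key(self) -> tuple[int, str, str]:
        return self.variant.key


def parse_ddg_tsv(source: Union[str, io.TextIOBase]) -> list[DdgRecord]:
    """Read the per-structure ΔΔG table.

    Tab-separated with header ``structure_id, chain_id, position, ref_aa,
    alt_aa, ddg_kcal_mol``; blank lines and ``#`` comments are skipped.
    Malformed rows raise with their line number.
    """
    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            return parse_ddg_tsv(fh)
    if isinstance(source, str):
        source = io.StringIO(source)
    records: list[DdgRecord] = []
    header: Optional[list[str]] = None
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            missing = [c for c in DDG_TSV_COLUMNS if c not in header]
            if missing:
                raise DdgParseError(f"line {lineno}: missing columns {missing}")
            continue
        if len(fields) != len(header):
            raise DdgParseError(
                f"line {lineno}: expected {len(header)} fields, got {len(fields)}")
        row = dict(zip(header, (f.strip() for f in fields)))
        try:
            ddg = float(row["ddg_kcal_mol"])
        except ValueError:
            raise DdgParseError(
                f"line {lineno}: non-numeric ddg {row['ddg_kcal_mol']!r}")
        try:
            records.append(DdgRecord(
                structure_id=row["structure_id"],
                chain_id=row["chain_id"],
                position=int(row["position"]),
                ref_aa=row["ref_aa"],
                alt_aa=row["alt_aa"],
                ddg=ddg,
            ))
        except (ValueError, StabilityError) as exc:
            raise DdgParseError(f"line {lineno}: {exc}")
    return records


def parse_foldx_dif(
    source: Union[str, io.TextIOBase],
    structure_id: str,
    mutant_order: Sequence[tuple[str, int, str]],
    chain_id: str = "A",
) -> list[DdgRecord]:
    """Adapter for FoldX BuildModel ``Dif_*.fxout`` tables.

    Rows are whitespace/tab delimited; the first numeric column after the
    model filename is the total energy difference for the corresponding
    mutant.  ``mutant_order`` lists ``(ref_aa, position, alt_aa)`` in the
    order the mutants were submitted; the row count must match.
    """
    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            return parse_foldx_dif(fh, structure_id, mutant_order, chain_id)
    if isinstance(source, str):
        source = io.StringIO(source)
    totals: list[float] = []
    for raw in source:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.replace("\t", " ").split()
        value = None
        for f in fields:
            try:
                value = float(f)
                break
            except ValueError:
                continue
        if value is None:
            continue        # banner / header line with no numeric field
        totals.append(value)
    if not totals:
        raise DdgParseError(f"{structure_id}: no energy rows in Dif output")
    if len(totals) != len(mutant_order):
        raise DdgParseError(
            f"{structure_id}: {len(totals)} energy rows for "
            f"{len(mutant_order)} expected mutants")
    return [
        DdgRecord(structure_id=structure_id, chain_id=chain_id,
                  position=pos, ref_aa=ref, alt_aa=alt, ddg=ddg)
        for (ref, pos, alt), ddg in zip(mutant_order, totals)
    ]


def classify_stability(mean_ddg: float, threshold: float) -> bool:
    """Strictly-above-threshold ΔΔG counts as destabilizing."""
    if threshold <= 0:
        raise StabilityError("threshold must be positive")
    if mean_ddg == threshold:
        log.info("ΔΔG exactly at threshold %.3g kcal/mol: classified "
                 "not destabilizing (strict inequality)", threshold)
    return mean_ddg > threshold


def aggregate_ddg(
    records: Iterable[DdgRecord],
    variants: Optional[Iterable[MissenseVariant]] = None,
    statistic: str = "mean",
    thresholds: tuple[float, float] = (3.0, 4.0),
) -> list[VariantAssessment]:
    """Aggregate per-structure ΔΔG records into per-variant assessments.

    Per unique ``(position, ref_aa, alt_aa)``: the mean (or, optionally,
    median) and sample SD of ΔΔG over all structure-chain records, and the
    record count as structure coverage.  Variants with no records are simply
    absent — only variants covered by at least one structure are assessed.
    When ``variants`` is supplied, assessments are joined to those records
    (carrying group labels and annotations); otherwise unlabeled stubs are
    created.
    """
    if statistic not in ("mean", "median"):
        raise StabilityError(f"unknown aggregation statistic {statistic!r}")
    by_key: dict[tuple[int, str, str], list[DdgRecord]] = {}
    ref_at_pos: dict[int, str] = {}
    for rec in records:
        seen = ref_at_pos.setdefault(rec.position, rec.ref_aa)
        if seen != rec.ref_aa:
            raise RefConflictError(
                f"position {rec.position}: conflicting reference residues "
                f"{seen!r} vs {rec.ref_aa!r}")
        by_key.setdefault(rec.key, []).append(rec)

    variant_by_key: dict[tuple[int, str, str], MissenseVariant] = {}
    if variants is not None:
        for v in variants:
            variant_by_key[v.key] = v

    lo, hi = min(thresholds), max(thresholds)
    out: list[VariantAssessment] = []
    for key in sorted(by_key):
        values = np.array([r.ddg for r in by_key[key]])
        center = float(np.mean(values) if statistic == "mean"
                       else np.median(values))
        # sample SD (ddof=1); a single record has zero spread by convention
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        pos, ref, alt = key
        variant = variant_by_key.get(key) or MissenseVariant(
            id=f"{ref}{pos}{alt}", position=pos, ref_aa=ref, alt_aa=alt)
        out.append(VariantAssessment(
            variant=variant,
            mean_ddg=center,
            sd_ddg=sd,
            n_structures=len(values),
            call_3=classify_stability(center, lo),
            call_4=classify_stability(center, hi),
        ))
    return out


def attach_rsa(
    assessments: Iterable[VariantAssessment],
    rsa_by_position: Mapping[int, float],
    buried_threshold: float = 0.2,
) -> list[VariantAssessment]:
    """Annotate assessments in place with RSA and burial at their positions."""
    out = []
    for a in assessments:
        rsa = rsa_by_position.get(a.variant.position)
        if rsa is not None:
            a.mean_rsa = float(rsa)
            a.buried = rsa < buried_threshold
        out.append(a)
    return out


def interface_shift(
    ddg_complex: Mapping[tuple[int, str, str], float],
    ddg_isolated: Mapping[tuple[int, str, str], float],
    flag_threshold: float = 3.0,
) -> list[tuple[tuple[int, str, str], float, bool]]:
    """ΔΔΔG = ΔΔG(complex) − ΔΔG(isolated) per variant.

    Large |ΔΔΔG| marks substitutions whose energetic effect depends on the
    bound partner, i.e. likely interface involvement; entries are flagged at
    |ΔΔΔG| ≥ ``flag_threshold``.  Variants present on only one side are
    skipped with a log entry.
    """
    shared = set(ddg_complex) & set(ddg_isolated)
    for key in sorted(set(ddg_complex) ^ set(ddg_isolated)):
        log.info("interface_shift: variant %s present on one side only; skipped",
                 key)
    out = []
    for key in sorted(shared):
        dddg = ddg_complex[key] - ddg_isolated[key]
        out.append((key, dddg, abs(dddg) >= flag_threshold))
    return out


def assessments_to_frame(assessments: Iterable[VariantAssessment]) -> pd.DataFrame:
    """Tabulate assessments in the assessment-TSV column layout."""
    rows = []
    for a in assessments:
        rows.append({
            "position": a.variant.position,
            "ref_aa": a.variant.ref_aa,
            "alt_aa": a.variant.alt_aa,
            "group": a.variant.group.value,
            "mean_ddg": a.mean_ddg,
            "sd_ddg": a.sd_ddg,
            "n_structures": a.n_structures,
            "mean_rsa": a.mean_rsa,
            "buried": a.buried,
            "destabilizing_3": a.call_3,
            "destabilizing_4": a.call_4,
        })
    return pd.DataFrame(rows)
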