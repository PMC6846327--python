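"""End-to-end orchestration: variant assessment and interface analysis runs.

``run_assess`` ties the layers together: read and deduplicate variants,
aggregate per-structure ΔΔG records into per-variant assessments, annotate
RSA/burial (from a precomputed RSA table or from PDB structures), then emit
the per-variant assessment table and a metrics report (threshold metrics at
3 and 4 kcal/mol, combined ΔΔG+REVEL rules, ROC/AUC per scorer, group
summaries with t-tests, a frequency-vs-ΔΔG table and a multiallelic-site
comparison).  ``run_interface`` compares complexed against isolated-chain
inputs per position (ΔRSA) and per variant (ΔΔΔG).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import sasa as sasa_mod
from . import stability, stats, structures, variants as variants_mod

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage cannot proceed."""


@dataclass
class RunConfig:
    """Inputs, thresholds and outputs for one assessment run."""

    variants_path: str
    ddg_path: str
    rsa_path: Optional[str] = None
    structure_paths: Sequence[str] = field(default_factory=list)
    ddg_threshold: float = 3.0
    ddg_threshold_strict: float = 4.0
    rsa_threshold: float = 0.2
    revel_threshold: float = 0.7
    combine_mode: str = "and"
    numbering: str = "610"
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("ddg_threshold", "ddg_threshold_strict", "rsa_threshold",
                     "revel_threshold"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"{name} must be positive")


def _rsa_by_position(cfg: RunConfig) -> Optional[dict[int, float]]:
    if cfg.rsa_path:
        profile = sasa_mod.RsaProfile.from_tsv(cfg.rsa_path,
                                               buried_threshold=cfg.rsa_threshold)
        return profile.rsa
    if cfg.structure_paths:
        members = []
        for path in cfg.structure_paths:
            s = structures.read_pdb(path, structure_id=os.path.basename(path))
            members.append((s, sasa_mod.shrake_rupley(s)))
        profile = sasa_mod.rsa_profile(members,
                                       buried_threshold=cfg.rsa_threshold)
        return profile.rsa
    return None


def _threshold_report(scored: list[tuple[float, str]],
                      revel_by_key: dict, keys: list,
                      threshold: float, cfg: RunConfig) -> dict:
    counts = stats.confusion(scored, threshold)
    report = {"confusion": dataclasses.asdict(counts),
              "metrics": stats.metrics(counts)}
    # combined ΔΔG + REVEL rule, evaluated only where a label exists
    tp = fp = tn = fn = 0
    for (value, label), key in zip(scored, keys):
        call = stats.combined_rule(value, revel_by_key.get(key), threshold,
                                   cfg.revel_threshold, mode=cfg.combine_mode)
        if label == stats.POSITIVE_LABEL:
            tp, fn = tp + call, fn + (not call)
        else:
            fp, tn = fp + call, tn + (not call)
    combined = stats.ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    report["combined_revel"] = {
        "mode": cfg.combine_mode,
        "revel_threshold": cfg.revel_threshold,
        "confusion": dataclasses.asdict(combined),
        "metrics": stats.metrics(combined),
    }
    return report


def run_assess(cfg: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Assess every covered variant and evaluate cohort-level classification.

    Returns ``(assessment table, metrics report)``; when ``cfg.out_dir`` is
    set they are also written as ``assessment.tsv`` and ``metrics.json``
    (plus ``roc_<scorer>.tsv`` tables).
    """
    variant_list = variants_mod.read_variant_tsv(cfg.variants_path,
                                                 numbering=cfg.numbering,
                                                 dedupe=True)
    records = stability.parse_ddg_tsv(cfg.ddg_path)
    assessments = stability.aggregate_ddg(
        records, variants=variant_list,
        thresholds=(cfg.ddg_threshold, cfg.ddg_threshold_strict))
    rsa_by_pos = _rsa_by_position(cfg)
    if rsa_by_pos is not None:
        stability.attach_rsa(assessments, rsa_by_pos,
                             buried_threshold=cfg.rsa_threshold)
    frame = stability.assessments_to_frame(assessments)
    if frame.empty:
        raise PipelineError("no variant is covered by any ΔΔG record")

    labelled = [a for a in assessments
                if a.variant.group in (variants_mod.Group.PATHOGENIC,
                                       variants_mod.Group.BENIGN)]
    scored = [(a.mean_ddg, a.variant.group.value) for a in labelled]
    keys = [a.key for a in labelled]
    revel_by_key = {a.key: a.variant.revel for a in labelled}

    report: dict = {
        "n_assessed": len(assessments),
        "n_labelled": len(labelled),
        "foldx_error_kcal_mol": stability.FOLDX_ERROR_KCAL_MOL,
        "thresholds": {},
        "roc": {},
        "group_summaries": {},
    }
    for thr in (cfg.ddg_threshold, cfg.ddg_threshold_strict):
        report["thresholds"][f"{thr:g}"] = _threshold_report(
            scored, revel_by_key, keys, thr, cfg)

    roc_tables = {}
    roc_curve = stats.roc(scored)
    report["roc"]["ddg"] = {"auc": roc_curve.auc}
    roc_tables["ddg"] = roc_curve
    revel_scored = [(a.variant.revel, a.variant.group.value)
                    for a in labelled if a.variant.revel is not None]
    if revel_scored and {lab for _, lab in revel_scored} == {
            stats.POSITIVE_LABEL, stats.NEGATIVE_LABEL}:
        revel_curve = stats.roc(revel_scored)
        report["roc"]["revel"] = {"auc": revel_curve.auc}
        roc_tables["revel"] = revel_curve

    # group summaries over mean ΔΔG, and burial fractions where RSA is known
    by_group: dict[str, list[float]] = {}
    for a in assessments:
        by_group.setdefault(a.variant.group.value, []).append(a.mean_ddg)
    summary = stats.group_summary(by_group)
    report["group_summaries"]["mean_ddg"] = {
        "groups": summary.groups, "p_value": summary.p_value,
        "test": summary.test,
    }
    buried_known = [a for a in assessments if a.buried is not None]
    if buried_known:
        burial = {}
        for grp in sorted({a.variant.group.value for a in buried_known}):
            members = [a for a in buried_known if a.variant.group.value == grp]
            burial[grp] = {
                "n": len(members),
                "buried_fraction": sum(a.buried for a in members) / len(members),
            }
        report["group_summaries"]["burial"] = burial

    report["frequency_vs_ddg"] = _frequency_table(assessments)
    report["multiallelic"] = _multiallelic_table(labelled)

    if cfg.out_dir:
        os.makedirs(cfg.out_dir, exist_ok=True)
        frame.to_csv(os.path.join(cfg.out_dir, "assessment.tsv"), sep="\t",
                     index=False, na_rep=".", float_format="%.6g")
        with open(os.path.join(cfg.out_dir, "metrics.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        for name, curve in roc_tables.items():
            rows = pd.DataFrame(
                {"threshold": curve.thresholds,
                 "fpr": [p[0] for p in curve.points],
                 "tpr": [p[1] for p in curve.points]})
            rows.to_csv(os.path.join(cfg.out_dir, f"roc_{name}.tsv"),
                        sep="\t", index=False, float_format="%.6g")
    return frame, report


def _frequency_table(assessments) -> list[dict]:
    """Population frequency against mean ΔΔG for variants carrying one."""
    rows = []
    for a in assessments:
        af = a.variant.allele_frequency
        if af is None or (isinstance(af, float) and math.isnan(af)):
            continue
        rows.append({
            "variant": a.variant.label,
            "group": a.variant.group.value,
            "allele_frequency": af,
            "mean_ddg": a.mean_ddg,
        })
    rows.sort(key=lambda r: -r["allele_frequency"])
    return rows


def _multiallelic_table(labelled) -> dict:
    """Positions carrying both benign and pathogenic substitutions.

    Reports, per shared position, the mean ΔΔG of each co-occurring group,
    plus a group-level t-test over all co-occurring variants.
    """
    by_pos: dict[int, dict[str, list[float]]] = {}
    for a in labelled:
        by_pos.setdefault(a.variant.position, {}).setdefault(
            a.variant.group.value, []).append(a.mean_ddg)
    shared = {pos: groups for pos, groups in by_pos.items()
              if len(groups) == 2}
    sites = [{
        "position": pos,
        "mean_ddg_pathogenic": float(np.mean(groups[stats.POSITIVE_LABEL])),
        "mean_ddg_benign": float(np.mean(groups[stats.NEGATIVE_LABEL])),
        "n_pathogenic": len(groups[stats.POSITIVE_LABEL]),
        "n_benign": len(groups[stats.NEGATIVE_LABEL]),
    } for pos, groups in sorted(shared.items())]
    out: dict = {"n_sites": len(sites), "sites": sites}
    path_all = [v for g in shared.values() for v in g[stats.POSITIVE_LABEL]]
    ben_all = [v for g in shared.values() for v in g[stats.NEGATIVE_LABEL]]
    if len(path_all) >= 2 and len(ben_all) >= 2:
        _, _, p = stats.t_test_two_sample(path_all, ben_all)
        out["group_means"] = {"pathogenic": float(np.mean(path_all)),
                              "benign": float(np.mean(ben_all))}
        out["p_value"] = p
    return out


def run_interface(
    ddg_complex_path: str,
    ddg_isolated_path: str,
    rsa_complex_path: Optional[str] = None,
    rsa_isolated_path: Optional[str] = None,
    flag_threshold: float = 3.0,
    out_path: Optional[str] = None,
) -> pd.DataFrame:
    """Interface analysis: per-variant ΔΔΔG (and per-position ΔRSA).

    ΔΔΔG = mean ΔΔG in the complex minus in the isolated chain; entries with
    |ΔΔΔG| ≥ ``flag_threshold`` are flagged as likely interface variants.
    """
    cx = stability.aggregate_ddg(stability.parse_ddg_tsv(ddg_complex_path))
    iso = stability.aggregate_ddg(stability.parse_ddg_tsv(ddg_isolated_path))
    cx_map = {a.key: a.mean_ddg for a in cx}
    iso_map = {a.key: a.mean_ddg for a in iso}
    if not set(cx_map) & set(iso_map):
        raise PipelineError(
            "complexed and isolated ΔΔG inputs share no variants")
    shifts = stability.interface_shift(cx_map, iso_map,
                                       flag_threshold=flag_threshold)
    drsa: dict[int, float] = {}
    if rsa_complex_path and rsa_isolated_path:
        drsa = sasa_mod.delta_rsa(
            sasa_mod.RsaProfile.from_tsv(rsa_complex_path),
            sasa_mod.RsaProfile.from_tsv(rsa_isolated_path))
    rows = []
    for (pos, ref, alt), dddg, flagged in shifts:
        rows.append({
            "position": pos, "ref_aa": ref, "alt_aa": alt,
            "ddg_complex": cx_map[(pos, ref, alt)],
            "ddg_isolated": iso_map[(pos, ref, alt)],
            "dddg": dddg, "flagged": flagged,
            "delta_rsa": drsa.get(pos),
        })
    frame = pd.DataFrame(rows)
    if out_path:
        frame.to_csv(out_path, sep="\t", index=False, na_rep=".",
                     float_format="%.6g")
    return frame
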