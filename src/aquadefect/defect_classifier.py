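"""Rule-based classification of mutation-induced structural defects.

Evidence from the upstream analyses (topology location, salt bridges,
proline placement, steric-clash scores, contact losses split by scope,
pore lining and profile narrowing) is combined by a fixed-precedence rule
cascade into one of four defect categories:

1. **signal loss** — C-tail site near a phosphosite or breaking a C-tail
   salt bridge (trafficking-signal defect; no transmembrane context);
2. **monomer folding** — helix-breaking proline, or substantial
   intra-monomer steric strain, or loss of intra-monomer packing contacts;
3. **tetramer assembly** — inter-monomer contact loss or clash;
4. **pore features** — pore-lining site whose mutation narrows the profile.

Folding outranks assembly outranks pore: a pore-lining residue whose
substitution also jams against its own monomer is a folding defect, not a
mere narrowing.  ``classify`` is a pure function of (evidence, thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .interactions import detect_clashes, diff_contacts, proline_in_helix, salt_bridges
from .mutator import MutationSpec, PlacementParams, mutate_residue
from .pore_logo import pore_lining_residues
from .pore_profiler import (PoreAxis, PoreProfile, ProfilerParams,
                            compare_profiles, compute_profile, estimate_axis)
from .structure import Structure, TopologyAnnotation

__all__ = [
    "Evidence",
    "DefectReport",
    "ClassifierThresholds",
    "ProteinContext",
    "gather_evidence",
    "classify",
    "batch_report",
]


@dataclass
class ClassifierThresholds:
    theta_clash: float = 0.25      # Å² summed squared overlap (~one 0.5 Å clash)
    theta_pore: float = 0.3        # Å sustained narrowing
    min_run: int = 3               # consecutive slices for a narrowing region
    phosphosite_window: int = 4    # residues
    contact_loss_min: int = 2
    lining_margin: float = 1.4     # Å, water-probe contact

    def __post_init__(self) -> None:
        if min(self.theta_clash, self.theta_pore) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class Evidence:
    location_label: str = ""
    is_c_tail: bool = False
    near_phosphosite: bool = False
    lost_salt_bridge_c_tail: bool = False
    pro_in_helix: bool = False
    intra_clash_score: float = 0.0
    intra_contacts_lost: int = 0
    inter_contacts_lost: int = 0
    inter_clash_score: float = 0.0
    is_pore_lining: bool = False
    max_narrowing: float = 0.0
    narrowing_side: str = "none"   # cytoplasmic | extracellular | none

    def __post_init__(self) -> None:
        if (self.intra_clash_score < 0 or self.inter_clash_score < 0
                or self.intra_contacts_lost < 0 or self.inter_contacts_lost < 0):
            raise ValueError("scores and counts must be non-negative")


@dataclass
class DefectReport:
    mutation: Optional[MutationSpec]
    category: str
    rationale: List[str]
    evidence: Evidence


def _clash_scores_by_scope(structure: Structure, key) -> Dict[str, float]:
    """Summed squared vdW overlap of the site residue, split by scope."""
    scores = {"intra_monomer": 0.0, "inter_monomer": 0.0}
    for c in detect_clashes(structure, key, clash_threshold=1e-9):
        scores[c.scope] += c.overlap ** 2
    return scores


def gather_evidence(wt: Structure, mut: Structure, spec: MutationSpec,
                    annotation: TopologyAnnotation,
                    wt_profile: Optional[PoreProfile] = None,
                    mut_profile: Optional[PoreProfile] = None,
                    thresholds: Optional[ClassifierThresholds] = None,
                    lining_numbers: Optional[Set[int]] = None) -> Evidence:
    """Populate the evidence record for one mutation.

    Clash scores are mutation-induced strain: the wild-type site's own
    overlap score is subtracted (clipped at zero), so wt-vs-wt evidence is
    identically zero.  Pore evidence requires profiles; when they are
    omitted, the pore fields stay at their neutral defaults.
    """
    th = thresholds or ClassifierThresholds()
    key = (spec.chain, spec.position, spec.icode)
    label = annotation.label_of(spec.position)
    is_c_tail = label == "C-ter"
    near_phos = any(abs(p - spec.position) <= th.phosphosite_window
                    for p in annotation.phosphosites)

    wt_sb = {(c.res_a, c.res_b) for c in salt_bridges(wt) if key in (c.res_a, c.res_b)}
    mut_sb = {(c.res_a, c.res_b) for c in salt_bridges(mut) if key in (c.res_a, c.res_b)}
    lost_sb = bool(wt_sb - mut_sb)

    wt_scores = _clash_scores_by_scope(wt, key)
    mut_scores = _clash_scores_by_scope(mut, key)
    intra_clash = max(0.0, mut_scores["intra_monomer"] - wt_scores["intra_monomer"])
    inter_clash = max(0.0, mut_scores["inter_monomer"] - wt_scores["inter_monomer"])

    diff = diff_contacts(wt, mut, key, kinds=("hydrophobic", "salt_bridge"))
    intra_lost = sum(1 for c in diff.lost if c.scope == "intra_monomer")
    inter_lost = sum(1 for c in diff.lost if c.scope == "inter_monomer")

    is_lining = False
    if lining_numbers is not None:
        is_lining = spec.position in lining_numbers
    elif wt_profile is not None:
        lining = pore_lining_residues(wt, wt_profile, margin=th.lining_margin)
        is_lining = any(r.number == spec.position and r.chain == spec.chain
                        for r in lining)

    max_narrow, side = 0.0, "none"
    if wt_profile is not None and mut_profile is not None:
        delta = compare_profiles(wt_profile, mut_profile,
                                 threshold=th.theta_pore, min_run=th.min_run)
        if delta.narrowing_regions:
            worst = max(delta.narrowing_regions, key=lambda r: r.max_reduction)
            max_narrow, side = worst.max_reduction, worst.side

    return Evidence(
        location_label=label,
        is_c_tail=is_c_tail,
        near_phosphosite=near_phos,
        lost_salt_bridge_c_tail=is_c_tail and lost_sb,
        pro_in_helix=proline_in_helix(annotation, spec),
        intra_clash_score=intra_clash,
        intra_contacts_lost=intra_lost,
        inter_contacts_lost=inter_lost,
        inter_clash_score=inter_clash,
        is_pore_lining=is_lining,
        max_narrowing=max_narrow,
        narrowing_side=side,
    )


def classify(evidence: Evidence,
             thresholds: Optional[ClassifierThresholds] = None,
             mutation: Optional[MutationSpec] = None) -> DefectReport:
    """Apply the fixed-precedence rule cascade to one evidence record."""
    th = thresholds or ClassifierThresholds()
    rationale: List[str] = []

    if evidence.is_c_tail and (evidence.near_phosphosite
                               or evidence.lost_salt_bridge_c_tail):
        if evidence.near_phosphosite:
            rationale.append("C-tail site within the phosphosite window")
        if evidence.lost_salt_bridge_c_tail:
            rationale.append("C-tail salt bridge lost on mutation")
        return DefectReport(mutation, "signal loss", rationale, evidence)

    if evidence.pro_in_helix:
        rationale.append("proline introduced inside a helix")
    if evidence.intra_clash_score >= th.theta_clash:
        rationale.append(
            f"intra-monomer clash score {evidence.intra_clash_score:.2f} "
            f">= {th.theta_clash}")
    if evidence.intra_contacts_lost >= th.contact_loss_min:
        rationale.append(
            f"{evidence.intra_contacts_lost} intra-monomer contacts lost")
    if rationale:
        return DefectReport(mutation, "monomer folding", rationale, evidence)

    if evidence.inter_contacts_lost >= th.contact_loss_min:
        rationale.append(
            f"{evidence.inter_contacts_lost} inter-monomer contacts lost")
    if evidence.inter_clash_score >= th.theta_clash:
        rationale.append(
            f"inter-monomer clash score {evidence.inter_clash_score:.2f} "
            f">= {th.theta_clash}")
    if rationale:
        return DefectReport(mutation, "tetramer assembly", rationale, evidence)

    if evidence.is_pore_lining and evidence.max_narrowing >= th.theta_pore:
        rationale.append(
            f"pore-lining site; {evidence.narrowing_side} narrowing "
            f"{evidence.max_narrowing:.2f} Å")
        return DefectReport(mutation, "pore features", rationale, evidence)

    return DefectReport(mutation, "unclassified", ["no rule fired"], evidence)


@dataclass
class ProteinContext:
    """Everything needed to analyse one protein's mutations."""

    structure: Structure
    annotation: TopologyAnnotation
    chain: str = "A"
    axis: Optional[PoreAxis] = None
    profiler: ProfilerParams = field(default_factory=ProfilerParams)
    placement: PlacementParams = field(default_factory=PlacementParams)
    with_profiles: bool = True


def batch_report(records, contexts: Dict[str, ProteinContext],
                 thresholds: Optional[ClassifierThresholds] = None
                 ) -> Tuple[pd.DataFrame, Dict[str, object]]:
    """Classify every record with available structure; tabulate agreement.

    Per-record failures are collected into the table (category ``error``)
    and the run continues.  Returns (table, stats) where stats holds the
    number compared against catalog labels and the number agreeing.
    """
    th = thresholds or ClassifierThresholds()
    rows = []
    profile_cache: Dict[str, tuple] = {}
    for rec in records:
        ctx = contexts.get(rec.protein)
        if ctx is None:
            rows.append({"protein": rec.protein, "mutation": rec.mutation,
                         "category": "no-structure", "expected": rec.defect,
                         "agree": None, "rationale": ""})
            continue
        try:
            spec = MutationSpec(chain=ctx.chain, position=rec.position,
                                wt_aa=rec.wt_aa, mut_aa=rec.mut_aa)
            mut_st = mutate_residue(ctx.structure, spec, ctx.placement)
            wt_profile = mut_profile = None
            lining_numbers = None
            if ctx.with_profiles:
                if rec.protein not in profile_cache:
                    axis = ctx.axis or estimate_axis(ctx.structure, ctx.annotation)
                    wt_p = compute_profile(ctx.structure, axis, ctx.profiler,
                                           ctx.annotation)
                    lining = pore_lining_residues(ctx.structure, wt_p,
                                                  margin=th.lining_margin)
                    profile_cache[rec.protein] = (
                        axis, wt_p, {r.number for r in lining})
                axis, wt_profile, lining_numbers = profile_cache[rec.protein]
                if rec.position in lining_numbers:
                    mut_profile = compute_profile(mut_st, axis, ctx.profiler,
                                                  ctx.annotation)
                else:
                    mut_profile = wt_profile
            ev = gather_evidence(ctx.structure, mut_st, spec, ctx.annotation,
                                 wt_profile, mut_profile, th,
                                 lining_numbers=lining_numbers)
            report = classify(ev, th, spec)
            agree = (report.category == rec.defect) if rec.defect else None
            rows.append({"protein": rec.protein, "mutation": rec.mutation,
                         "category": report.category, "expected": rec.defect,
                         "agree": agree,
                         "rationale": "; ".join(report.rationale)})
        except Exception as exc:  # noqa: BLE001 - per-record failures collected
            rows.append({"protein": rec.protein, "mutation": rec.mutation,
                         "category": "error", "expected": rec.defect,
                         "agree": None, "rationale": str(exc)})
    table = pd.DataFrame(rows)
    compared = table["agree"].notna().sum() if len(table) else 0
    agreed = int((table["agree"] == True).sum()) if len(table) else 0  # noqa: E712
    stats = {"n_records": len(rows), "n_compared": int(compared),
             "n_agree": agreed}
    return table, stats
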