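"""Rule cascade: purity, precedence, evidence gathering, planted recovery."""

import dataclasses

import numpy as np
import pytest

from aquadefect.defect_classifier import (ClassifierThresholds, Evidence,
                                          ProteinContext, batch_report,
                                          classify, gather_evidence)
from aquadefect.mutator import MutationSpec, PlacementParams, mutate_residue
from aquadefect.pore_profiler import ProfilerParams
from aquadefect.structure import TopologyAnnotation
from aquadefect.synthetic import (make_bundle_channel, make_interface_tetramer,
                                  make_tailed_bundle)
from aquadefect.variant_catalog import SAPRecord

from conftest import salt_bridge_pair


PORE_EVIDENCE = Evidence(location_label="H5", is_pore_lining=True,
                         max_narrowing=1.2, narrowing_side="extracellular")


class TestClassifyRules:
    def test_empty_evidence_is_unclassified(self):
        assert classify(Evidence()).category == "unclassified"

    def test_pure_function_same_input_same_output(self):
        a = classify(PORE_EVIDENCE)
        b = classify(PORE_EVIDENCE)
        assert a.category == b.category and a.rationale == b.rationale

    def test_pore_lining_narrowing_is_pore_features(self):
        assert classify(PORE_EVIDENCE).category == "pore features"

    def test_intra_clash_overrides_pore_narrowing(self):
        # a pore-lining residue that also jams against its own monomer is a
        # folding defect, never the reverse
        ev = dataclasses.replace(PORE_EVIDENCE, intra_clash_score=0.9)
        assert classify(ev).category == "monomer folding"

    def test_c_tail_signal_loss_outranks_everything(self):
        ev = dataclasses.replace(PORE_EVIDENCE, is_c_tail=True,
                                 near_phosphosite=True, intra_clash_score=2.0)
        assert classify(ev).category == "signal loss"

    def test_inter_contact_loss_is_tetramer_assembly(self):
        ev = Evidence(location_label="H1", inter_contacts_lost=2)
        assert classify(ev).category == "tetramer assembly"

    def test_folding_outranks_assembly(self):
        ev = Evidence(location_label="H1", inter_contacts_lost=3,
                      pro_in_helix=True)
        assert classify(ev).category == "monomer folding"

    def test_lowering_theta_pore_never_flips_folding_or_signal(self):
        folding = Evidence(location_label="H2", pro_in_helix=True,
                           is_pore_lining=True, max_narrowing=5.0)
        signal = Evidence(location_label="C-ter", is_c_tail=True,
                          near_phosphosite=True, is_pore_lining=True,
                          max_narrowing=5.0)
        for theta in (0.3, 0.05, 0.001):
            th = ClassifierThresholds(theta_pore=theta)
            assert classify(folding, th).category == "monomer folding"
            assert classify(signal, th).category == "signal loss"

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            Evidence(intra_clash_score=-1.0)

    def test_nonpositive_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ClassifierThresholds(theta_clash=0.0)


class TestGatherEvidence:
    def test_wt_vs_wt_evidence_is_neutral(self, bundle6, bundle_annotation):
        spec = MutationSpec("A", 110, "A", "A")
        ev = gather_evidence(bundle6, bundle6.copy(), spec, bundle_annotation)
        assert ev.intra_clash_score == 0.0
        assert ev.inter_clash_score == 0.0
        assert ev.intra_contacts_lost == 0
        assert ev.inter_contacts_lost == 0
        assert not ev.pro_in_helix

    def test_c_tail_salt_bridge_loss_detected(self):
        st = salt_bridge_pair(separation=3.0)
        ann = TopologyAnnotation(c_tail_start=700)
        spec = MutationSpec("A", 704, "R", "L")
        mut = mutate_residue(st, spec)
        ev = gather_evidence(st, mut, spec, ann)
        assert ev.is_c_tail
        assert ev.lost_salt_bridge_c_tail
        assert classify(ev).category == "signal loss"

    def test_interface_mutation_populates_inter_loss(self, interface_tetramer):
        ann = TopologyAnnotation(helix_ranges={"H1": (1, 18), "H2": (101, 118)})
        spec = MutationSpec("A", 109, "L", "V")
        mut = mutate_residue(interface_tetramer, spec)
        ev = gather_evidence(interface_tetramer, mut, spec, ann)
        assert ev.inter_contacts_lost >= 2
        assert ev.intra_clash_score < 0.25


class TestPlantedDefectRecovery:
    """End-to-end: each planted synthetic defect maps to its category."""

    def test_pore_narrowing_recovered(self, bundle_annotation):
        from aquadefect.pore_profiler import compute_profile, estimate_axis
        wt = make_bundle_channel(6, 9.0, 18, facing_residue=(0, 9, "G"))
        axis = estimate_axis(wt)
        params = ProfilerParams(seed=3)
        spec = MutationSpec("A", 10, "G", "W")
        mut = mutate_residue(wt, spec)
        ev = gather_evidence(wt, mut, spec, bundle_annotation,
                             compute_profile(wt, axis, params),
                             compute_profile(mut, axis, params))
        assert classify(ev, mutation=spec).category == "pore features"

    def test_helix_proline_recovered(self, bundle6, bundle_annotation):
        spec = MutationSpec("A", 209, "A", "P")
        mut = mutate_residue(bundle6, spec)
        ev = gather_evidence(bundle6, mut, spec, bundle_annotation)
        assert classify(ev, mutation=spec).category == "monomer folding"

    def test_interface_loss_recovered(self, interface_tetramer):
        ann = TopologyAnnotation(helix_ranges={"H1": (1, 18), "H2": (101, 118)})
        spec = MutationSpec("A", 109, "L", "V")
        mut = mutate_residue(interface_tetramer, spec)
        ev = gather_evidence(interface_tetramer, mut, spec, ann)
        assert classify(ev, mutation=spec).category == "tetramer assembly"

    def test_tail_phosphosite_recovered(self, tailed_bundle, tail_annotation):
        spec = MutationSpec("A", 704, "R", "L")
        mut = mutate_residue(tailed_bundle, spec)
        ev = gather_evidence(tailed_bundle, mut, spec, tail_annotation)
        assert classify(ev, mutation=spec).category == "signal loss"


class TestBatchReport:
    def test_empty_records_give_empty_table(self):
        table, stats = batch_report([], {})
        assert len(table) == 0
        assert stats["n_records"] == 0

    def test_missing_structure_marked_not_errored(self):
        recs = [SAPRecord("AQP9", "A", 5, "V", "x", defect="pore features")]
        table, stats = batch_report(recs, {})
        assert list(table["category"]) == ["no-structure"]
        assert stats["n_compared"] == 0

    def test_per_record_failure_collected_and_run_continues(
            self, tailed_bundle, tail_annotation):
        recs = [
            SAPRecord("SYN", "W", 704, "G", "x"),          # wrong wild type
            SAPRecord("SYN", "R", 704, "L", "x",
                      defect="signal loss"),
        ]
        ctx = ProteinContext(structure=tailed_bundle,
                             annotation=tail_annotation, with_profiles=False)
        table, stats = batch_report(recs, {"SYN": ctx})
        assert list(table["category"])[0] == "error"
        assert list(table["category"])[1] == "signal loss"
        assert stats["n_agree"] == 1

    def test_planted_catalog_fully_recovered(self, tailed_bundle,
                                             tail_annotation,
                                             interface_tetramer):
        tet_ann = TopologyAnnotation(
            helix_ranges={"H1": (1, 18), "H2": (101, 118)})
        records = [
            SAPRecord("TAIL", "R", 704, "L", "x", defect="signal loss"),
            SAPRecord("TET", "L", 109, "V", "x", defect="tetramer assembly"),
            SAPRecord("TET", "A", 5, "P", "x", defect="monomer folding"),
        ]
        contexts = {
            "TAIL": ProteinContext(structure=tailed_bundle,
                                   annotation=tail_annotation,
                                   with_profiles=False),
            "TET": ProteinContext(structure=interface_tetramer,
                                  annotation=tet_ann, with_profiles=False),
        }
        table, stats = batch_report(records, contexts)
        assert stats["n_compared"] == 3
        assert stats["n_agree"] == 3

    def test_reports_byte_identical_for_fixed_seed(self, tailed_bundle,
                                                   tail_annotation):
        recs = [SAPRecord("SYN", "R", 704, "L", "x", defect="signal loss")]
        ctx = ProteinContext(structure=tailed_bundle,
                             annotation=tail_annotation,
                             profiler=ProfilerParams(seed=9),
                             placement=PlacementParams(seed=9),
                             with_profiles=False)
        a, _ = batch_report(recs, {"SYN": ctx})
        b, _ = batch_report(recs, {"SYN": ctx})
        assert a.to_csv(sep="\t") == b.to_csv(sep="\t")
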