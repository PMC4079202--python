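"""ORF-disruption detection, sharing classification, loss dating."""

import numpy as np
import pytest

from genedecay.core import CodonAlignment, SpeciesManifest, SpeciesTree
from genedecay.errors import ManifestError
from genedecay.orf import (
    DisruptionKind,
    SharingClass,
    call_gene_status,
    detect_disruptions,
    group_and_classify,
    infer_loss_branch,
    status_matrix_row,
)
from oracles import naive_disruption_scan, naive_mrca

MANIFEST = SpeciesManifest(
    clades={
        "Mouse": "outgroup", "SpA": "toothed", "SpB": "toothed",
        "SpC": "baleen", "SpD": "baleen",
    },
    genes={"G1": {"Mouse": "+", "SpA": "P", "SpB": "P", "SpC": "P", "SpD": "-"}},
)

REF = "ATGGCCAAATTTGGGCCCAAAGAGTTTTAA"  # 10 codons, terminal TAA


def _aln(**rows):
    records = [("Mouse", REF)] + [(k, v) for k, v in rows.items()]
    return CodonAlignment(records=records, reference_id="Mouse")


class TestDetect:
    def test_species_identical_to_reference_yields_nothing(self):
        res = detect_disruptions(_aln(SpA=REF))
        assert res.disruptions == []

    def test_single_base_deletion(self):
        spa = REF[:6] + "-" + REF[7:]
        res = detect_disruptions(_aln(SpA=spa))
        assert len(res.disruptions) == 1
        d = res.disruptions[0]
        assert d.kind is DisruptionKind.FRAMESHIFT_DELETION
        assert (d.ref_start, d.length) == (7, 1)

    def test_premature_stop_in_reference_frame(self):
        spb = REF[:9] + "TGA" + REF[12:]
        res = detect_disruptions(_aln(SpB=spb))
        assert [d.kind for d in res.disruptions] == [DisruptionKind.PREMATURE_STOP]
        assert res.disruptions[0].ref_start == 10

    def test_reference_terminal_stop_not_reported(self):
        # the reference's own TAA at codon 10 is shared by SpA: not premature
        res = detect_disruptions(_aln(SpA=REF))
        assert res.disruptions == []

    def test_in_frame_deletion_is_annotation_not_disruption(self):
        spa = REF[:6] + "---" + REF[9:]
        res = detect_disruptions(_aln(SpA=spa))
        assert res.disruptions == []
        assert [a.kind for a in res.annotations] == ["inframe_deletion"]

    def test_insertion_against_gapped_reference(self):
        ref = REF[:6] + "--" + REF[6:]
        spa = REF[:6] + "GT" + REF[6:]
        aln = CodonAlignment(records=[("Mouse", ref), ("SpA", spa)], reference_id="Mouse")
        res = detect_disruptions(aln)
        assert len(res.disruptions) == 1
        d = res.disruptions[0]
        assert d.kind is DisruptionKind.FRAMESHIFT_INSERTION
        assert (d.ref_start, d.length) == (6, 2)

    def test_codon_with_n_skipped_for_stop_detection(self):
        spb = REF[:9] + "TGN" + REF[12:]
        res = detect_disruptions(_aln(SpB=spb))
        assert res.disruptions == []

    def test_manifest_conflict_for_absent_species(self):
        with pytest.raises(ManifestError):
            detect_disruptions(_aln(SpD=REF), manifest=MANIFEST, gene="G1")

    def test_adding_identical_species_only_extends_carriers(self):
        spa = REF[:6] + "-" + REF[7:]
        res1 = detect_disruptions(_aln(SpA=spa))
        res2 = detect_disruptions(_aln(SpA=spa, SpB=spa))
        coords1 = {(d.kind, d.ref_start, d.length) for d in res1.disruptions}
        coords2 = {(d.kind, d.ref_start, d.length) for d in res2.disruptions}
        assert coords1 == coords2

    def test_matches_naive_scanner_on_random_alignments(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        for _ in range(25):
            n_codons = 8
            ref = "".join(rng.choice(bases, 3 * n_codons))
            # avoid internal stops in the reference scan window edge cases:
            sp = list(ref)
            for _ in range(rng.integers(1, 5)):
                i = int(rng.integers(0, len(sp)))
                if rng.random() < 0.5:
                    sp[i] = "-"
                else:
                    sp[i] = str(rng.choice(bases))
            sp = "".join(sp)
            aln = CodonAlignment(records=[("R", ref), ("S", sp)], reference_id="R")
            got = {
                (d.kind.value, d.ref_start, d.length)
                for d in detect_disruptions(aln).disruptions
            }
            assert got == naive_disruption_scan(ref, sp)


class TestGroupingAndStatus:
    def test_shared_across_clades_is_class_s(self):
        spa = REF[:6] + "-" + REF[7:]
        res = detect_disruptions(_aln(SpA=spa, SpC=spa))
        grouped, _ = group_and_classify(res.disruptions, MANIFEST)
        assert len(grouped) == 1
        assert grouped[0].sharing is SharingClass.S
        assert grouped[0].disruption.carriers == {"SpA", "SpC"}

    def test_baleen_only_stop_is_s_hash(self):
        spc = REF[:9] + "TGA" + REF[12:]
        res = detect_disruptions(_aln(SpC=spc, SpD=spc))
        manifest = SpeciesManifest(clades=dict(MANIFEST.clades))
        grouped, _ = group_and_classify(res.disruptions, manifest)
        assert grouped[0].sharing is SharingClass.S_HASH

    def test_toothed_only_is_s_star_and_single_is_u(self):
        spa = REF[:6] + "-" + REF[7:]
        res = detect_disruptions(_aln(SpA=spa, SpB=spa))
        grouped, _ = group_and_classify(res.disruptions, MANIFEST)
        assert grouped[0].sharing is SharingClass.S_STAR
        res_u = detect_disruptions(_aln(SpA=spa))
        grouped_u, _ = group_and_classify(res_u.disruptions, MANIFEST)
        assert grouped_u[0].sharing is SharingClass.U

    def test_near_match_warned_not_merged(self):
        spa = REF[:6] + "-" + REF[7:]
        spc = REF[:7] + "-" + REF[8:]
        res = detect_disruptions(_aln(SpA=spa, SpC=spc))
        grouped, warnings = group_and_classify(res.disruptions, MANIFEST)
        assert len(grouped) == 2
        assert len(warnings) == 1

    def test_status_calls(self):
        spa = REF[:6] + "-" + REF[7:]
        aln = _aln(SpA=spa, SpB=REF, SpC=REF)
        res = detect_disruptions(aln)
        grouped, _ = group_and_classify(res.disruptions, MANIFEST)
        call = call_gene_status(aln, MANIFEST, grouped, "G1")
        assert call.status["SpA"] == "pseudogene"
        assert call.status["SpB"] == "intact"
        assert call.status["SpD"] == "absent"  # manifest "-" wins
        cells = status_matrix_row(call, ["Mouse", "SpA", "SpB", "SpC", "SpD"])
        assert cells == ["+", "U", "+", "+", "-"]

    def test_in_frame_deletion_keeps_species_intact(self):
        spa = REF[:6] + "---" + REF[9:]
        aln = _aln(SpA=spa)
        res = detect_disruptions(aln)
        grouped, _ = group_and_classify(res.disruptions, MANIFEST)
        call = call_gene_status(aln, MANIFEST, grouped, "G1")
        assert call.status["SpA"] == "intact"


class TestLossDating:
    TREE = SpeciesTree.from_newick(
        "(Mouse:0.5,((SpA:0.1,SpB:0.1):0.1,(SpC:0.1,SpD:0.1):0.1):0.2#stem);"
    )

    def _grouped(self, carriers):
        spa = REF[:6] + "-" + REF[7:]
        aln = _aln(**{sp: spa for sp in carriers})
        res = detect_disruptions(aln)
        grouped, _ = group_and_classify(res.disruptions, MANIFEST)
        return grouped[0]

    def test_cross_clade_carriers_map_to_stem_branch(self):
        g = self._grouped(["SpA", "SpC"])
        bid = infer_loss_branch(g, self.TREE)
        assert self.TREE.branch_class(bid) == "stem"

    def test_single_carrier_maps_to_its_terminal_branch(self):
        g = self._grouped(["SpB"])
        assert infer_loss_branch(g, self.TREE) == "SpB"

    def test_clade_carriers_match_naive_mrca(self):
        for carriers in (["SpA", "SpB"], ["SpC", "SpD"], ["SpA", "SpB", "SpC"]):
            g = self._grouped(carriers)
            bid = infer_loss_branch(g, self.TREE)
            expected = naive_mrca(self.TREE.tree, carriers)
            assert bid == SpeciesTree.branch_id(expected)

    def test_unknown_carrier_rejected(self):
        g = self._grouped(["SpA"])
        from genedecay.orf import Disruption

        bad = Disruption(
            kind=g.disruption.kind, ref_start=1, length=1, columns=(0,),
            carriers=frozenset({"Ghost"}),
        )
        with pytest.raises(KeyError):
            infer_loss_branch(bad, self.TREE)


class TestSimulatedRecovery:
    def test_every_truth_disruption_recovered_exactly(self, stem_loss_sim):
        aln, truth, cfg = stem_loss_sim
        res = detect_disruptions(aln)
        got = {}
        for d in res.disruptions:
            sp = next(iter(d.carriers))
            got.setdefault(sp, set()).add((d.kind.value, d.ref_start, d.length))
        for sp, ds in truth.disruptions_by_species.items():
            expected = {
                (d.kind, d.ref_start, d.length)
                for d in ds
                if not d.kind.startswith("inframe")
            }
            assert got.get(sp, set()) == expected

    def test_reference_never_reported(self, stem_loss_sim):
        aln, _, _ = stem_loss_sim
        res = detect_disruptions(aln)
        for d in res.disruptions:
            assert aln.reference_id not in d.carriers
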