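"""Edit rules: loxPsym placement, stop swaps, recoding, deletions, liftover."""

import pytest
from hypothesis import given, settings, strategies as st

from synchrom._codons import revcomp, translate
from synchrom.design_rules import (
    LOXPSYM,
    DesignError,
    DesignPolicy,
    Edit,
    EditPlan,
    apply_edits,
    apply_plan_to_sequence,
    build_base_plan,
    delete_elements,
    find_tandem_repeats,
    invert_plan,
    place_loxpsym,
    recode_restriction_sites,
    smash_repeats,
    swap_stop_codons,
    trna_array_records,
)
from synchrom.fixtures import REPEAT_UNIT, FixtureSpec, make_mini_chromosome
from synchrom.genome_model import OrfFeature

from conftest import plus_orf, toy_annotation


def _embed(length, *placements):
    seq = list("ACGT" * (length // 4 + 1))[:length]
    for pos, s in placements:
        seq[pos : pos + len(s)] = s
    return "".join(seq)


class TestPolicy:
    def test_loxpsym_is_self_reverse_complementary(self):
        assert revcomp(LOXPSYM) == LOXPSYM

    def test_asymmetric_motif_rejected(self):
        with pytest.raises(DesignError):
            DesignPolicy(loxpsym_motif="ATAACTTCGTATA")

    def test_yaml_round_trip(self, tmp_path):
        pol = DesignPolicy.v1(chunk_len_bp=(5000, 9000), enzyme_set=("GGATCC",))
        path = tmp_path / "policy.yaml"
        pol.to_yaml(path)
        back = DesignPolicy.from_yaml(path)
        assert back == pol


class TestPlaceLoxpsym:
    def test_forward_gene_gets_site_three_bp_downstream(self, v1_policy):
        seq = _embed(600, (100, "ATGGCTTAA"))
        ann = toy_annotation(seq, orfs=[plus_orf("g", 100, "ATGGCTTAA")])
        plan = place_loxpsym(ann, v1_policy)
        assert len(plan) == 1
        edit = plan.edits[0]
        assert edit.kind == "insert"
        assert edit.wt_interval == (112, 112)  # stop ends at 109, +3
        assert edit.replacement == LOXPSYM

    def test_minus_strand_site_upstream_of_genomic_start(self, v1_policy):
        seq = _embed(600, (100, revcomp("ATGGCTTAA")))
        orf = OrfFeature(id="g", strand="-", exons=((100, 109),))
        ann = toy_annotation(seq, orfs=[orf])
        plan = place_loxpsym(ann, v1_policy)
        assert plan.edits[0].wt_interval == (97, 97)

    def test_essential_gene_excluded(self, v1_policy):
        seq = _embed(600, (100, "ATGGCTTAA"))
        ann = toy_annotation(
            seq, orfs=[plus_orf("g", 100, "ATGGCTTAA", essential=True)]
        )
        assert len(place_loxpsym(ann, v1_policy)) == 0

    def test_colliding_insertions_merge(self, v1_policy):
        # convergent pair: + gene ends at 109 (site at 112), - gene starts at
        # 115 (site at 112): one merged motif
        seq = _embed(600, (100, "ATGGCTTAA"), (115, revcomp("ATGGCTTAA")))
        minus = OrfFeature(id="m", strand="-", exons=((115, 124),))
        ann = toy_annotation(seq, orfs=[plus_orf("p", 100, "ATGGCTTAA"), minus])
        plan = place_loxpsym(ann, v1_policy)
        assert len(plan) == 1
        assert set(plan.edits[0].feature_id.split("+")) == {"p", "m"}

    def test_v2_drops_dubious_and_window_intruding_sites(self, mini, v1_policy, v2_policy):
        ann, gt = mini
        assert len(place_loxpsym(ann, v1_policy)) == gt.loxpsym_v1
        assert len(place_loxpsym(ann, v2_policy)) == gt.loxpsym_v2
        assert gt.loxpsym_v2 < gt.loxpsym_v1


class TestSwapStopCodons:
    def test_forward_tag_swapped_to_taa(self, v1_policy):
        seq = _embed(300, (50, "ATGGCTTAG"))
        ann = toy_annotation(seq, orfs=[plus_orf("g", 50, "ATGGCTTAG")])
        plan = swap_stop_codons(ann, v1_policy)
        assert len(plan) == 1
        assert plan.edits[0].wt_interval == (58, 59)
        assert plan.edits[0].replacement == "A"
        designed = apply_edits(ann, plan)
        assert designed.features_lifted.orfs[0].spliced_cds(designed.sequence) == \
            "ATGGCTTAA"

    def test_taa_and_tga_left_alone(self, v1_policy):
        seq = _embed(300, (50, "ATGGCTTAA"), (100, "ATGGCTTGA"))
        ann = toy_annotation(
            seq,
            orfs=[plus_orf("a", 50, "ATGGCTTAA"), plus_orf("b", 100, "ATGGCTTGA")],
        )
        assert len(swap_stop_codons(ann, v1_policy)) == 0

    def test_minus_strand_substitutes_complement_base(self, v1_policy):
        seq = _embed(300, (50, revcomp("ATGGCTTAG")))
        orf = OrfFeature(id="g", strand="-", exons=((50, 59),))
        ann = toy_annotation(seq, orfs=[orf])
        plan = swap_stop_codons(ann, v1_policy)
        assert plan.edits[0].wt_interval == (50, 51)
        assert plan.edits[0].replacement == "T"
        designed = apply_edits(ann, plan)
        assert designed.features_lifted.orfs[0].spliced_cds(designed.sequence) == \
            "ATGGCTTAA"

    def test_v2_reverts_nested_dubious_and_preserves_host_protein(self, mini, v2_policy):
        ann, gt = mini
        plan = swap_stop_codons(ann, v2_policy)
        assert len(plan) == gt.stop_swaps_v2
        designed = apply_edits(ann, plan)
        for orf in ann.orfs_by_class("verified"):
            lifted = designed.features_lifted.get_orf(orf.id)
            assert translate(lifted.spliced_cds(designed.sequence))[:-1] == \
                orf.protein(ann.sequence)[:-1]


class TestSmashRepeats:
    def test_no_repeat_no_edits(self, v2_policy):
        seq = _embed(300, (50, "ATGGCTGATCCATTGTAA"))
        ann = toy_annotation(seq, orfs=[plus_orf("g", 50, "ATGGCTGATCCATTGTAA")])
        assert len(smash_repeats(ann, v2_policy)) == 0

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_edits_confined_to_repeat_span_protein_kept(self, strand, v2_policy):
        cds = "ATG" + "GCTGATCCATTGGATCAA" + REPEAT_UNIT * 5 + \
            "TTGGATCAAGCTAGAACT" + "TAA"
        genomic = cds if strand == "+" else revcomp(cds)
        seq = _embed(400, (50, genomic))
        orf = OrfFeature(id="g", strand=strand, exons=((50, 50 + len(cds)),),
                         classification="verified")
        ann = toy_annotation(seq, orfs=[orf])
        hits = find_tandem_repeats(orf.spliced_cds(seq))
        assert len(hits) == 1
        span = hits[0]
        plan = smash_repeats(ann, v2_policy)
        assert len(plan) > 0
        gspan = sorted(orf.cds_to_genomic(i) for i in (span[0], span[1] - 1))
        for e in plan:
            assert gspan[0] <= e.wt_interval[0] < e.wt_interval[1] <= gspan[1] + 1
        designed = apply_edits(ann, plan)
        lifted = designed.features_lifted.orfs[0]
        assert translate(lifted.spliced_cds(designed.sequence)) == \
            translate(cds)
        # periodicity of the run is actually broken
        new_cds = lifted.spliced_cds(designed.sequence)
        unit = span[2]
        block = new_cds[span[0]: span[1]]
        assert any(block[i] != block[i + unit] for i in range(len(block) - unit))

    def test_detector_requires_primitive_unit(self):
        assert find_tandem_repeats("A" * 30) == []
        assert find_tandem_repeats("ACACACACACAC") == []
        hits = find_tandem_repeats("CAGTT" * 4)
        assert hits and hits[0][2] == 5


class TestRecodeRestrictionSites:
    def test_in_frame_site_destroyed_protein_unchanged(self):
        policy = DesignPolicy.v2(enzyme_set=("GGTACC",))
        cds = "ATGGATCGA" + "GGTACC" + "CCAGATTTGTAA"
        seq = _embed(400, (60, cds))
        ann = toy_annotation(
            seq, orfs=[plus_orf("g", 60, cds, classification="verified")]
        )
        plan, failures = recode_restriction_sites(ann, policy)
        assert not failures
        designed = apply_edits(ann, plan)
        assert "GGTACC" not in designed.sequence
        lifted = designed.features_lifted.orfs[0]
        assert translate(lifted.spliced_cds(designed.sequence)) == translate(cds)

    def test_no_site_no_edits(self):
        policy = DesignPolicy.v2(enzyme_set=("GGTACC",))
        cds = "ATGGATCGACCAGATTTGTAA"
        ann = toy_annotation(_embed(300, (60, cds)),
                             orfs=[plus_orf("g", 60, cds, classification="verified")])
        plan, failures = recode_restriction_sites(ann, policy)
        assert len(plan) == 0 and not failures

    def test_boundary_site_fixed_on_intergenic_side(self):
        # motif AAGCTT straddles the stop codon (TAA) and intergenic bases;
        # the stop cannot be recoded, so an intergenic base is substituted
        policy = DesignPolicy.v2(enzyme_set=("AAGCTT",))
        cds = "ATGGATCGATTGTAA"
        end = 60 + len(cds)
        seq = _embed(300, (60, cds), (end, "GCTTGG"))
        ann = toy_annotation(seq, orfs=[plus_orf("g", 60, cds,
                                                 classification="verified")])
        assert "AAGCTT" in seq
        plan, failures = recode_restriction_sites(ann, policy)
        assert not failures
        designed = apply_edits(ann, plan)
        assert "AAGCTT" not in designed.sequence
        lifted = designed.features_lifted.orfs[0]
        assert lifted.spliced_cds(designed.sequence) == cds  # CDS untouched


class TestDeleteElements:
    def test_trna_deletions_and_array(self, mini, v2_policy):
        ann, gt = mini
        plan = delete_elements(ann, v2_policy)
        assert len(plan.by_rule("trna_del")) == gt.trna_genes_removed
        records = trna_array_records(ann, flank_bp=50)
        assert len(records) == gt.trna_genes_removed
        for rec, trna in zip(records, ann.trnas):
            assert str(rec.seq)[50:125] in ann.sequence  # gene body present

    def test_intron_removal_preserves_protein(self, mini, v2_policy):
        ann, _ = mini
        plan = delete_elements(ann, v2_policy)
        designed = apply_edits(ann, plan)
        for orf in ann.orfs:
            if len(orf.exons) < 2:
                continue
            lifted = designed.features_lifted.get_orf(orf.id)
            assert len(lifted.exons) == 1
            assert lifted.spliced_cds(designed.sequence) == \
                orf.spliced_cds(ann.sequence)

    def test_no_repeats_no_repeat_edits(self, v2_policy):
        ann, _ = make_mini_chromosome(
            FixtureSpec(seed=9, length_bp=25_000, n_verified=4, n_ltr_repeat=0,
                        n_uncharacterized=1, n_dubious=1, n_trna=1, n_intron=1,
                        n_tag_stop_codons=2, n_essential=1, n_enzyme_sites=1,
                        n_dubious_overlapping_verified=0,
                        n_dubious_stop_in_verified=0)
        )
        assert len(delete_elements(ann, v2_policy).by_rule("repeat_del")) == 0


class TestApplyEdits:
    def test_empty_plan_is_identity(self, mini):
        ann, _ = mini
        designed = apply_edits(ann, EditPlan())
        assert designed.sequence == ann.sequence
        for p in (0, 137, len(ann.sequence) - 1):
            assert designed.liftover.wt_to_designed(p) == p

    def test_length_arithmetic(self):
        seq = "ACGT" * 250
        ann = toy_annotation(seq)
        plan = EditPlan([
            Edit("insert", (100, 100), LOXPSYM, "loxpsym", "x"),
            Edit("delete", (500, 580), "", "repeat_del", "y"),
        ])
        designed = apply_edits(ann, plan)
        assert len(designed.sequence) == 1000 + 34 - 80

    def test_overlapping_edits_rejected(self):
        with pytest.raises(DesignError):
            EditPlan([
                Edit("delete", (10, 30), "", "repeat_del", "a"),
                Edit("substitute", (20, 21), "A", "stop_swap", "b"),
            ])
        with pytest.raises(DesignError):
            EditPlan([
                Edit("insert", (10, 10), "AC", "loxpsym", "a"),
                Edit("insert", (10, 10), "GT", "loxpsym", "b"),
            ])

    def test_inversion_recovers_wild_type(self, mini, mini_v2):
        ann, _ = mini
        plan = mini_v2.designed.plan
        inverse = invert_plan(plan, ann.sequence)
        assert apply_plan_to_sequence(mini_v2.designed.sequence, inverse) == \
            ann.sequence


@st.composite
def _random_plans(draw):
    n = draw(st.integers(1, 8))
    length = 400
    cursor = 0
    edits = []
    kinds = ("insert", "delete", "substitute")
    for _ in range(n):
        start = draw(st.integers(cursor, min(cursor + 60, length - 20)))
        kind = draw(st.sampled_from(kinds))
        if kind == "insert":
            rep = draw(st.text(alphabet="ACGT", min_size=1, max_size=12))
            edits.append(Edit("insert", (start, start), rep, "loxpsym", "h"))
            cursor = start + 1
        elif kind == "delete":
            end = draw(st.integers(start + 1, min(start + 15, length)))
            edits.append(Edit("delete", (start, end), "", "repeat_del", "h"))
            cursor = end
        else:
            end = draw(st.integers(start + 1, min(start + 6, length)))
            rep = draw(st.text(alphabet="ACGT", min_size=end - start,
                               max_size=end - start))
            edits.append(Edit("substitute", (start, end), rep, "tag_recode", "h"))
            cursor = end
        if cursor >= length - 20:
            break
    return EditPlan(edits)


class TestPlanProperties:
    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(plan=_random_plans(), seed=st.integers(0, 10_000))
    def test_apply_invert_round_trip_and_monotone_liftover(self, plan, seed):
        import random

        rng = random.Random(seed)
        seq = "".join(rng.choices("ACGT", k=400))
        out = apply_plan_to_sequence(seq, plan)
        assert len(out) == 400 + sum(e.length_delta for e in plan)
        back = apply_plan_to_sequence(out, invert_plan(plan, seq))
        assert back == seq
        from synchrom.design_rules import Liftover

        lift = Liftover(plan, 400)
        mapped = [lift.wt_to_designed(p) for p in range(400)]
        kept = [m for m in mapped if m is not None]
        assert kept == sorted(kept)
        for p, m in enumerate(mapped):
            if m is not None:
                assert lift.designed_to_wt(m) == p


class TestFullRuleIdempotence:
    def test_redesigning_a_designed_chromosome_is_stable(self, mini, v2_policy):
        """Applying the rules to an already-designed chromosome produces no
        new recoding or deletion work (loxPsym sites would simply be
        re-placed next to the already-inserted motifs)."""
        ann, _ = mini
        plan = build_base_plan(ann, v2_policy)
        designed = apply_edits(ann, plan)
        replan = build_base_plan(designed.features_lifted, v2_policy)
        assert len(replan.by_rule("stop_swap")) == 0
        assert len(replan.by_rule("trna_del")) == 0
        assert len(replan.by_rule("intron_del")) == 0
        assert len(replan.by_rule("repeat_del")) == 0
        assert len(replan.by_rule("repeat_smash")) == 0
        assert len(replan.by_rule("rs_removal")) == 0
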