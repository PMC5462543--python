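import pytest

from paleoplastid.core_io import parse_tree
from paleoplastid.origin_assignment import (annotate_cash_position,
                                            blast_top_hit_origin,
                                            combine_origins,
                                            deeper_affinity_hits,
                                            deeper_affinity_tree,
                                            reduced_library_top_hit,
                                            tree_sister_origin)


class TestTopHitRule:
    @pytest.mark.parametrize("lineages,expected", [
        (["red", "red", "red", "green"], ("red", 3)),
        (["red", "green", "red"], ("ambiguous", 1)),
        (["green"] * 5, ("green", 5)),
        ([], ("ambiguous", 0)),
    ])
    def test_consecutive_prefix(self, lineages, expected):
        assert blast_top_hit_origin(lineages) == expected

    def test_reduced_library_exclusion(self):
        hits = ["haptophytes"] + ["hypogyristea"] * 3
        origin, n = reduced_library_top_hit(hits, "haptophytes")
        assert (origin, n) == ("hypogyristea", 3)

    def test_reduced_library_all_excluded(self):
        assert reduced_library_top_hit(["haptophytes"] * 4,
                                       "haptophytes") == ("ambiguous", 0)

    def test_deeper_affinity_from_suffix(self):
        hits = ["aplastidic stramenopiles"] * 3 + ["red algae"] * 3 + ["green"]
        assert deeper_affinity_hits(hits, "aplastidic stramenopiles") == \
            ("red algae", 3)

    def test_deeper_affinity_ambiguous_suffix(self):
        hits = ["aplastidic stramenopiles"] * 3 + ["red algae", "green", "red"]
        origin, _ = deeper_affinity_hits(hits, "aplastidic stramenopiles")
        assert origin == "ambiguous"


OCH = "((px|Esil|a,raphidophytes|Haka|b),(pennates|Ptri|c,corethron|Ccor|d))"
OCH_IDS = {"px|Esil|a", "raphidophytes|Haka|b", "pennates|Ptri|c",
           "corethron|Ccor|d"}
DEEP = "(cyanobacteria|Syne|o1,proteobacteria|Ecol|o2)"


class TestSisterRule:
    def test_two_subcategory_red_sister(self, taxonomy):
        t = parse_tree(
            f"({DEEP},(cyanidiales|Cmer|r1,((porphyridiophytes|Ppur|r2,"
            f"rhodellophytes|Rvio|r3),{OCH})));", taxonomy)
        origin, subcats = tree_sister_origin(t, OCH_IDS)
        assert origin == "red algae"
        assert subcats == {"porphyridiophytes", "rhodellophytes"}

    def test_single_sequence_sister_undetermined(self, taxonomy):
        t = parse_tree(
            f"({DEEP},(cyanidiales|Cmer|r1,(streptophytes|Atha|g1,{OCH})));",
            taxonomy)
        origin, _ = tree_sister_origin(t, OCH_IDS)
        assert origin == "undetermined"

    def test_mixed_lineage_sister_undetermined(self, taxonomy):
        t = parse_tree(
            f"({DEEP},(glaucophytes|Cpar|x,((cyanidiales|Cmer|r1,"
            f"streptophytes|Atha|g1),{OCH})));", taxonomy)
        origin, _ = tree_sister_origin(t, OCH_IDS)
        assert origin == "undetermined"

    def test_non_monophyletic_focal_undetermined(self, taxonomy):
        t = parse_tree(
            f"({DEEP},(px|Esil|a,(cyanidiales|Cmer|r1,(raphidophytes|Haka|b,"
            "(pennates|Ptri|c,corethron|Ccor|d)))));", taxonomy)
        origin, _ = tree_sister_origin(t, OCH_IDS)
        assert origin == "undetermined"

    def test_missing_focal_clade_is_an_error(self, taxonomy):
        t = parse_tree(f"({DEEP},cyanidiales|Cmer|r1,glaucophytes|Cpar|x);",
                       taxonomy)
        with pytest.raises(ValueError):
            tree_sister_origin(t, OCH_IDS)

    def test_deeper_affinity_sister_of_expanded_clade(self, taxonomy):
        t = parse_tree(
            f"(({OCH},(oomycetes|Psoj|h1,labyrinthulomycetes|Alim|h2)),"
            "(streptophytes|Atha|g1,(mamiellophytes|Otau|g2,"
            "chlorophyceae|Crei|g3)));",
            taxonomy)
        origin, _ = deeper_affinity_tree(t, OCH_IDS)
        assert origin == "green algae"


class TestCombination:
    def test_agreement_gives_high_confidence(self):
        call = combine_origins("h", ("red algae", 4),
                               ("red algae", frozenset({"a", "b"})))
        assert call.combined_origin == "red algae"
        assert call.confidence == "high"

    def test_disagreement_prefers_tree_for_annotation(self):
        call = combine_origins("h", ("red algae", 3),
                               ("green algae", frozenset({"a", "b"})))
        assert call.combined_origin == "unresolved"
        assert call.confidence == "low"
        assert call.annotation == "green algae"

    def test_double_failure_is_unannotated(self):
        call = combine_origins("h", ("ambiguous", 1),
                               ("undetermined", frozenset()))
        assert call.combined_origin == "unresolved"
        assert call.annotation == ""


HAP = "((pavlovophytes|Plut|h1,prymnesiales|Ctob|h2),isochrysidales|Ehux|h3)"
HAP_IDS = {"pavlovophytes|Plut|h1", "prymnesiales|Ctob|h2",
           "isochrysidales|Ehux|h3"}


class TestCashPosition:
    def test_nested_in_hypogyristea(self, taxonomy):
        t = parse_tree(
            f"({DEEP},(cyanidiales|Cmer|r1,(((pelagophytes|Aano|p1,"
            f"dictyochophytes|Dspe|p2),{HAP}),"
            "(pennates|Ptri|c,(px|Esil|a,raphidophytes|Haka|b)))));",
            taxonomy)
        cat, _ = annotate_cash_position(t, "haptophytes", taxonomy, HAP_IDS)
        assert cat == "internal:hypogyristea"

    def test_single_subcategory_not_recorded(self, taxonomy):
        t = parse_tree(
            f"({DEEP},(cyanidiales|Cmer|r1,((pennates|Ptri|c,"
            "pavlovophytes|Plut|h1),(px|Esil|a,raphidophytes|Haka|b))));",
            taxonomy)
        cat, reason = annotate_cash_position(
            t, "haptophytes", taxonomy, {"pavlovophytes|Plut|h1"})
        assert cat is None and "sub-category" in reason

    def test_immediate_sister_to_all_ochrophytes(self, taxonomy):
        t = parse_tree(
            f"({DEEP},(cyanidiales|Cmer|r1,({HAP},"
            "((px|Esil|a,raphidophytes|Haka|b),"
            "(pennates|Ptri|c,corethron|Ccor|d)))));", taxonomy)
        cat, _ = annotate_cash_position(t, "haptophytes", taxonomy, HAP_IDS)
        assert cat == "external:immediate-sister"

    def test_requires_plastid_targeted_member(self, taxonomy):
        t = parse_tree(
            f"({DEEP},(cyanidiales|Cmer|r1,({HAP},"
            "((px|Esil|a,raphidophytes|Haka|b),"
            "(pennates|Ptri|c,corethron|Ccor|d)))));", taxonomy)
        cat, reason = annotate_cash_position(t, "haptophytes", taxonomy,
                                             set())
        assert cat is None and "plastid" in reason


def test_origin_recovery_on_default_dataset(pipeline_result):
    """Combined calls match the planted origins."""
    truth = pipeline_result.dataset.truth
    determined = [c for c in pipeline_result.origin_calls.values()
                  if c.confidence == "high"]
    assert len(determined) >= 10
    correct = sum(
        1 for c in determined
        if c.combined_origin == truth.families.loc[
            truth.sequences.loc[c.hppg_id, "family"], "origin"])
    assert correct / len(determined) >= 0.90
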