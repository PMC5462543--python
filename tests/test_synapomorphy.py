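import numpy as np
import pytest

from paleoplastid.core_io import parse_tree
from paleoplastid.synapomorphy import (composition_bias_filter,
                                       count_shared_residues_concatenated,
                                       find_unique_shared_residues,
                                       green_screen_rules, infer_origin_node,
                                       screen_vertical_inheritance,
                                       validate_member_sequence)

from ._oracles import shared_residue_columns

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestVerticalScreen:
    def test_single_clades_included(self, taxonomy):
        t = parse_tree(
            "((cyanidiales|Cmer|r1,florideophytes|Chon|r2),"
            "(streptophytes|Atha|g1,mamiellophytes|Otau|g2));", taxonomy)
        include, offenders = screen_vertical_inheritance(
            t, taxonomy, green_screen_rules())
        assert include and not offenders

    def test_split_red_clades_excluded(self, taxonomy):
        t = parse_tree(
            "((cyanidiales|Cmer|r1,florideophytes|Chon|r2),"
            "((streptophytes|Atha|g1,mamiellophytes|Otau|g2),"
            "(porphyridiophytes|Ppur|r3,rhodellophytes|Rvio|r4)));", taxonomy)
        include, offenders = screen_vertical_inheritance(
            t, taxonomy, green_screen_rules())
        assert not include and offenders == {"red algae"}

    def test_green_paraphyly_to_ochrophytes_allowed(self, taxonomy):
        t = parse_tree(
            "((cyanidiales|Cmer|r1,florideophytes|Chon|r2),"
            "((streptophytes|Atha|g1,(pennates|Ptri|o1,px|Esil|o2)),"
            "(mamiellophytes|Otau|g2,chlorophyceae|Crei|g3)));", taxonomy)
        include, offenders = screen_vertical_inheritance(
            t, taxonomy, green_screen_rules())
        assert include, offenders


class TestMemberValidation:
    def test_clean_red_member_kept(self, taxonomy):
        v = validate_member_sequence(
            "cyanidiales|Cmer|x", "red algae",
            ["red algae"] * 3, [("red algae", "florideophytes")],
            "cyanidiales", taxonomy)
        assert v.keep

    def test_wrong_global_lineage_dropped(self, taxonomy):
        v = validate_member_sequence(
            "cyanidiales|Cmer|x", "red algae",
            ["green algae", "red algae", "red algae"],
            [("red algae", "florideophytes")], "cyanidiales", taxonomy)
        assert not v.keep and v.reason == "global lineage"

    def test_glaucophyte_cyanobacterial_top_hit_allowed(self, taxonomy):
        v = validate_member_sequence(
            "glaucophytes|Cpar|x", "glaucophytes",
            ["glaucophytes"], [("cyanobacteria-class", "cyanobacteria")],
            "glaucophytes", taxonomy)
        assert v.keep

    def test_same_subcategory_fallback(self, taxonomy):
        v = validate_member_sequence(
            "cyanidiales|Cmer|x", "red algae",
            ["red algae"] * 3, [("red algae", "cyanidiales")],
            "cyanidiales", taxonomy)
        assert v.keep   # no other sub-category present in the alignment


def _aln(rows):
    return {sid: row for sid, row in rows.items()}


class TestSharedResidues:
    def test_qualifying_column(self):
        aln = _aln({"pennates|a|1": "A", "corethron|b|2": "A",
                    "px|c|3": "A", "streptophytes|d|4": "A",
                    "mamiellophytes|e|5": "-", "cyanidiales|f|6": "G",
                    "florideophytes|g|7": "G"})
        calls = find_unique_shared_residues(
            aln, ["pennates|a|1", "corethron|b|2", "px|c|3"],
            ["streptophytes|d|4", "mamiellophytes|e|5"],
            [["cyanidiales|f|6", "florideophytes|g|7"]])
        assert len(calls) == 1 and calls[0].residue == "A"

    def test_fully_gapped_exclusion_fails_clause_d(self):
        aln = _aln({"pennates|a|1": "A", "corethron|b|2": "A",
                    "px|c|3": "A", "streptophytes|d|4": "A",
                    "cyanidiales|f|6": "-", "florideophytes|g|7": "-"})
        calls = find_unique_shared_residues(
            aln, ["pennates|a|1", "corethron|b|2", "px|c|3"],
            ["streptophytes|d|4"],
            [["cyanidiales|f|6", "florideophytes|g|7"]])
        assert calls == []

    def test_two_thirds_of_ungapped_focal_enough(self):
        aln = _aln({"pennates|a|1": "A", "corethron|b|2": "A",
                    "px|c|3": "G", "streptophytes|d|4": "A",
                    "cyanidiales|f|6": "S"})
        calls = find_unique_shared_residues(
            aln, ["pennates|a|1", "corethron|b|2", "px|c|3"],
            ["streptophytes|d|4"], [["cyanidiales|f|6"]])
        assert len(calls) == 1
        assert calls[0].focal_share_fraction == pytest.approx(2 / 3)

    def test_matches_exhaustive_per_column_oracle(self):
        rng = np.random.default_rng(5)
        focal = [f"pennates|f|{i}" for i in range(4)]
        donors = [f"streptophytes|d|{i}" for i in range(3)]
        excl = [f"cyanidiales|e|{i}" for i in range(3)]
        for _ in range(100):
            ncol = int(rng.integers(5, 51))
            aln = {}
            for sid in focal + donors + excl:
                row = [AA[rng.integers(0, 4)] if rng.random() > 0.2 else "-"
                       for _ in range(ncol)]
                aln[sid] = "".join(row)
            ours = [c.column for c in find_unique_shared_residues(
                aln, focal, donors, [excl])]
            assert ours == shared_residue_columns(aln, focal, donors, excl)


GREEN_TREE = ("(streptophytes,(prasinodermophytes,(mamiellophytes,"
              "(chlorophyceae,trebouxiophytes))));")


class TestOriginNode:
    def _tree(self, taxonomy):
        return parse_tree(GREEN_TREE, taxonomy)

    def test_all_green_ancestor_under_majority(self, taxonomy):
        # 4 of 5 lineages match: even the root clade passes the majority
        # rule, so the residue maps to the common ancestor of all greens
        status = {"mamiellophytes": "match", "chlorophyceae": "match",
                  "trebouxiophytes": "match", "prasinodermophytes": "match",
                  "streptophytes": "mismatch"}
        node = infer_origin_node(self._tree(taxonomy), status, "observed")
        assert set(node.split("+")) == {"streptophytes", "prasinodermophytes",
                                        "mamiellophytes", "chlorophyceae",
                                        "trebouxiophytes"}

    def test_core_chlorophyte_ancestor(self, taxonomy):
        # 2 of 5 match: the root and the prasinodermophyte clade fail the
        # majority rule, the (mamiellophyte,(chloro,treboux)) clade passes
        status = {"mamiellophytes": "mismatch", "chlorophyceae": "match",
                  "trebouxiophytes": "match",
                  "prasinodermophytes": "mismatch",
                  "streptophytes": "mismatch"}
        node = infer_origin_node(self._tree(taxonomy), status, "observed")
        assert set(node.split("+")) == {"mamiellophytes", "chlorophyceae",
                                        "trebouxiophytes"}

    def test_single_subcategory_gives_that_leaf(self, taxonomy):
        status = {"chlorophyceae": "match", "trebouxiophytes": "mismatch",
                  "mamiellophytes": "mismatch",
                  "prasinodermophytes": "mismatch",
                  "streptophytes": "mismatch"}
        assert infer_origin_node(self._tree(taxonomy), status,
                                 "observed") == "chlorophyceae"

    def test_gaps_count_for_earliest_but_not_observed(self, taxonomy):
        status = {"chlorophyceae": "match", "trebouxiophytes": "match",
                  "mamiellophytes": "gap", "prasinodermophytes": "gap",
                  "streptophytes": "mismatch"}
        observed = infer_origin_node(self._tree(taxonomy), status, "observed")
        earliest = infer_origin_node(self._tree(taxonomy), status, "earliest")
        # observed: (mam,(chloro,treboux)) has 2 matches vs 1 gap-against;
        # deeper clades fail.  earliest: gaps count as matches -> whole tree
        assert set(observed.split("+")) == {"mamiellophytes", "chlorophyceae",
                                            "trebouxiophytes"}
        assert set(earliest.split("+")) == {"streptophytes",
                                            "prasinodermophytes",
                                            "mamiellophytes", "chlorophyceae",
                                            "trebouxiophytes"}

    def test_earliest_is_ancestor_or_equal_of_observed(self, taxonomy):
        rng = np.random.default_rng(9)
        tree = self._tree(taxonomy)
        leaves = ["streptophytes", "prasinodermophytes", "mamiellophytes",
                  "chlorophyceae", "trebouxiophytes"]
        for _ in range(200):
            status = {l: ["match", "mismatch", "gap"][rng.integers(0, 3)]
                      for l in leaves}
            if not any(v == "match" for v in status.values()):
                continue
            obs = set(infer_origin_node(tree, status, "observed").split("+"))
            early = set(infer_origin_node(tree, status, "earliest").split("+"))
            assert obs <= early


class TestCompositionBias:
    def test_identical_composition_no_flags(self):
        aln = {"a|x|1": "AG" * 50, "b|x|2": "AG" * 50}
        flags, filtered = composition_bias_filter(aln, ["a|x|1"], ["b|x|2"])
        assert flags == []
        assert filtered == aln

    def test_planted_glycine_bias_flagged(self):
        a = "G" * 40 + "A" * 1960     # 2% glycine
        b = "G" * 160 + "A" * 1840    # 8% glycine
        flags, filtered = composition_bias_filter(
            {"x|x|1": a, "y|y|2": b}, ["x|x|1"], ["y|y|2"])
        assert "G" in flags
        assert all("G" not in row for row in filtered.values())


class TestConcatenatedCounts:
    def test_unique_to_one_partner(self):
        aln = {"hap1": "A", "hap2": "A", "crypt1": "A", "red1": "G"}
        counts = count_shared_residues_concatenated(
            aln, ["hap1", "hap2"],
            {"cryptomonads": ["crypt1"], "red": ["red1"]}, mode="strict")
        assert counts == {"cryptomonads": 1, "red": 0}

    def test_shared_with_two_partners_counts_for_neither(self):
        aln = {"hap1": "A", "hap2": "A", "crypt1": "A", "red1": "A"}
        counts = count_shared_residues_concatenated(
            aln, ["hap1", "hap2"],
            {"cryptomonads": ["crypt1"], "red": ["red1"]}, mode="strict")
        assert counts == {"cryptomonads": 0, "red": 0}

    def test_matches_brute_force_column_scan(self):
        rng = np.random.default_rng(3)
        focal = [f"hap{i}" for i in range(4)]
        partners = {"cryptomonads": ["c1", "c2"], "red": ["r1", "r2"],
                    "green": ["g1"]}
        ids = focal + [s for v in partners.values() for s in v]
        aln = {sid: "".join(AA[rng.integers(0, 3)] if rng.random() > 0.15
                            else "-" for _ in range(50)) for sid in ids}
        counts = count_shared_residues_concatenated(aln, focal, partners,
                                                    mode="strict")
        expected = {lin: 0 for lin in partners}
        for col in range(50):
            f = {aln[s][col] for s in focal}
            if len(f) != 1 or "-" in f:
                continue
            residue = next(iter(f))
            holders = [lin for lin, ids_ in partners.items()
                       if any(aln[s][col] == residue for s in ids_)]
            if len(holders) == 1:
                expected[holders[0]] += 1
        assert counts == expected
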