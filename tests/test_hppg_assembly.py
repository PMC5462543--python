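import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleoplastid.core_io import HitRecord, SequenceRecord, parse_tree
from paleoplastid.hppg_assembly import (HPPG, ConservationPattern, OutgroupCap,
                                        check_ochrophyte_clade,
                                        compute_outgroup_cap, curate_alignment,
                                        default_patterns,
                                        evaluate_conservation, grow_hppg,
                                        merge_seeds,
                                        select_conservation_patterns,
                                        trim_columns)

from ._oracles import transitive_closure_clusters


def _hit(q, s, evalue, rank=1, bitscore=100.0):
    return HitRecord(query_id=q, subject_id=s, rank=rank,
                     percent_identity=80.0, query_interval=(0, 50),
                     subject_interval=(0, 50), evalue=evalue,
                     bitscore=bitscore)


def _rec(sid, seq="MKVLAEQRSTMKVLAEQRST"):
    sub = sid.split("|")[0]
    return SequenceRecord(seq_id=sid, species_id=sid.split("|")[1],
                          sub_category=sub, library_id=sid.split("|")[1],
                          residues=seq)


class TestOutgroupCap:
    def test_cap_from_best_outgroup_hit(self):
        cap = compute_outgroup_cap("seed", [_hit("seed", "o1", 1e-30, rank=4)])
        assert cap.evalue == 1e-30 and not cap.open_cap

    def test_no_outgroup_hit_gives_open_cap(self):
        cap = compute_outgroup_cap("seed", [])
        assert cap.open_cap
        assert cap.admits(_hit("seed", "x", 1.0, rank=99))

    def test_rank_one_rule_with_two_outgroup_hits(self):
        cap = compute_outgroup_cap("seed", [
            _hit("seed", "o2", 1e-10, rank=7), _hit("seed", "o1", 1e-30, rank=3)])
        assert cap.evalue == 1e-30

    def test_strict_inequality_and_zero_zero_rank_tiebreak(self):
        cap = OutgroupCap(evalue=1e-30, bitscore=100, rank=5, open_cap=False)
        assert cap.admits(_hit("s", "a", 1e-40))
        assert not cap.admits(_hit("s", "a", 1e-30))   # equality rejected
        zero_cap = OutgroupCap(evalue=0.0, bitscore=500, rank=6, open_cap=False)
        assert zero_cap.admits(_hit("s", "a", 0.0, rank=2))
        assert not zero_cap.admits(_hit("s", "a", 0.0, rank=9))


class TestMergeSeeds:
    PREC = ["Ptri", "Tpse", "Aano"]

    def _caps(self, ids, evalue=1e-30):
        return {i: OutgroupCap(evalue=evalue, bitscore=100, rank=5,
                               open_cap=False) for i in ids}

    def test_hit_below_cap_merges(self):
        ids = ["pennates|Ptri|a", "thalassiosirales|Tpse|b"]
        hits = {ids[0]: [_hit(ids[0], ids[1], 1e-50)]}
        retained, mapping = merge_seeds(ids, hits, self._caps(ids), self.PREC)
        assert retained == ["pennates|Ptri|a"]       # precedence keeps Ptri
        assert mapping[ids[1]] == ids[0]

    def test_hit_above_cap_does_not_merge(self):
        ids = ["pennates|Ptri|a", "thalassiosirales|Tpse|b"]
        hits = {ids[0]: [_hit(ids[0], ids[1], 1e-20)]}
        retained, _ = merge_seeds(ids, hits, self._caps(ids), self.PREC)
        assert len(retained) == 2

    def test_duplicate_precedence_is_a_configuration_error(self):
        with pytest.raises(ValueError):
            merge_seeds([], {}, {}, ["Ptri", "Ptri"])

    def test_transitive_closure_matches_union_find_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n = int(rng.integers(5, 21))
            ids = [f"pennates|sp{i}|c{i}" for i in range(n)]
            caps = self._caps(ids)
            hits = {}
            for i in ids:
                out = []
                for j in ids:
                    if i != j and rng.random() < 0.15:
                        out.append(_hit(i, j, 10.0 ** -int(rng.integers(10, 60))))
                hits[i] = out

            def related(a, b):
                return any(h.subject_id == b and caps[a].admits(h)
                           for h in hits[a])

            _, mapping = merge_seeds(ids, hits, caps, [])
            ours = {}
            for member, keeper in mapping.items():
                ours.setdefault(keeper, set()).add(member)
            expected = {frozenset(c) for c in
                        transitive_closure_clusters(ids, related)}
            assert {frozenset(v) for v in ours.values()} == expected


class TestGrow:
    def test_admission_boundaries(self, taxonomy):
        seed = _rec("pennates|Ptri|s")
        cap = OutgroupCap(evalue=1e-30, bitscore=100, rank=4, open_cap=False)
        hits = [_hit(seed.seq_id, "px|Esil|in", 1e-40, rank=1),
                _hit(seed.seq_id, "pesc|Ngad|at", 1e-30, rank=2)]
        seqs = {"px|Esil|in": _rec("px|Esil|in"),
                "pesc|Ngad|at": _rec("pesc|Ngad|at")}
        hppg, _ = grow_hppg(seed, hits, cap, taxonomy, seqs)
        assert "px|Esil|in" in hppg.member_ids
        assert "pesc|Ngad|at" not in hppg.member_ids

    def test_members_trimmed_to_first_methionine(self, taxonomy):
        seed = _rec("pennates|Ptri|s")
        cap = OutgroupCap(evalue=1e-30, bitscore=100, rank=4, open_cap=False)
        hits = [_hit(seed.seq_id, "px|Esil|m", 1e-40)]
        seqs = {"px|Esil|m": _rec("px|Esil|m", "GAVMKLRST")}
        hppg, trimmed = grow_hppg(seed, hits, cap, taxonomy, seqs)
        assert trimmed["px|Esil|m"] == "MKLRST"

    def test_member_without_methionine_excluded(self, taxonomy, caplog):
        seed = _rec("pennates|Ptri|s")
        cap = OutgroupCap(evalue=1e-30, bitscore=100, rank=4, open_cap=False)
        hits = [_hit(seed.seq_id, "px|Esil|nom", 1e-40)]
        seqs = {"px|Esil|nom": _rec("px|Esil|nom", "GAVKLRST")}
        with caplog.at_level("INFO", logger="paleoplastid"):
            hppg, _ = grow_hppg(seed, hits, cap, taxonomy, seqs)
        assert "px|Esil|nom" not in hppg.member_ids


def _hppg(presence):
    h = HPPG(hppg_id="h", seed_id="s", member_ids=["s"])
    h.presence = dict(presence)
    return h


CHRYSISTA = ("px", "raphidophytes", "pesc")
HYPO = ("pelagophytes", "dictyochophytes", "bolidophytes")
DIATOMS = ("corethron", "radial_centrics", "thalassiosirales",
           "odontellids", "pennates")


class TestConservation:
    def test_pattern_one(self, taxonomy):
        presence = {s: 1 for s in CHRYSISTA[:2] + DIATOMS[:3]}
        assert evaluate_conservation(_hppg(presence), taxonomy) == {"P1"}

    def test_pattern_three(self, taxonomy):
        presence = {s: 1 for s in CHRYSISTA[:1] + HYPO[:2] + DIATOMS[:3]}
        assert evaluate_conservation(_hppg(presence), taxonomy) == {"P3"}

    def test_empty_presence_stays_candidate(self, taxonomy):
        h = _hppg({})
        assert evaluate_conservation(h, taxonomy) == set()
        assert h.status == "candidate"

    @settings(max_examples=60, deadline=None)
    @given(st.sets(st.sampled_from(CHRYSISTA + HYPO + DIATOMS)),
           st.sampled_from(CHRYSISTA + HYPO + DIATOMS))
    def test_adding_a_member_never_removes_a_pattern(self, taxonomy, subs,
                                                     extra):
        before = evaluate_conservation(
            _hppg({s: 1 for s in subs}), taxonomy)
        after = evaluate_conservation(
            _hppg({s: 1 for s in subs | {extra}}), taxonomy)
        assert before <= after


class TestPatternSelection:
    def test_perfect_separation_ranks_first(self, taxonomy):
        good = ConservationPattern("good", {"chrysista": 2 / 3})
        bad = ConservationPattern("bad", {"diatoms": 1 / 5})
        pos = [_hppg({s: 1 for s in CHRYSISTA + DIATOMS[:1]})
               for _ in range(10)]
        neg = [_hppg({"corethron": 1}) for _ in range(10)]
        ranked = select_conservation_patterns([bad, good], pos, neg, taxonomy)
        assert ranked[0][0].pattern_id == "good"

    def test_identical_pass_rates_give_zero_statistic(self, taxonomy):
        p = ConservationPattern("p", {"chrysista": 2 / 3})
        controls = [_hppg({s: 1 for s in CHRYSISTA}) for _ in range(5)]
        ranked = select_conservation_patterns([p], controls, list(controls),
                                              taxonomy)
        assert ranked[0][1] == pytest.approx(0.0)

    def test_statistic_matches_hand_computed_chi_squared(self, taxonomy):
        # 16/20 positives pass, 4/20 negatives pass:
        # chi2 = sum (o-e)^2/e over the 2x2 with margins 20/20 and 20/20
        p = ConservationPattern("p", {"chrysista": 2 / 3})
        passing = _hppg({s: 1 for s in CHRYSISTA})
        failing = _hppg({"px": 1})
        pos = [passing] * 16 + [failing] * 4
        neg = [passing] * 4 + [failing] * 16
        ranked = select_conservation_patterns([p], pos, neg, taxonomy)
        assert ranked[0][1] == pytest.approx(14.4)   # classic Pearson value


class TestCuration:
    def _alignment(self, late_by=0, n=6, ncol=120):
        rows = {}
        core = "ACDEFGHIKLMNPQRSTVWY" * (ncol // 20)
        for i in range(n):
            sub = (CHRYSISTA + DIATOMS)[i % 8]
            sid = f"{sub}|sp{i}|m{i}"
            rows[sid] = core
        late_sub = DIATOMS[-1]
        late_id = f"{late_sub}|spL|late"
        rows[late_id] = "-" * late_by + core[late_by:]
        return rows, late_id

    def test_member_starting_sixty_positions_late_removed(self, taxonomy):
        rows, late_id = self._alignment(late_by=60)
        hppg = HPPG(hppg_id="h", seed_id=list(rows)[0],
                    member_ids=list(rows))
        hppg.recount_presence(taxonomy)
        curated, kept = curate_alignment(hppg, rows, taxonomy)
        assert late_id not in kept

    def test_member_starting_ten_positions_late_retained(self, taxonomy):
        rows, late_id = self._alignment(late_by=10)
        hppg = HPPG(hppg_id="h", seed_id=list(rows)[0],
                    member_ids=list(rows))
        hppg.recount_presence(taxonomy)
        curated, kept = curate_alignment(hppg, rows, taxonomy)
        assert late_id in kept

    def test_removal_that_breaks_conservation_eliminates_the_hppg(
            self, taxonomy):
        # chrysista presence hangs on one member that curation removes
        core = "ACDEFGHIKLMNPQRSTVWY" * 6
        rows = {f"{s}|sp|{s}": core for s in DIATOMS}
        rows["px|spX|frail"] = "-" * 70 + core[70:]
        rows["raphidophytes|spY|frail2"] = "-" * 70 + core[70:]
        hppg = HPPG(hppg_id="h", seed_id=list(rows)[0], member_ids=list(rows))
        hppg.recount_presence(taxonomy)
        assert evaluate_conservation(hppg, taxonomy)   # P1 before curation
        curated, _ = curate_alignment(hppg, rows, taxonomy)
        assert curated is None


class TestTrimColumns:
    @pytest.mark.parametrize("occupied,kept", [(6, True), (5, True),
                                               (4, False)])
    def test_keep_fraction_boundary(self, occupied, kept):
        rows = {f"s{i}": ("A" if i < occupied else "-") + "CC"
                for i in range(10)}
        trimmed = trim_columns(rows, keep_fraction=0.5)
        assert (len(next(iter(trimmed.values()))) == 3) == kept

    def test_row_order_preserved(self):
        rows = {"b": "AC", "a": "AC", "c": "AC"}
        assert list(trim_columns(rows)) == ["b", "a", "c"]

    def test_vanished_alignment_is_an_error(self):
        rows = {f"s{i}": "A-" if i == 0 else "-A" for i in range(10)}
        with pytest.raises(ValueError, match="vanished"):
            trim_columns(rows, keep_fraction=0.95)


class TestCladeCheck:
    def _tree(self, newick, taxonomy):
        return parse_tree(newick, taxonomy)

    def test_pure_ochrophyte_clade_passes(self, taxonomy):
        leaves = ",".join(f"{s}|sp|{s}" for s in CHRYSISTA + DIATOMS)
        t = self._tree(f"(({leaves}),cyanidiales|Cmer|r);", taxonomy)
        ok, offenders = check_ochrophyte_clade(t, taxonomy)
        assert ok

    def test_single_red_interruption_allowed(self, taxonomy):
        inner = ",".join(f"{s}|sp|{s}" for s in CHRYSISTA + DIATOMS)
        t = self._tree(f"((({inner}),cyanidiales|Cmer|r),"
                       "(streptophytes|Atha|g,opisthokonts|Scer|o));",
                       taxonomy)
        ok, _ = check_ochrophyte_clade(t, taxonomy)
        assert ok

    def test_two_interrupting_groups_fail(self, taxonomy):
        half1 = ",".join(f"{s}|sp|{s}" for s in CHRYSISTA)
        half2 = ",".join(f"{s}|sp|{s}" for s in DIATOMS)
        t = self._tree(
            f"((({half1}),cyanidiales|Cmer|r),(({half2}),"
            "streptophytes|Atha|g),(opisthokonts|Scer|o,amoebozoa|Ddis|a));",
            taxonomy)
        ok, offenders = check_ochrophyte_clade(t, taxonomy)
        assert not ok

    def test_tiny_tree_uninformative(self, taxonomy):
        t = self._tree("(px|sp|a,(pennates|Ptri|b,cyanidiales|Cmer|c));",
                       taxonomy)
        ok, offenders = check_ochrophyte_clade(t, taxonomy)
        assert not ok and offenders == {"uninformative"}
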