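import numpy as np
import pandas as pd
import pytest

from paleoplastid.enrichment_stats import (category_enrichment,
                                           chi_squared_obs_exp,
                                           coexpression_by_origin,
                                           count_unique_shared,
                                           expected_pair_fraction,
                                           expected_unique_shared,
                                           neighbour_origin_concordance,
                                           targeting_enrichment)
from paleoplastid.synthetic_data import (simulate_expression,
                                         simulate_family_labels)

SUBCATS = {"diatoms": 5, "hypogyristea": 3, "chrysista": 3,
           "haptophytes": 3, "cryptomonads": 2}


def _presence(rows):
    """rows: hppg -> {lineage: n subcats present}"""
    return {h: {lin: set(f"{lin}{i}" for i in range(n))
                for lin, n in by.items()}
            for h, by in rows.items()}


class TestCountUniqueShared:
    def test_majority_plus_any(self):
        presence = _presence({
            "h1": {"haptophytes": 2, "hypogyristea": 1},       # qualifies
            "h2": {"haptophytes": 1, "hypogyristea": 1},       # no majority
            "h3": {"haptophytes": 2, "hypogyristea": 1, "diatoms": 1},
        })
        n = count_unique_shared(presence, ("haptophytes", "hypogyristea"),
                                "majority+any", SUBCATS)
        assert n == 1

    def test_third_lineage_disqualifies(self):
        presence = _presence({
            "h": {"haptophytes": 3, "hypogyristea": 2, "diatoms": 1}})
        assert count_unique_shared(presence, ("haptophytes", "hypogyristea"),
                                   "majority+any", SUBCATS) == 0

    def test_matches_exhaustive_row_scan(self):
        rng = np.random.default_rng(2)
        lineages = list(SUBCATS)
        presence = {}
        for i in range(30):
            by = {}
            for lin in lineages:
                if rng.random() < 0.5:
                    by[lin] = int(rng.integers(1, SUBCATS[lin] + 1))
            presence[f"h{i}"] = by
        pres = _presence(presence)
        pair = ("haptophytes", "hypogyristea")
        got = count_unique_shared(pres, pair, "majority+majority", SUBCATS)
        expect = 0
        for h, by in presence.items():
            if set(by) != set(pair):
                continue
            if all(by[lin] / SUBCATS[lin] >= 2 / 3 - 1e-12 for lin in pair):
                expect += 1
        assert got == expect


class TestExpectedUniqueShared:
    def test_published_worked_example(self):
        # involvement proportions one half each -> corrected third
        assert expected_pair_fraction(0.5, 0.5) == pytest.approx(1 / 3)

    def test_published_mode_on_counts(self):
        # haptophytes involved in 20/40, diatoms in 20/40: the published
        # correction gives 40 * (1/2)(1/2)/(1 - 1/4) = 40/3
        counts = {("haptophytes", "diatoms"): 10,
                  ("haptophytes", "chrysista"): 10,
                  ("diatoms", "cryptomonads"): 10,
                  ("chrysista", "cryptomonads"): 10}
        out = expected_unique_shared(counts, correction="published")
        assert out[("haptophytes", "diatoms")] == pytest.approx(40 / 3)

    def test_normalized_three_symmetric_lineages(self):
        counts = {("a", "b"): 10, ("a", "c"): 10, ("b", "c"): 10}
        out = expected_unique_shared(counts, correction="normalized")
        for pair in counts:
            assert out[pair] == pytest.approx(10.0)

    def test_normalized_mode_conserves_the_total(self):
        rng = np.random.default_rng(0)
        lineages = ["a", "b", "c", "d"]
        counts = {}
        for i in range(len(lineages)):
            for j in range(i + 1, len(lineages)):
                counts[(lineages[i], lineages[j])] = int(rng.integers(0, 30))
        out = expected_unique_shared(counts, correction="normalized")
        assert sum(out.values()) == pytest.approx(sum(counts.values()))

    def test_single_lineage_is_an_error(self):
        with pytest.raises(ValueError):
            expected_unique_shared({})


class TestChiSquared:
    def test_observed_equals_expected(self):
        res = chi_squared_obs_exp(10, 10.0, 100)
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        res = chi_squared_obs_exp(15, 5.0, 100)
        assert res.statistic == pytest.approx(100 / 5 + 100 / 95)

    def test_p_decreases_with_distance(self):
        ps = [chi_squared_obs_exp(5 + d, 5.0, 100).p for d in (1, 4, 8, 12)]
        assert ps == sorted(ps, reverse=True)

    def test_invalid_totals_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_obs_exp(10, 5.0, 8)
        with pytest.raises(ValueError):
            chi_squared_obs_exp(1, 0.0, 10)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(123)
        n, q = 400, 0.25
        draws = rng.binomial(n, q, size=2000)
        rejections = 0
        for obs in draws:
            res = chi_squared_obs_exp(int(obs), n * q, n)
            rejections += res.p < 0.05
        assert 0.03 <= rejections / 2000 <= 0.07


class TestTargetingEnrichment:
    def test_expected_is_proportional(self):
        fams = pd.DataFrame({
            "origin": ["red"] * 10 + ["host"] * 90,
            "plastid": [True] * 3 + [False] * 7 + [True] * 27 + [False] * 63})
        res = targeting_enrichment(fams)
        assert res["red"].expected == pytest.approx(30 * 10 / 100)

    def test_expectations_sum_to_plastid_total(self):
        rng = np.random.default_rng(1)
        fams = simulate_family_labels(
            rng, 500, {"red": 0.4, "green": 0.3, "host": 0.3},
            {"red": 0.5, "green": 0.4, "host": 0.2})
        res = targeting_enrichment(fams)
        assert sum(r.expected for r in res.values()) == \
            pytest.approx(fams["plastid"].sum())

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(7)
        fams = simulate_family_labels(
            rng, 2000,
            {"red algae": 0.3, "green algae": 0.2,
             "aplastidic stramenopiles": 0.3, "prokaryotes": 0.2},
            {"red algae": 0.6, "green algae": 0.5,
             "aplastidic stramenopiles": 0.15, "prokaryotes": 0.15})
        res = targeting_enrichment(fams)
        assert res["red algae"].significant
        assert res["green algae"].significant
        assert res["red algae"].observed > res["red algae"].expected
        assert not (res["aplastidic stramenopiles"].significant
                    and res["aplastidic stramenopiles"].observed
                    > res["aplastidic stramenopiles"].expected)


class TestCategoryEnrichment:
    def test_matching_proportions_no_flags(self):
        res = category_enrichment({"a": 10, "b": 20},
                                  {"a": 100, "b": 200})
        assert not any(r.significant for r in res.values())

    def test_overrepresented_category_flagged(self):
        res = category_enrichment({"a": 60, "b": 140},
                                  {"a": 100, "b": 900})
        assert res["a"].significant

    def test_flags_invariant_under_category_order(self):
        subset = {"a": 60, "b": 140, "c": 30}
        background = {"a": 100, "b": 900, "c": 130}
        res1 = category_enrichment(subset, background)
        res2 = category_enrichment(dict(reversed(list(subset.items()))),
                                   background)
        assert {k: r.significant for k, r in res1.items()} == \
            {k: r.significant for k, r in res2.items()}


class TestNeighbourConcordance:
    def test_uniform_origin_zero_statistic(self):
        pairs = [(f"p{i}", f"q{i}") for i in range(10)]
        origins = {p: "red" for pair in pairs for p in pair}
        res = neighbour_origin_concordance(pairs, origins)
        assert res.statistic == 0.0

    def test_toy_fixture_matches_hand_computation(self):
        pairs = [("a", "b"), ("c", "d"), ("e", "f"),
                 ("g", "h"), ("i", "j"), ("k", "l")]
        origins = dict(a="r", b="r", c="r", d="g", e="g", f="g",
                       g="r", h="r", i="g", j="r", k="r", l="g")
        res = neighbour_origin_concordance(pairs, origins)
        assert res.observed == 3
        q_r, q_g = 7 / 12, 5 / 12
        assert res.expected == pytest.approx(6 * (q_r ** 2 + q_g ** 2))

    def test_random_pairing_ratio_near_one(self):
        rng = np.random.default_rng(4)
        proteins = [f"p{i}" for i in range(400)]
        origins = {p: ("red" if rng.random() < 0.5 else "green")
                   for p in proteins}
        pairs = [(proteins[i], proteins[i + 1])
                 for i in range(0, 1000 % 400, 2)]
        pairs = []
        for _ in range(1000):
            i, j = rng.choice(400, 2, replace=False)
            pairs.append((proteins[i], proteins[j]))
        res = neighbour_origin_concordance(pairs, origins)
        assert res.observed / res.expected == pytest.approx(1.0, abs=0.1)


class TestCoexpression:
    def test_identical_profiles_correlate_perfectly(self):
        x = np.sin(np.arange(12))
        expr = pd.DataFrame([x, x, x + 1], index=["a", "b", "c"])
        summary = coexpression_by_origin(expr, {"a": "r", "b": "r", "c": "r"})
        assert summary.class_means[("r", "r")] == pytest.approx(1.0)

    def test_null_expression_rarely_flagged(self):
        flags = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            genes = [f"g{i}" for i in range(24)]
            origins = {g: ["red", "green", "host", "prok"][i % 4]
                       for i, g in enumerate(genes)}
            expr = simulate_expression(rng, genes, 0.6, 24)
            summary = coexpression_by_origin(expr, origins)
            flags += bool(summary.flagged)
        assert flags <= 1   # >= 95% of seeds flag nothing

    def test_origin_structured_expression_is_flagged(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(28)]
        origins = {g: "rghp"[i % 4] for i, g in enumerate(genes)}
        base = {o: rng.standard_normal(24) for o in "rghp"}
        data = np.array([0.9 * base[origins[g]]
                         + 0.45 * rng.standard_normal(24) for g in genes])
        expr = pd.DataFrame(data, index=genes)
        summary = coexpression_by_origin(expr, origins)
        assert set(summary.flagged) == set("rghp")

    def test_constant_vector_excluded(self, caplog):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.standard_normal((4, 10)),
                            index=["a", "b", "c", "d"])
        expr.loc["d"] = 1.0
        summary = coexpression_by_origin(
            expr, {"a": "r", "b": "r", "c": "g", "d": "g"})
        assert ("g", "g") not in summary.class_values
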