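import numpy as np
import pandas as pd
import pytest

import enrichcord as ec
from enrichcord.exceptions import AnalysisError, ParameterError
from enrichcord.gsea import _es_batch


def brute_force_es(scores, member_mask, weight):
    """Independent loop-based running-sum recomputation (the oracle)."""
    n = len(scores)
    nh = int(np.sum(member_mask))
    total = sum(abs(scores[i]) ** weight for i in range(n) if member_mask[i])
    running, best, best_abs = [], 0.0, -1.0
    acc = 0.0
    for i in range(n):
        if member_mask[i]:
            acc += (abs(scores[i]) ** weight) / total if total else 1.0 / nh
        else:
            acc -= 1.0 / (n - nh)
        running.append(acc)
        if abs(acc) > best_abs:
            best_abs, best = abs(acc), acc
    return best, np.array(running)


def ranked_from(scores, genes=None):
    genes = genes or [f"g{i:03d}" for i in range(len(scores))]
    return ec.RankedList(genes, np.asarray(scores, dtype=float))


class TestBuildRankedList:
    def _stats(self):
        table = pd.DataFrame({
            "t_stat": [1, -2, 1], "t_p": [0.5, 0.01, 0.5],
            "log2fc": [2.0, -3.0, 1.0],
            "sam_d": [1.0, -2.0, 0.5], "sam_p": [0.1, 0.1, 0.1],
        }, index=pd.Index(["a", "b", "c"], name="gene"))
        return ec.GeneStatistics(table, 5, 5)

    def test_fc_metric_sorts_signed_descending(self):
        deg = ec.DEGList(ec.DEGCriterion("FC", 0.05), ["a", "b", "c"],
                         np.array([2.0, 3.0, 1.0]))
        ranked = ec.build_ranked_list(deg, self._stats())
        assert list(ranked.scores) == [2.0, 1.0, -3.0]
        assert ranked.genes == ["a", "c", "b"]

    def test_ttest_metric_is_signed_neg_log10_p(self):
        deg = ec.DEGList(ec.DEGCriterion("TTEST", 0.05), ["b"], np.array([0.01]))
        ranked = ec.build_ranked_list(deg, self._stats())
        assert ranked.scores[0] == pytest.approx(-2.0)

    def test_tied_metric_breaks_by_gene_id(self):
        table = pd.DataFrame({
            "t_stat": [0, 0], "t_p": [0.5, 0.5], "log2fc": [1.0, 1.0],
            "sam_d": [0, 0], "sam_p": [1, 1],
        }, index=pd.Index(["zz", "aa"], name="gene"))
        stats = ec.GeneStatistics(table, 5, 5)
        deg = ec.DEGList(ec.DEGCriterion("FC", 0.05), ["zz", "aa"],
                         np.array([1.0, 1.0]))
        assert ec.build_ranked_list(deg, stats).genes == ["aa", "zz"]

    def test_missing_metric_is_an_analysis_error(self):
        deg = ec.DEGList(ec.DEGCriterion("FC", 0.05), ["nope"], np.array([1.0]))
        with pytest.raises(AnalysisError):
            ec.build_ranked_list(deg, self._stats())


class TestEnrichmentScore:
    def test_unweighted_micro_example(self):
        ranked = ranked_from([4.0, 3.0, 2.0, 1.0])
        es, _idx, running = ec.enrichment_score(
            ranked, {ranked.genes[0], ranked.genes[2]}, weight_exponent=0.0)
        np.testing.assert_allclose(running, [0.5, 0.0, 0.5, 0.0], atol=1e-12)
        assert es == pytest.approx(0.5, abs=1e-12)

    def test_weighted_micro_example(self):
        ranked = ranked_from([4.0, 3.0, 2.0, 1.0])
        es, _idx, running = ec.enrichment_score(
            ranked, {ranked.genes[0], ranked.genes[3]}, weight_exponent=1.0)
        np.testing.assert_allclose(running, [0.8, 0.3, -0.2, 0.0], atol=1e-12)
        assert es == pytest.approx(0.8, abs=1e-12)

    def test_terminal_hit_reaches_minus_one(self):
        ranked = ranked_from(np.arange(10, 0, -1, dtype=float))
        es, idx, _run = ec.enrichment_score(
            ranked, {ranked.genes[-1]}, weight_exponent=0.0)
        assert es == pytest.approx(-1.0, abs=1e-12)
        assert idx == 8      # extremum just before the terminal hit

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 21))
            scores = np.sort(rng.normal(size=n))[::-1]
            k = int(rng.integers(1, n))
            members = rng.choice(n, size=k, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[members] = True
            ranked = ranked_from(scores)
            for w in (0.0, 1.0):
                es, _i, run = ec.enrichment_score(
                    ranked, {ranked.genes[j] for j in members}, w)
                ref_es, ref_run = brute_force_es(scores, mask, w)
                assert es == pytest.approx(ref_es, abs=1e-12)
                np.testing.assert_allclose(run, ref_run, atol=1e-12)
                assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12
                assert abs(run[-1]) < 1e-9      # increments conserve to zero

    def test_weight_zero_is_classic_ks(self, rng):
        """With w=0 the running sum is the scaled difference of hit/miss ECDFs."""
        for _ in range(50):
            n = int(rng.integers(5, 30))
            scores = np.sort(rng.normal(size=n))[::-1]
            k = int(rng.integers(1, n))
            members = set(rng.choice(n, size=k, replace=False).tolist())
            ranked = ranked_from(scores)
            _es, _i, run = ec.enrichment_score(
                ranked, {ranked.genes[j] for j in members}, 0.0)
            hits = np.cumsum([1 if j in members else 0 for j in range(n)])
            misses = np.arange(1, n + 1) - hits
            ks = hits / k - misses / (n - k)
            np.testing.assert_allclose(run, ks, atol=1e-12)

    def test_tied_score_reordering_bounded_by_step(self, rng):
        scores = np.array([2.0, 1.0, 1.0, 0.5, -1.0, -2.0])
        genes = ["a", "b", "c", "d", "e", "f"]
        members = {"b", "e"}
        r1 = ec.RankedList(genes, scores)
        genes2 = ["a", "c", "b", "d", "e", "f"]   # swap the tied pair
        r2 = ec.RankedList(genes2, scores)
        es1 = ec.enrichment_score(r1, members, 1.0)[0]
        es2 = ec.enrichment_score(r2, members, 1.0)[0]
        step = max(1.0 / (len(genes) - len(members)),
                   max(abs(scores)) / sum(abs(scores[i]) for i in (1, 4)))
        assert abs(es1 - es2) <= step + 1e-12

    def test_no_members_or_all_members_rejected(self):
        ranked = ranked_from([3.0, 2.0, 1.0])
        with pytest.raises(ParameterError):
            ec.enrichment_score(ranked, {"absent"}, 1.0)
        with pytest.raises(ParameterError):
            ec.enrichment_score(ranked, set(ranked.genes), 1.0)


class TestPermutationNull:
    def test_symmetric_scores_give_centred_null(self):
        scores = np.concatenate([np.arange(50, 0, -1), -np.arange(1, 51)]) * 0.1
        ranked = ranked_from(np.sort(scores)[::-1])
        null = ec.gene_set_permutation_null(ranked, 10, 1000, 0.0, seed=4)
        se = null.std(ddof=1) / np.sqrt(null.size)
        assert abs(null.mean()) < 3 * se

    def test_same_seed_reproducible(self):
        ranked = ranked_from(np.arange(30, 0, -1, dtype=float))
        a = ec.gene_set_permutation_null(ranked, 5, 200, 1.0, seed=9)
        b = ec.gene_set_permutation_null(ranked, 5, 200, 1.0, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_batch_es_agrees_with_scalar_path(self, rng):
        scores = np.sort(rng.normal(size=40))[::-1]
        ranked = ranked_from(scores)
        hits = np.array([rng.choice(40, size=6, replace=False)
                         for _ in range(20)])
        batch = _es_batch(scores, hits, 1.0)
        for row, h in zip(batch, hits):
            ref = ec.enrichment_score(ranked, {ranked.genes[j] for j in h}, 1.0)[0]
            assert row == pytest.approx(ref, abs=1e-12)

    def test_parameter_errors(self):
        ranked = ranked_from([3.0, 2.0, 1.0])
        with pytest.raises(ParameterError):
            ec.gene_set_permutation_null(ranked, 3, 200, 1.0, seed=0)
        with pytest.raises(ParameterError):
            ec.gene_set_permutation_null(ranked, 1, 50, 1.0, seed=0)


class TestNormalizeAndFdr:
    def test_es_equal_to_mean_positive_null_gives_nes_one(self, rng):
        null = np.concatenate([rng.uniform(0.1, 0.5, 500),
                               -rng.uniform(0.1, 0.5, 500)])
        mu = null[null > 0].mean()
        out = ec.normalize_and_fdr({"s": mu}, {"s": null})
        assert out["s"][0] == pytest.approx(1.0)

    def test_es_beyond_every_null_gets_q_zero(self, rng):
        null = rng.uniform(-0.3, 0.3, 1000)
        out = ec.normalize_and_fdr({"s": 0.99}, {"s": null})
        assert out["s"][1] == 0.0

    def test_duplicate_sets_identical_results(self, rng):
        null = rng.uniform(-0.4, 0.4, 500)
        out = ec.normalize_and_fdr({"a": 0.3, "b": 0.3},
                                   {"a": null, "b": null.copy()})
        assert out["a"] == out["b"]

    def test_q_monotone_in_abs_nes_within_sign(self, rng):
        observed = {f"s{i}": float(es)
                    for i, es in enumerate(rng.uniform(-0.6, 0.6, 40))}
        nulls = {sid: rng.uniform(-0.4, 0.4, 300) for sid in observed}
        out = ec.normalize_and_fdr(observed, nulls)
        for sign in (1, -1):
            rows = sorted(((nes, q) for nes, q in out.values()
                           if (nes >= 0) == (sign == 1)),
                          key=lambda t: abs(t[0]))
            qs = [q for _nes, q in rows]
            assert all(qs[i] >= qs[i + 1] - 1e-12 for i in range(len(qs) - 1))


class TestRunGsea:
    def test_recovers_planted_sets(self, desk_study, desk_stats):
        _studies, sets, truth = desk_study
        deg = ec.select_degs(desk_stats, ec.DEGCriterion("FC", 0.05))
        res = ec.run_gsea(deg, desk_stats, sets, seed=3)
        sig = {r.set_id for r in res if r.significant()}
        assert len(sig & set(truth.planted_sets)) >= 8

    def test_absent_sets_are_dropped(self, desk_stats):
        coll = ec.GeneSetCollection({
            "IN": ec.GeneSet("IN", "", tuple(desk_stats.genes[:30])),
            "OUT": ec.GeneSet("OUT", "", ("nope1", "nope2", "nope3",
                                          "nope4", "nope5")),
        })
        deg = ec.select_degs(desk_stats, ec.DEGCriterion("TTEST", 0.05))
        res = ec.run_gsea(deg, desk_stats, coll, seed=1, n_perm=200)
        ids = {r.set_id for r in res}
        assert "OUT" not in ids

    def test_direction_matches_es_sign(self, desk_study, desk_stats):
        _studies, sets, _truth = desk_study
        deg = ec.select_degs(desk_stats, ec.DEGCriterion("SAM", 0.05))
        res = ec.run_gsea(deg, desk_stats, sets, seed=2, n_perm=200)
        assert all((r.direction == "pos") == (r.es > 0) for r in res)
        assert all(0.0 <= r.fdr_q <= 1.0 for r in res)
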