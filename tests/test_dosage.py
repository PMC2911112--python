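import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ds21 import (
    ConfigurationError,
    DosageClassifier,
    ExpressionMatrix,
    FormatError,
    GeneSet,
    basal_ranking,
    classify_dosage,
    disorder_group_test,
    disorder_score,
    gsea_enrichment_score,
    gsea_significance,
)


def profile_from(ids, metric):
    return pd.DataFrame({"id": ids, "mean_expression": metric, "sd": 0.0})


def brute_force_es(ids, metric, members, weight_p):
    """Running sum computed step by step, straight from its definition."""
    hits = [i in members for i in ids]
    n, n_hit = len(ids), sum(hits)
    n_r = sum(abs(m) ** weight_p for m, h in zip(metric, hits) if h)
    rs, best = 0.0, 0.0
    for m, h in zip(metric, hits):
        if h:
            rs += (abs(m) ** weight_p / n_r) if n_r > 0 else 1.0 / n_hit
        else:
            rs -= 1.0 / (n - n_hit)
        if abs(rs) > abs(best) + 1e-12:  # earliest extreme wins on ties
            best = rs
    return best


class TestBasalRanking:
    def test_orders_by_descending_mean(self):
        df = pd.DataFrame({"s1": [8.0, 5.0], "s2": [8.0, 5.0]}, index=["hi", "lo"])
        profile = basal_ranking(ExpressionMatrix(df))
        assert profile["id"].tolist() == ["hi", "lo"]
        assert profile["rank"].tolist() == [1, 2]

    def test_constant_matrix_ties_break_by_id(self):
        df = pd.DataFrame({"s1": [1.0] * 3, "s2": [1.0] * 3}, index=["c", "a", "b"])
        profile = basal_ranking(ExpressionMatrix(df))
        assert profile["id"].tolist() == ["a", "b", "c"]

    def test_empty_matrix_rejected(self):
        with pytest.raises(FormatError):
            basal_ranking(ExpressionMatrix(pd.DataFrame()))

    def test_silent_genes_rank_above_effective(self, study):
        matrix, _, truth = study
        profile = basal_ranking(matrix)
        rank_of = dict(zip(profile["id"], profile["rank"]))
        silent = np.median([rank_of[truth.transgene_probes[g]] for g in truth.silent_genes])
        effective = np.median(
            [rank_of[truth.transgene_probes[g]] for g in truth.effective_genes]
        )
        assert silent < effective  # rank 1 = most expressed


class TestEnrichmentScore:
    def test_top_hit_reaches_plus_one(self):
        profile = profile_from(list("abcde"), [5.0, 4.0, 3.0, 2.0, 1.0])
        assert gsea_enrichment_score(profile, GeneSet("s", frozenset("a"))) == pytest.approx(1.0)

    def test_bottom_hit_reaches_minus_one(self):
        profile = profile_from(list("abcde"), [5.0, 4.0, 3.0, 2.0, 1.0])
        assert gsea_enrichment_score(profile, GeneSet("s", frozenset("e"))) == pytest.approx(-1.0)

    def test_equals_brute_force_on_all_small_subsets(self):
        """Exhaustive check against the step-by-step running sum, N <= 8."""
        rng = np.random.default_rng(4)
        for n in (4, 6, 8):
            metric = np.sort(rng.uniform(0.5, 5.0, size=n))[::-1]
            ids = [f"g{i}" for i in range(n)]
            profile = profile_from(ids, metric)
            for r in range(1, n):
                for members in itertools.combinations(ids, r):
                    for weight_p in (0.0, 1.0):
                        es = gsea_enrichment_score(
                            profile, GeneSet("s", frozenset(members)), weight_p
                        )
                        expected = brute_force_es(ids, metric, set(members), weight_p)
                        assert es == pytest.approx(expected, abs=1e-12)

    def test_weight_zero_is_ks_statistic(self):
        """At p=0 the score is the signed KS distance between the hit and
        miss empirical step functions."""
        rng = np.random.default_rng(9)
        n = 40
        ids = [f"g{i}" for i in range(n)]
        metric = np.sort(rng.normal(size=n))[::-1]
        members = frozenset(rng.choice(ids, size=12, replace=False))
        profile = profile_from(ids, metric)
        es = gsea_enrichment_score(profile, GeneSet("s", members), weight_p=0.0)
        hits = np.array([i in members for i in ids])
        f_hit = np.cumsum(hits) / hits.sum()
        f_miss = np.cumsum(~hits) / (~hits).sum()
        diff = f_hit - f_miss
        assert es == pytest.approx(diff[np.argmax(np.abs(diff))], abs=1e-12)

    def test_es_invariant_under_monotone_metric_transform_at_p0(self):
        ids = [f"g{i}" for i in range(20)]
        metric = np.linspace(10, 1, 20)
        members = frozenset(ids[2:7])
        p1 = profile_from(ids, metric)
        p2 = profile_from(ids, np.exp(metric))  # same order, different values
        es1 = gsea_enrichment_score(p1, GeneSet("s", members), weight_p=0.0)
        es2 = gsea_enrichment_score(p2, GeneSet("s", members), weight_p=0.0)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_full_coverage_set_rejected(self):
        profile = profile_from(list("ab"), [2.0, 1.0])
        with pytest.raises(ConfigurationError):
            gsea_enrichment_score(profile, GeneSet("s", frozenset("ab")))

    def test_disjoint_set_rejected(self):
        profile = profile_from(list("ab"), [2.0, 1.0])
        with pytest.raises(ConfigurationError):
            gsea_enrichment_score(profile, GeneSet("s", frozenset("xy")))


class TestEnrichmentSignificance:
    def test_planted_silent_set_enriched(self, study):
        matrix, _, truth = study
        profile = basal_ranking(matrix)
        result = gsea_significance(profile, truth.silent_gene_set(), n_perm=1000, seed=0)
        assert result.es > 0
        assert result.p_value <= 0.01

    def test_add_one_lower_bound(self):
        rng = np.random.default_rng(1)
        ids = [f"g{i}" for i in range(60)]
        profile = profile_from(ids, np.sort(rng.normal(size=60))[::-1])
        members = frozenset(rng.choice(ids, size=10, replace=False))
        result = gsea_significance(profile, GeneSet("s", members), n_perm=100, seed=2)
        assert result.p_value >= 1.0 / 101.0

    def test_null_p_roughly_uniform(self):
        """Random sets give uniform permutation p-values across seeds."""
        from scipy import stats as sps

        rng = np.random.default_rng(6)
        ids = [f"g{i}" for i in range(80)]
        profile = profile_from(ids, np.sort(rng.normal(size=80))[::-1])
        pvals = []
        for seed in range(200):
            members = frozenset(rng.choice(ids, size=8, replace=False))
            r = gsea_significance(profile, GeneSet("s", members), n_perm=200, seed=seed)
            pvals.append(r.p_value)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestDisorderScore:
    @pytest.mark.parametrize(
        "intervals,expected",
        [([], 0), ([(1, 180)], 180), ([(10, 40), (30, 60)], 51), ([(5, 5)], 1)],
    )
    def test_examples(self, intervals, expected):
        assert disorder_score(intervals) == expected

    def test_inverted_interval_rejected(self):
        with pytest.raises(FormatError):
            disorder_score([(10, 5)])

    @given(
        st.lists(
            st.tuples(st.integers(1, 300), st.integers(0, 60)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            max_size=12,
        )
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_equals_residue_union_cardinality(self, intervals):
        residues = set()
        for start, end in intervals:
            residues |= set(range(start, end + 1))
        assert disorder_score(intervals) == len(residues)


class TestDosageClassifier:
    def fixture_scores_labels(self):
        scores = {"eA": 300, "eB": 250, "eC": 26, "sA": 90, "sB": 40}
        labels = {"eA": "effective", "eB": "effective", "eC": "effective",
                  "sA": "silent", "sB": "silent"}
        return scores, labels

    def test_low_disorder_effective_gene_is_the_exception(self):
        """An effective gene scoring 26 (< 180) is the lone misprediction."""
        scores, labels = self.fixture_scores_labels()
        predictions, exceptions = classify_dosage(scores, labels)
        assert exceptions == ["eC"]
        assert predictions["eC"] == "silent"  # low disorder predicts silent
        assert predictions["eA"] == "effective"

    def test_perfect_segregation_no_exceptions(self):
        scores = {"e1": 200, "e2": 400, "s1": 10, "s2": 179}
        labels = {"e1": "effective", "e2": "effective", "s1": "silent", "s2": "silent"}
        _, exceptions = classify_dosage(scores, labels)
        assert exceptions == []

    def test_threshold_one_predicts_everything_effective(self):
        scores, labels = self.fixture_scores_labels()
        predictions, exceptions = classify_dosage(
            scores, labels, DosageClassifier(threshold=1)
        )
        assert all(p == "effective" for p in predictions.values())
        assert set(exceptions) == {"sA", "sB"}

    def test_predictions_monotone_in_threshold(self):
        scores, labels = self.fixture_scores_labels()
        effective_sets = []
        for theta in (1, 50, 180, 260, 1000):
            predictions, _ = classify_dosage(
                scores, labels, DosageClassifier(threshold=theta)
            )
            effective_sets.append({g for g, p in predictions.items() if p == "effective"})
        for smaller, larger in zip(effective_sets[1:], effective_sets):
            assert smaller <= larger

    def test_excluded_genes_dropped(self):
        scores, labels = self.fixture_scores_labels()
        predictions, _ = classify_dosage(scores, labels, exclude=["eA", "sB"])
        assert set(predictions) == {"eB", "eC", "sA"}


class TestDisorderGroupTest:
    def test_identical_distributions_p_one(self):
        scores = {"a": 10, "b": 20, "c": 30, "d": 10, "e": 20, "f": 30}
        labels = {"a": "effective", "b": "effective", "c": "effective",
                  "d": "silent", "e": "silent", "f": "silent"}
        t, p = disorder_group_test(scores, labels)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_label_swap_flips_sign_keeps_p(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(10)]
        scores = {g: int(rng.integers(10, 400)) for g in genes}
        labels = {g: ("effective" if i < 4 else "silent") for i, g in enumerate(genes)}
        swapped = {g: ("silent" if l == "effective" else "effective") for g, l in labels.items()}
        t1, p1 = disorder_group_test(scores, labels)
        t2, p2 = disorder_group_test(scores, swapped)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_power_at_planted_separation(self):
        """Groups of 7 vs 13 drawn ~N(300,80) vs ~N(80,40) separate at
        p < 0.05 in at least 90% of seeds."""
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(3000 + seed)
            scores, labels = {}, {}
            for i in range(7):
                scores[f"e{i}"] = float(rng.normal(300, 80))
                labels[f"e{i}"] = "effective"
            for i in range(13):
                scores[f"s{i}"] = float(rng.normal(80, 40))
                labels[f"s{i}"] = "silent"
            _, p = disorder_group_test(scores, labels)
            hits += p < 0.05
        assert hits >= 0.90 * n_seeds

    def test_small_group_rejected(self):
        with pytest.raises(ConfigurationError):
            disorder_group_test({"a": 1, "b": 2}, {"a": "effective", "b": "silent"})
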