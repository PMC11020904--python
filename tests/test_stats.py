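"""Signed-rank tests, kappa and rating comparisons against brute force."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata
from scipy.stats import wilcoxon as scipy_wilcoxon
from sklearn.metrics import cohen_kappa_score

from hypersimp.stats import (
    DegenerateSampleError,
    PairedSample,
    align_pairs,
    cohens_kappa,
    kappa_band,
    kappa_from_table,
    load_ratings_csv,
    paired_deltas,
    rating_compare,
    significance_stars,
    wilcoxon_signed_rank,
)


def sample(diffs):
    diffs = list(diffs)
    return PairedSample(
        ids=tuple(range(len(diffs))),
        pre_values=(0.0,) * len(diffs),
        post_values=tuple(diffs),
    )


def brute_force_two_sided_p(diffs):
    """Exact p by literal enumeration of all 2^n sign assignments."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    ranks = rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    n = len(ranks)
    ws = [
        sum(r for r, keep in zip(ranks, signs) if keep)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestAlign:
    def test_intersection_and_drop_count(self):
        pre = {"a": 1.0, "b": 2.0, "c": 3.0}
        post = {"a": 1.5, "c": 2.5}
        (s,), dropped = align_pairs(pre, post)
        assert s.ids == ("a", "c")
        assert dropped == ["b"]

    def test_identical_id_sets_drop_nothing(self):
        pre = {"a": 1.0, "b": 2.0}
        (s,), dropped = align_pairs(pre, {"a": 0.0, "b": 0.0})
        assert dropped == []
        assert len(s.ids) == 2

    def test_undefined_values_are_dropped(self):
        pre = {"a": 1.0, "b": None, "c": 3.0}
        post = {"a": 1.0, "b": 2.0, "c": None}
        (s,), dropped = align_pairs(pre, post)
        assert s.ids == ("a",)
        assert sorted(dropped) == ["b", "c"]

    def test_empty_intersection_errors(self):
        with pytest.raises(ValueError, match="empty"):
            align_pairs({"a": 1.0}, {"b": 2.0})

    def test_multiple_post_corpora_share_one_id_set(self):
        pre = {"a": 1.0, "b": 2.0, "c": 3.0}
        p1 = {"a": 1.0, "b": 2.0}
        p2 = {"b": 5.0, "c": 6.0}
        (s1, s2), dropped = align_pairs(pre, p1, p2)
        assert s1.ids == s2.ids == ("b",)
        assert sorted(dropped) == ["a", "c"]


class TestWilcoxon:
    def test_all_positive_n5(self):
        r = wilcoxon_signed_rank(sample([1, 2, 3, 4, 5]))
        assert r.statistic == 15.0
        assert r.p_value == pytest.approx(0.0625)
        assert r.method == "exact"

    def test_all_positive_n6(self):
        r = wilcoxon_signed_rank(sample([1, 2, 3, 4, 5, 6]))
        assert r.statistic == 21.0
        assert r.p_value == pytest.approx(0.03125)

    def test_zeros_discarded(self):
        r = wilcoxon_signed_rank(sample([0, 0, 1, 2, 3, 4, 5]))
        assert r.n_used == 5
        assert r.p_value == pytest.approx(0.0625)

    def test_all_zero_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            wilcoxon_signed_rank(sample([0.0, 0.0, 0.0]))

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            d = rng.normal(0.4, 1.0, size=int(rng.integers(4, 15)))
            d = d[d != 0]
            fwd = wilcoxon_signed_rank(sample(d))
            rev = wilcoxon_signed_rank(sample(-d))
            n = fwd.n_used
            assert rev.statistic == pytest.approx(n * (n + 1) / 2 - fwd.statistic)
            assert rev.p_value == pytest.approx(fwd.p_value)

    def test_exact_p_equals_full_enumeration(self):
        """Oracle equivalence for n <= 12, including ties and zeros."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(2, 13))
            # half-integer grid induces frequent tied |differences|
            d = np.round(rng.normal(0.3, 1.0, size=n) * 2) / 2
            if np.all(d == 0):
                continue
            mine = wilcoxon_signed_rank(sample(d))
            assert mine.method == "exact"
            assert mine.p_value == pytest.approx(brute_force_two_sided_p(d), abs=1e-12)

    def test_matches_scipy_exact_mode(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            d = rng.normal(0.5, 1.0, size=int(rng.integers(6, 20)))
            mine = wilcoxon_signed_rank(sample(d))
            ref = scipy_wilcoxon(d, alternative="two-sided", method="exact")
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approx_close_to_exact_at_boundary(self, monkeypatch):
        """Continuity check at n = 25: the approximation the larger
        samples use stays within 0.01 of the exact value on the same data."""
        import hypersimp.stats as stats_mod

        rng = np.random.default_rng(31)
        for _ in range(10):
            d = rng.normal(0.2, 1.0, size=25)
            exact = wilcoxon_signed_rank(sample(d))
            assert exact.method == "exact"
            with monkeypatch.context() as m:
                m.setattr(stats_mod, "EXACT_MAX_N", 0)
                approx = wilcoxon_signed_rank(sample(d))
            assert approx.method == "normal_approx"
            assert abs(approx.p_value - exact.p_value) < 0.01


class TestPairedDeltas:
    def test_constant_shift(self):
        s = {"FKS": PairedSample(("a", "b", "c"), (1.0, 2.0, 3.0), (3.0, 4.0, 5.0))}
        report = paired_deltas(s, seed=0).to_dataframe().iloc[0]
        assert report["mean_delta"] == pytest.approx(2.0)
        assert report["iqr_delta"] == pytest.approx(0.0)

    def test_undefined_entries_excluded_and_counted(self):
        s = {"MTLD": PairedSample(("a", "b", "c"), (1.0, None, 3.0), (2.0, 2.0, 5.0))}
        row = paired_deltas(s, seed=0).to_dataframe().iloc[0]
        assert row["n_pairs"] == 2
        assert row["n_excluded_undefined"] == 1

    def test_degenerate_deltas_flagged(self):
        s = {"FKS": PairedSample(("a", "b"), (1.0, 2.0), (1.0, 2.0))}
        row = paired_deltas(s, seed=0).to_dataframe().iloc[0]
        assert row["test_method"] == "degenerate"
        assert row["stars"] == ""

    def test_bootstrap_ci_is_seeded(self):
        s = {"FKS": PairedSample(tuple(range(10)), (0.0,) * 10, tuple(range(10)))}
        r1 = paired_deltas(s, seed=9).to_dataframe().iloc[0]
        r2 = paired_deltas(s, seed=9).to_dataframe().iloc[0]
        assert r1["ci_low"] == r2["ci_low"]
        assert r1["ci_low"] <= r1["mean_delta"] <= r1["ci_high"]

    def test_star_tiers(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.004) == "***"
        assert significance_stars(0.2) == ""


class TestKappa:
    def test_identical_vectors(self):
        assert cohens_kappa([1, 1, 2, 2], [1, 1, 2, 2]) == pytest.approx(1.0)

    def test_marginal_independence_case(self):
        assert cohens_kappa([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(0.0)

    def test_relabeling_invariance(self):
        r1 = [1, 2, 3, 1, 2, 3, 1, 1]
        r2 = [1, 2, 2, 1, 3, 3, 2, 1]
        relabel = {1: "x", 2: "y", 3: "z"}
        a = cohens_kappa(r1, r2)
        b = cohens_kappa([relabel[v] for v in r1], [relabel[v] for v in r2])
        assert a == pytest.approx(b)

    def test_table_equals_vectors(self):
        rng = np.random.default_rng(3)
        r1 = rng.integers(1, 4, size=40)
        r2 = rng.integers(1, 4, size=40)
        table = np.zeros((3, 3))
        for a, b in zip(r1, r2):
            table[a - 1, b - 1] += 1
        assert cohens_kappa(r1, r2) == pytest.approx(kappa_from_table(table))

    def test_matches_sklearn(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = int(rng.integers(5, 60))
            r1 = rng.integers(1, 6, size=n)
            r2 = np.where(rng.random(n) < 0.6, r1, rng.integers(1, 6, size=n))
            ours = cohens_kappa(r1, r2)
            ref = cohen_kappa_score(r1, r2)
            if np.isnan(ref):
                assert ours is None or ours == pytest.approx(1.0)
            else:
                assert ours == pytest.approx(ref, abs=1e-12)

    def test_both_raters_constant_identical_is_undefined(self):
        assert cohens_kappa([2, 2, 2], [2, 2, 2]) is None

    def test_band_labels(self):
        assert kappa_band(-0.1) == "poor"
        assert kappa_band(0.1) == "slight"
        assert kappa_band(0.3) == "fair"
        assert kappa_band(0.5) == "moderate"
        assert kappa_band(0.7) == "substantial"
        assert kappa_band(0.9) == "almost perfect"


def ratings_frame(systems_scores, metric="clarity", rater="r1"):
    rows = []
    for system, scores in systems_scores.items():
        for i, score in enumerate(scores):
            rows.append(
                {"id": f"t{i}", "rater": rater, "system": system,
                 "metric": metric, "score": score}
            )
    return pd.DataFrame(rows)


class TestRatingCompare:
    def test_identical_systems_flagged_degenerate(self):
        df = ratings_frame({"A": [3] * 10, "B": [3] * 10})
        row = rating_compare(df).iloc[0]
        assert row["test_method"] == "degenerate"

    def test_uniform_one_point_gap(self):
        df = ratings_frame({"A": [4] * 10, "B": [3] * 10})
        row = rating_compare(df).iloc[0]
        assert row["mean_a"] > row["mean_b"]
        # all 10 differences (B - A) negative: W = 0, exact two-sided p = 2/1024
        assert row["W"] == 0.0
        assert row["p_value"] == pytest.approx(2 / 1024)

    def test_three_systems_give_three_pairs_per_metric(self):
        df = pd.concat(
            [
                ratings_frame({"A": [1, 2, 3], "B": [2, 3, 4], "C": [3, 4, 5]},
                              metric=m)
                for m in ("clarity", "accuracy")
            ]
        )
        out = rating_compare(df)
        assert len(out) == 6
        assert set(out["metric"]) == {"clarity", "accuracy"}

    def test_load_ratings_validates(self, tmp_path):
        good = tmp_path / "r.csv"
        ratings_frame({"A": [1, 2]}).to_csv(good, index=False)
        assert len(load_ratings_csv(good)) == 2
        bad = tmp_path / "bad.csv"
        ratings_frame({"A": [1, 2]}).drop(columns=["metric"]).to_csv(bad, index=False)
        with pytest.raises(ValueError, match="metric"):
            load_ratings_csv(bad)
        out_of_scale = tmp_path / "scale.csv"
        ratings_frame({"A": [1, 9]}).to_csv(out_of_scale, index=False)
        with pytest.raises(ValueError, match="Likert"):
            load_ratings_csv(out_of_scale)
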