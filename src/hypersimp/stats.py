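"""Evaluation statistics: paired deltas, Wilcoxon signed-rank tests,
Cohen's kappa and Likert rating comparisons.

The signed-rank test is two-sided throughout. For n <= 25 nonzero
differences the p-value is exact, computed over the full null
distribution of all 2^n equiprobable sign assignments (a subset-sum
recursion over the tied ranks — identical to brute-force enumeration,
just not exponential); larger samples use the normal approximation with
continuity and tie corrections.

Zero differences are discarded before ranking (the classical treatment).
Undefined metric values are excluded from pairing with an exclusion
count, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "PairedSample",
    "TestResult",
    "BenchmarkReport",
    "DegenerateSampleError",
    "align_pairs",
    "wilcoxon_signed_rank",
    "paired_deltas",
    "cohens_kappa",
    "kappa_from_table",
    "kappa_band",
    "significance_stars",
    "rating_compare",
    "load_ratings_csv",
    "EXACT_MAX_N",
]

#: largest sample for which the signed-rank p-value is computed exactly.
EXACT_MAX_N = 25


class DegenerateSampleError(ValueError):
    """All paired differences are zero (or no pairs remain)."""


@dataclass(frozen=True)
class PairedSample:
    """Pre/post values paired by definition id; ``None`` marks an
    undefined metric value for that definition."""

    ids: tuple
    pre_values: tuple
    post_values: tuple

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.pre_values) == len(self.post_values)):
            raise ValueError("ids, pre_values and post_values must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ids must be unique")

    def defined(self) -> tuple[np.ndarray, np.ndarray, int]:
        """(pre, post) arrays over pairs where both sides are defined,
        plus the count of excluded pairs."""
        keep = [
            i
            for i in range(len(self.ids))
            if self.pre_values[i] is not None and self.post_values[i] is not None
        ]
        pre = np.array([self.pre_values[i] for i in keep], dtype=float)
        post = np.array([self.post_values[i] for i in keep], dtype=float)
        return pre, post, len(self.ids) - len(keep)


@dataclass(frozen=True)
class TestResult:
    statistic: float  # W = sum of positive ranks
    p_value: float
    n_used: int  # nonzero differences actually ranked
    method: str  # "exact" or "normal_approx"


def align_pairs(
    pre: Mapping, *post_corpora: Mapping
) -> tuple[list[PairedSample], list]:
    """Pair values by id across a pre corpus and one or more post corpora.

    Only ids present *and defined* (non-None) in every corpus survive;
    dropped ids are returned for logging. Raises ``ValueError`` when the
    surviving intersection is empty.
    """
    if not post_corpora:
        raise ValueError("align_pairs needs at least one post corpus")
    all_corpora = (pre, *post_corpora)
    kept = [
        k
        for k in pre
        if all(k in c and c[k] is not None for c in all_corpora)
    ]
    dropped = [k for k in pre if k not in kept]
    if not kept:
        raise ValueError("empty id intersection across corpora")
    samples = [
        PairedSample(
            ids=tuple(kept),
            pre_values=tuple(pre[k] for k in kept),
            post_values=tuple(post[k] for k in kept),
        )
        for post in post_corpora
    ]
    return samples, dropped


def _exact_two_sided_p(ranks: np.ndarray, w: float) -> float:
    """P-value over the full null distribution of sign assignments.

    Ranks (possibly half-integer from ties) are doubled to integers and a
    subset-sum recursion counts, for every achievable W, the number of
    sign patterns producing it — an exact tabulation of all 2^n patterns.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    ways = np.zeros(total + 1, dtype=object)
    ways[0] = 1
    for r in doubled:
        ways[r:] = ways[r:] + ways[:-r] if r > 0 else ways[r:]
    w2 = int(round(2 * w))
    denom = 1 << len(ranks)
    p_le = int(sum(ways[: w2 + 1])) / denom
    p_ge = int(sum(ways[w2:])) / denom
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(s: PairedSample) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on post - pre differences.

    Zeros are discarded; |differences| are ranked with average ranks for
    ties; W is the positive-rank sum. Raises
    :class:`DegenerateSampleError` when no nonzero difference remains.
    """
    pre, post, _ = s.defined()
    diffs = post - pre
    diffs = diffs[diffs != 0]
    n = len(diffs)
    if n == 0:
        raise DegenerateSampleError("all paired differences are zero")
    ranks = rankdata(np.abs(diffs))
    w = float(ranks[diffs > 0].sum())
    if n <= EXACT_MAX_N:
        return TestResult(w, _exact_two_sided_p(ranks, w), n, "exact")
    mu = n * (n + 1) / 4.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    sigma2 -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    z = (abs(w - mu) - 0.5) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return TestResult(w, p, n, "normal_approx")


def significance_stars(p: float) -> str:
    """Star tiers: * p<0.05, ** p<0.01, *** p<0.005."""
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class BenchmarkReport:
    """Per-metric pre/post comparison: mean delta, IQR, bootstrap CI of
    the mean delta, signed-rank test and star tier."""

    rows: tuple[dict, ...]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.rows))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.to_dataframe().to_json(path, orient="records", indent=2)


def paired_deltas(
    samples: Mapping[str, PairedSample],
    seed: int | None = None,
    n_bootstrap: int = 10_000,
) -> BenchmarkReport:
    """Summarize post - pre deltas per metric.

    The CI of the mean delta is a seeded nonparametric bootstrap
    (percentile, ``n_bootstrap`` resamples). Degenerate samples (all
    deltas zero) are reported with a note instead of a test result.
    """
    if not samples:
        raise ValueError("paired_deltas needs at least one metric")
    rng = np.random.default_rng(seed)
    rows = []
    for metric, sample in samples.items():
        pre, post, n_excluded = sample.defined()
        deltas = post - pre
        row: dict = {
            "metric": metric,
            "n_pairs": len(deltas),
            "n_excluded_undefined": n_excluded,
        }
        if len(deltas) == 0:
            row.update(
                mean_delta=None, iqr_delta=None, ci_low=None, ci_high=None,
                W=None, p_value=None, stars="", test_method="no_defined_pairs",
            )
            rows.append(row)
            continue
        q25, q75 = np.percentile(deltas, [25, 75])
        boots = rng.choice(deltas, size=(n_bootstrap, len(deltas)), replace=True)
        ci_low, ci_high = np.percentile(boots.mean(axis=1), [2.5, 97.5])
        row.update(
            mean_delta=float(deltas.mean()),
            iqr_delta=float(q75 - q25),
            ci_low=float(ci_low),
            ci_high=float(ci_high),
        )
        try:
            test = wilcoxon_signed_rank(sample)
            row.update(
                W=test.statistic,
                p_value=test.p_value,
                stars=significance_stars(test.p_value),
                test_method=test.method,
            )
        except DegenerateSampleError:
            row.update(W=None, p_value=None, stars="", test_method="degenerate")
        rows.append(row)
    return BenchmarkReport(rows=tuple(rows))


# --------------------------------------------------------------------------
# Cohen's kappa
# --------------------------------------------------------------------------


def kappa_from_table(table: np.ndarray) -> float | None:
    """Unweighted Cohen's kappa from a square contingency table."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n == 0:
        raise ValueError("empty contingency table")
    p_o = np.trace(table) / n
    p_e = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if p_e == 1.0:
        return None
    return (p_o - p_e) / (1.0 - p_e)


def cohens_kappa(r1: Sequence, r2: Sequence) -> float | None:
    """Unweighted Cohen's kappa between two raters' categorical vectors.

    Returns ``None`` (undefined) when chance agreement is 1 — both raters
    constant and identical. Invariant under any consistent relabeling of
    categories.
    """
    if len(r1) != len(r2):
        raise ValueError("rating vectors must have equal length")
    if len(r1) == 0:
        raise ValueError("rating vectors must be non-empty")
    cats = sorted(set(r1) | set(r2), key=repr)
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)))
    for a, b in zip(r1, r2):
        table[idx[a], idx[b]] += 1
    return kappa_from_table(table)


_KAPPA_BANDS = (
    (0.00, "slight"),
    (0.21, "fair"),
    (0.41, "moderate"),
    (0.61, "substantial"),
    (0.81, "almost perfect"),
)


def kappa_band(kappa: float) -> str:
    """Conventional strength-of-agreement band for a kappa value
    (<0 poor, 0-0.20 slight, 0.21-0.40 fair, 0.41-0.60 moderate,
    0.61-0.80 substantial, >0.80 almost perfect)."""
    if kappa < 0:
        return "poor"
    label = _KAPPA_BANDS[0][1]
    for lo, name in _KAPPA_BANDS:
        if kappa >= lo:
            label = name
    return label


# --------------------------------------------------------------------------
# Likert rating comparisons
# --------------------------------------------------------------------------


def load_ratings_csv(path) -> pd.DataFrame:
    """Load a ratings table with columns id, rater, system, metric, score."""
    df = pd.read_csv(path)
    required = {"id", "rater", "system", "metric", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ratings CSV missing columns: {sorted(missing)}")
    bad = df[~df["score"].isin([1, 2, 3, 4, 5])]
    if not bad.empty:
        raise ValueError("ratings must be Likert scores in 1..5")
    return df


def rating_compare(ratings: pd.DataFrame) -> pd.DataFrame:
    """Pairwise system comparison per metric on rater-averaged Likert
    scores paired by text id.

    Returns one row per (metric, system pair) with the signed-rank W and
    p (or a degenerate flag when the two systems' ratings coincide), plus
    each system's mean rating for ranking.
    """
    agg = (
        ratings.groupby(["metric", "system", "id"])["score"].mean().reset_index()
    )
    rows = []
    for metric, chunk in agg.groupby("metric"):
        systems = sorted(chunk["system"].unique())
        by_system = {
            sys_name: dict(zip(g["id"], g["score"]))
            for sys_name, g in chunk.groupby("system")
        }
        for i, sys_a in enumerate(systems):
            for sys_b in systems[i + 1 :]:
                (sample,), dropped = align_pairs(by_system[sys_a], by_system[sys_b])
                row = {
                    "metric": metric,
                    "system_a": sys_a,
                    "system_b": sys_b,
                    "n_pairs": len(sample.ids),
                    "n_dropped": len(dropped),
                    "mean_a": float(np.mean(sample.pre_values)),
                    "mean_b": float(np.mean(sample.post_values)),
                }
                try:
                    test = wilcoxon_signed_rank(sample)
                    row.update(
                        W=test.statistic,
                        p_value=test.p_value,
                        stars=significance_stars(test.p_value),
                        test_method=test.method,
                    )
                except DegenerateSampleError:
                    row.update(W=None, p_value=None, stars="", test_method="degenerate")
                rows.append(row)
    return pd.DataFrame(rows)
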