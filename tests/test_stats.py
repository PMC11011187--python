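"""ANOVA decomposition and Duncan's multiple range test."""

import numpy as np
import pytest
from scipy import stats as sps

from feedeval.stats import (
    anova_oneway,
    assign_letters,
    compare_treatments,
    duncan_mrt,
)
from feedeval.trial import FeedEvalError


def duncan_oracle_letters(groups, alpha=0.05):
    """Exhaustive-span reference implementation, straight from the
    definition: raw significance of every span from its least significant
    range, containment closure, maximal spans, letters left to right."""
    arrays = [np.asarray(g, float) for g in groups]
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / (n_total - k)
    df = n_total - k
    harmonic_n = k / sum(1.0 / len(a) for a in arrays)
    means = np.array([a.mean() for a in arrays])
    order = list(np.argsort(-means, kind="stable"))
    sorted_means = means[order]

    def lsr(width):
        protection = 1.0 - (1.0 - alpha) ** (width - 1)
        q = sps.studentized_range.ppf(1.0 - protection, width, df)
        return q * np.sqrt(mse / harmonic_n)

    raw_nonsig = set()
    for i in range(k):
        for j in range(i + 1, k):
            if sorted_means[i] - sorted_means[j] <= lsr(j - i + 1):
                raw_nonsig.add((i, j))
    effective = set()
    for width in range(k, 1, -1):
        for i in range(k - width + 1):
            j = i + width - 1
            contained = any(a <= i and j <= b for a, b in effective)
            if contained or (i, j) in raw_nonsig:
                effective.add((i, j))
    sorted_letters = assign_letters(k, effective)
    letters = [""] * k
    for rank, group in enumerate(order):
        letters[group] = sorted_letters[rank]
    return letters


class TestAnova:
    def test_identical_groups_report_no_difference(self):
        result = anova_oneway([[1, 2, 3], [1, 2, 3]])
        assert result.f_statistic == 0.0 and result.p_value == 1.0

    def test_constant_equal_groups_are_degenerate_no_difference(self):
        result = anova_oneway([[5, 5, 5], [5, 5, 5]])
        assert result.p_value == 1.0

    def test_separated_groups(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1e-3, 5)
        b = 10 + rng.normal(0, 1e-3, 5)
        assert anova_oneway([a, b]).p_value < 1e-6

    def test_matches_definitional_sums_of_squares(self, rng):
        groups = [rng.normal(rng.uniform(0, 5), 1.0, size=9)
                  for _ in range(4)]
        result = anova_oneway(groups)
        flat = np.concatenate(groups)
        grand = flat.mean()
        ss_b = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ss_w = sum(sum((x - np.mean(g)) ** 2 for x in g) for g in groups)
        f = (ss_b / 3) / (ss_w / (len(flat) - 4))
        assert result.f_statistic == pytest.approx(f, rel=1e-12)
        assert result.mse == pytest.approx(ss_w / (len(flat) - 4), rel=1e-12)

    def test_agrees_with_scipy_f_oneway(self, rng):
        groups = [rng.normal(i, 2.0, size=7) for i in range(3)]
        ours = anova_oneway(groups)
        ref = sps.f_oneway(*groups)
        assert ours.f_statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_requires_two_groups_of_two(self):
        with pytest.raises(FeedEvalError):
            anova_oneway([[1.0, 2.0]])
        with pytest.raises(FeedEvalError):
            anova_oneway([[1.0, 2.0], [3.0]])


class TestDuncan:
    def test_identical_groups_share_a(self):
        groups = [[5.0, 5.1, 4.9]] * 4
        result = duncan_mrt(groups)
        assert result.letters == ["a", "a", "a", "a"]

    def test_fully_resolved_ordering(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(mean, 0.1, 9) for mean in (10, 20, 30, 40)]
        result = duncan_mrt(groups)
        assert result.letters == ["d", "c", "b", "a"]

    def test_single_group_gets_a(self):
        assert duncan_mrt([[1.0, 2.0, 3.0]]).letters == ["a"]

    def test_permutation_equivariance(self, rng):
        groups = [rng.normal(m, 1.5, 8) for m in (3, 3.5, 7, 7.3)]
        base = duncan_mrt(groups).letters
        perm = [2, 0, 3, 1]
        permuted = duncan_mrt([groups[i] for i in perm]).letters
        assert permuted == [base[i] for i in perm]

    def test_matches_exhaustive_span_oracle(self, rng):
        """Letter partitions equal the brute-force definition on random
        2-6 group instances, including unequal sizes and near ties."""
        for _ in range(150):
            k = int(rng.integers(2, 7))
            spread = rng.uniform(0.2, 4.0)
            groups = [rng.normal(rng.uniform(0, spread), 1.0,
                                 size=int(rng.integers(3, 10)))
                      for _ in range(k)]
            assert duncan_mrt(groups).letters == duncan_oracle_letters(groups)

    def test_smaller_alpha_never_splits_finer(self, rng):
        """Any two groups sharing a letter at alpha 0.05 still share one at
        alpha 0.01 (larger least significant ranges only merge further)."""
        for _ in range(50):
            k = int(rng.integers(3, 6))
            groups = [rng.normal(rng.uniform(0, 3), 1.0, size=6)
                      for _ in range(k)]
            fine = duncan_mrt(groups, alpha=0.05).letters
            coarse = duncan_mrt(groups, alpha=0.01).letters
            for i in range(k):
                for j in range(i + 1, k):
                    if set(fine[i]) & set(fine[j]):
                        assert set(coarse[i]) & set(coarse[j])

    def test_never_more_conservative_than_newman_keuls(self):
        """Duncan's protected quantile is below the Newman-Keuls quantile
        for spans > 2 (protection level 1-(1-a)^(p-1) exceeds a)."""
        for df in (8, 16, 32):
            for span in (2, 3, 4, 5, 6):
                duncan_q = sps.studentized_range.ppf(
                    (1 - 0.05) ** (span - 1), span, df)
                nk_q = sps.studentized_range.ppf(0.95, span, df)
                if span == 2:
                    assert duncan_q == pytest.approx(nk_q)
                else:
                    assert duncan_q < nk_q

    def test_protected_mode_gates_on_f(self, rng):
        groups = [rng.normal(0, 5.0, 4) for _ in range(3)]
        anova = anova_oneway(groups)
        if anova.p_value >= 0.05:
            protected = duncan_mrt(groups, protected=True, anova=anova)
            assert set(protected.letters) == {"a"}


class TestCompareTreatments:
    def test_identical_treatments_share_letter(self):
        values = [[10.0, 11.0, 9.5], [10.0, 11.0, 9.5]]
        comparison = compare_treatments(values, ["A", "B"])
        assert comparison.letters_by_label["A"] == \
            comparison.letters_by_label["B"]

    def test_label_mismatch_is_an_error(self):
        with pytest.raises(FeedEvalError):
            compare_treatments([[1.0, 2.0]], ["A", "B"])

    def test_formatted_cell_carries_letters(self):
        comparison = compare_treatments(
            [[10.0, 10.5, 9.5], [30.0, 29.5, 30.5]], ["low", "high"])
        high = next(g for g in comparison.groups if g.label == "high")
        assert "±" in high.formatted() and high.letters == "a"
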