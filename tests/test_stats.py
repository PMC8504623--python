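"""Best-hit order statistic, truncated product, empirical P and FDR."""

import math
from types import SimpleNamespace

import numpy as np
import pytest

from spacerlink.stats import (
    PairMatch,
    best_hit_pvalue,
    combine_truncated_product,
    empirical_pvalue,
    estimate_fdr,
    min_order_pvalue,
)


def _hit(p, spacer="s"):
    return SimpleNamespace(p_hit=p, query_fragment=SimpleNamespace(parent_accession=spacer))


class TestBestHitPvalue:
    def test_single_fragment_is_identity(self):
        assert min_order_pvalue(0.5, 1) == 0.5

    def test_closed_form_value(self):
        assert min_order_pvalue(0.01, 100) == pytest.approx(1 - 0.99**100, rel=1e-12)

    def test_zero_pvalue_stays_zero(self):
        assert min_order_pvalue(0.0, 7) == 0.0

    def test_monotone_in_n_and_p(self):
        assert min_order_pvalue(0.01, 10) < min_order_pvalue(0.01, 100)
        assert min_order_pvalue(0.001, 50) < min_order_pvalue(0.01, 50)

    def test_matches_simulated_minima(self):
        rng = np.random.default_rng(42)
        n = 10
        x = 0.05
        minima = rng.uniform(size=(10_000, n)).min(axis=1)
        emp = float((minima <= x).mean())
        model = min_order_pvalue(x, n)
        se = math.sqrt(emp * (1 - emp) / minima.shape[0])
        assert abs(emp - model) <= 3 * se

    def test_selects_best_hit_and_requires_fragments(self):
        hits = [_hit(0.2, "a"), _hit(0.01, "b"), _hit(0.5, "c")]
        bh = best_hit_pvalue(hits, 1, "T")
        assert bh.spacer_accession == "b" and bh.p_bh == 0.01
        with pytest.raises(ValueError):
            best_hit_pvalue(hits, 0, "T")
        with pytest.raises(ValueError):
            best_hit_pvalue([], 5, "T")


class TestTruncatedProduct:
    def test_single_pvalue_reduces_to_itself(self):
        assert combine_truncated_product([0.05], tau=0.1) == pytest.approx(0.05)

    def test_two_significant_pvalues(self):
        s = combine_truncated_product([0.01, 0.02], tau=0.1)
        assert s == pytest.approx(0.002, rel=1e-9)

    def test_fallback_to_minimum_when_none_below_tau(self):
        assert combine_truncated_product([0.5, 0.9], tau=0.1) == pytest.approx(0.5)

    def test_errors(self):
        with pytest.raises(ValueError):
            combine_truncated_product([])
        with pytest.raises(ValueError):
            combine_truncated_product([0.5], tau=0.0)

    def test_appending_significant_pvalue_never_increases(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            ps = list(rng.uniform(0, 1, size=rng.integers(1, 6)))
            base = combine_truncated_product(ps)
            extra = float(rng.uniform(0, 0.1))
            assert combine_truncated_product(ps + [extra]) <= base + 1e-15

    def test_permutation_invariant(self):
        rng = np.random.default_rng(2)
        ps = list(rng.uniform(0, 0.3, size=6))
        shuffled = list(ps)
        rng.shuffle(shuffled)
        assert combine_truncated_product(ps) == pytest.approx(
            combine_truncated_product(shuffled), rel=1e-12
        )

    def test_dominated_by_min_when_two_below_tau(self):
        ps = [0.05, 0.01, 0.7]
        s = combine_truncated_product(ps, tau=0.1)
        assert s <= min(0.1, min(ps))


class TestEmpiricalPvalue:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.nulls = sorted(rng.uniform(size=999))

    def test_below_all_nulls(self):
        assert empirical_pvalue(-1.0, self.nulls, 999) == pytest.approx(1 / 1000)

    def test_above_all_nulls(self):
        assert empirical_pvalue(2.0, self.nulls, 999) == 1.0

    def test_median_is_about_half(self):
        med = self.nulls[499]
        assert empirical_pvalue(med, self.nulls, 999) == pytest.approx(0.5, abs=0.01)

    def test_nondecreasing_and_bounded(self):
        ps = [empirical_pvalue(s, self.nulls, 999) for s in np.linspace(0, 1, 50)]
        assert all(a <= b for a, b in zip(ps, ps[1:]))
        assert all(0 < p <= 1 for p in ps)

    def test_no_null_comparisons_is_error(self):
        with pytest.raises(ValueError, match="null"):
            empirical_pvalue(0.5, [], 0)


def _match(q, t, s):
    return PairMatch(query_set_id=q, target_set_id=t, best_hits=[None], s_comb=s)


class TestEstimateFdr:
    def test_no_null_below_any_real_score_retains_all(self):
        ms = [_match("a", "x", 1e-8), _match("b", "y", 1e-6)]
        out = estimate_fdr(ms, [1e-3, 1e-2], size_ratio=1.0)
        assert [m.fdr for m in out] == [0.0, 0.0]
        assert all(m.retained for m in out)

    def test_direct_counting_example(self):
        ms = [_match("a", "x", 1e-9), _match("b", "y", 1e-3)]
        out = estimate_fdr(ms, [1e-4], size_ratio=1.0)
        assert out[0].fdr == 0.0 and out[0].retained
        assert out[1].fdr == pytest.approx(0.5) and not out[1].retained

    def test_monotonization_is_cumulative_minimum(self):
        # raw FDRs would be [0/1, 2/2, 2/3] = [0, 1, 2/3] -> monotone [0, 2/3, 2/3]
        ms = [_match("a", "x", 1e-9), _match("b", "y", 5e-3), _match("c", "z", 2e-2)]
        out = estimate_fdr(ms, [1e-3, 2e-3], size_ratio=1.0)
        assert [m.fdr for m in out] == pytest.approx([0.0, 2 / 3, 2 / 3])

    def test_size_ratio_rescales_null_counts(self):
        ms = [_match("a", "x", 1e-3)]
        out = estimate_fdr(ms, [1e-4, 1e-4], size_ratio=0.5)
        assert out[0].fdr == pytest.approx(1.0)  # 0.5 * 2 / 1
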