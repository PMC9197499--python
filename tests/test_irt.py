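"""Response functions, information, SE and reliability of the IRT core."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from catlab.irt import (
    CategoryIndexError,
    InvalidItemError,
    ItemBank,
    ItemParams,
    Model,
    category_probs,
    gpcm_category_probs,
    grm_category_probs,
    grm_cumulative,
    item_information,
    marginal_reliability,
    response_loglik,
    standard_error,
)
from catlab import irt

total_information = irt.test_information

# high-precision logistic evaluations frozen from a symbolic oracle
SAS_C3_CUM_AT_0 = [0.934616111858, 0.559876289476, 0.171504769975, 0.010576164001]
SAS_C3_CATS = {
    -2.0: [0.465091884071, 0.442059587480, 0.076465651213, 0.015523566260, 0.000859310976],
    0.0: [0.065383888142, 0.374739822382, 0.388371519501, 0.160928605975, 0.010576164001],
    2.0: [0.005597288405, 0.053890140709, 0.220404044086, 0.602836414027, 0.117272112773],
}
GPCM_ORACLE = [0.024961927696, 0.236832175946, 0.501373720412, 0.236832175946]


def random_item(rng, model=Model.GRM, m=None):
    m = m or rng.integers(2, 8)
    thr = np.sort(rng.uniform(-3, 3, size=m - 1))
    return ItemParams(f"r{rng.integers(1e9)}", "S", model, int(m), rng.uniform(0.5, 2.5),
                      tuple(thr))


class TestGRM:
    def test_cumulative_half_at_threshold(self, sas_c3):
        for t in range(1, 5):
            item = ItemParams("x", "S", Model.GRM, 5, 2.3, sas_c3.thresholds)
            assert grm_cumulative(item.thresholds[t - 1], item, t) == pytest.approx(0.5)

    def test_cumulative_closed_form(self):
        item = ItemParams("x", "S", Model.GRM, 2, 2.0, (0.0,))
        assert grm_cumulative(1.0, item, 1) == pytest.approx(1 / (1 + np.exp(-2)), abs=1e-4)

    def test_cumulative_matches_precision_oracle(self, sas_c3):
        got = [grm_cumulative(0.0, sas_c3, t) for t in range(1, 5)]
        np.testing.assert_allclose(got, SAS_C3_CUM_AT_0, atol=1e-10)

    def test_category_index_out_of_range(self, sas_c3):
        with pytest.raises(CategoryIndexError):
            grm_cumulative(0.0, sas_c3, 5)
        with pytest.raises(CategoryIndexError):
            grm_cumulative(0.0, sas_c3, 0)

    @pytest.mark.parametrize("theta", [-2.0, 0.0, 2.0])
    def test_category_probs_match_oracle(self, sas_c3, theta):
        np.testing.assert_allclose(
            grm_category_probs(theta, sas_c3), SAS_C3_CATS[theta], atol=1e-10
        )

    def test_dichotomous_symmetry(self, dichotomous_grm):
        np.testing.assert_allclose(grm_category_probs(0.0, dichotomous_grm), [0.5, 0.5])

    def test_nonmonotone_thresholds_rejected(self):
        with pytest.raises(InvalidItemError):
            ItemParams("bad", "S", Model.GRM, 4, 1.0, (1.0, 0.0, 2.0))


class TestGPCM:
    def test_matches_term_by_term_oracle(self, gpcm_item):
        np.testing.assert_allclose(
            gpcm_category_probs(0.5, gpcm_item), GPCM_ORACLE, atol=1e-10
        )

    def test_dichotomous_equivalence_with_grm(self):
        """With m=2 and D=1 the partial-credit and graded models coincide."""
        for b in (-1.3, 0.0, 0.8):
            grm = ItemParams("a", "S", Model.GRM, 2, 1.4, (b,))
            gpc = ItemParams("b", "S", Model.GPCM, 2, 1.4, (b,))
            for theta in np.linspace(-3, 3, 13):
                np.testing.assert_allclose(
                    grm_category_probs(theta, grm),
                    gpcm_category_probs(theta, gpc),
                    atol=1e-14,
                )

    def test_overflow_safety(self):
        item = ItemParams("g", "S", Model.GPCM, 3, 100.0, (-5.0, 5.0))
        p = gpcm_category_probs(7.0, item)
        assert np.all(np.isfinite(p)) and p.sum() == pytest.approx(1.0)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    theta=st.floats(-4, 4),
    model=st.sampled_from([Model.GRM, Model.GPCM]),
)
def test_probability_normalization_property(seed, theta, model):
    """Category probabilities are nonnegative and sum to 1 within 1e-12."""
    rng = np.random.default_rng(seed)
    item = random_item(rng, model=model)
    p = category_probs(theta, item)
    assert np.all(p >= 0)
    assert abs(p.sum() - 1.0) < 1e-12


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_grm_cumulative_monotone_property(seed):
    """P(X>=t) strictly decreases in t and strictly increases in theta."""
    rng = np.random.default_rng(seed)
    m = int(rng.integers(3, 8))
    thr = np.sort(rng.uniform(-3, 3, size=m - 1))
    thr += np.arange(m - 1) * 1e-3  # force strict ordering
    item = ItemParams("p", "S", Model.GRM, m, float(rng.uniform(0.5, 2.5)), tuple(thr))
    thetas = [-1.5, 0.0, 1.5]
    cums = np.array([[grm_cumulative(th, item, t) for t in range(1, m)] for th in thetas])
    assert np.all(np.diff(cums, axis=1) < 0)  # decreasing in t
    assert np.all(np.diff(cums, axis=0) > 0)  # increasing in theta


class TestInformation:
    def test_dichotomous_closed_form(self, dichotomous_grm):
        # a^2 P (1-P) = 0.25 at theta = b with a = 1
        assert item_information(0.0, dichotomous_grm) == pytest.approx(0.25)

    @pytest.mark.parametrize("model", [Model.GRM, Model.GPCM])
    def test_matches_finite_difference_oracle(self, sas_c3, gpcm_item, model):
        """Closed-form Fisher information vs central-difference derivative."""
        item = sas_c3 if model is Model.GRM else gpcm_item
        h = 1e-5
        for theta in np.arange(-3.0, 3.1, 1.0):
            p0 = category_probs(theta, item)
            dp = (category_probs(theta + h, item) - category_probs(theta - h, item)) / (2 * h)
            oracle = float(np.sum(dp**2 / p0))
            assert item_information(theta, item) == pytest.approx(oracle, abs=1e-6)

    def test_nonnegative_everywhere(self, sas_c3, gpcm_item):
        grid = np.linspace(-6, 6, 41)
        assert np.all(item_information(grid, sas_c3) >= 0)
        assert np.all(item_information(grid, gpcm_item) >= 0)


class TestTestInformationAndSE:
    def test_additivity(self, sas_c3):
        single = item_information(0.3, sas_c3)
        assert total_information(0.3, [sas_c3]) == pytest.approx(single)
        two = ItemParams("c2", "S", Model.GRM, 5, sas_c3.a, sas_c3.thresholds)
        assert total_information(0.3, [sas_c3, two]) == pytest.approx(2 * single)

    def test_brute_force_sum_over_bank(self, bank89):
        loop = sum(item_information(0.0, it) for it in bank89)
        assert total_information(0.0, bank89.items) == pytest.approx(loop, rel=1e-12)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            total_information(0.0, [])

    def test_se_reciprocal_sqrt(self, sas_c3):
        info = total_information(0.0, [sas_c3])
        assert standard_error(0.0, [sas_c3]) == pytest.approx(1 / np.sqrt(info))

    def test_se_from_total_information_4(self):
        """Total information 4 gives SE 0.5; 6.574 gives about 0.39."""
        items = [
            ItemParams(f"i{k}", "S", Model.GRM, 2, 2.0, (0.0,)) for k in range(4)
        ]
        # each dichotomous item at theta=0: a^2/4 = 1, so total = 4
        assert standard_error(0.0, items) == pytest.approx(0.5)
        assert 1 / np.sqrt(6.574) == pytest.approx(0.39, abs=0.0005)

    def test_adding_items_never_increases_se(self, bank89):
        prev = np.inf
        for k in range(1, 12):
            se = standard_error(0.5, bank89.items[:k])
            assert se <= prev
            prev = se


class TestMarginalReliability:
    @pytest.mark.parametrize(
        "se,expected", [(0.30, 0.91), (0.48, 0.77), (0.0, 1.0)]
    )
    def test_constant_se_values(self, se, expected):
        assert marginal_reliability([se] * 885) == pytest.approx(expected, abs=0.005)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            marginal_reliability([])


class TestResponseLoglik:
    def test_single_dichotomous(self, dichotomous_grm):
        assert response_loglik([1], 0.0, [dichotomous_grm]) == pytest.approx(np.log(0.5))

    def test_duplication_additivity(self, sas_c3):
        twin = ItemParams("twin", "S", Model.GRM, 5, sas_c3.a, sas_c3.thresholds)
        one = response_loglik([2], 0.4, [sas_c3])
        both = response_loglik([2, 2], 0.4, [sas_c3, twin])
        assert both == pytest.approx(2 * one, abs=1e-12)

    def test_term_by_term_oracle(self, bank89):
        items = bank89.items[:5]
        pattern = [1, 0, 2, 3, 1]
        oracle = sum(
            np.log(category_probs(0.7, it)[x]) for it, x in zip(items, pattern)
        )
        assert response_loglik(pattern, 0.7, items) == pytest.approx(oracle, abs=1e-12)

    def test_missing_skipped_and_all_missing_warns(self, sas_c3):
        with pytest.warns(UserWarning):
            assert response_loglik([np.nan], 0.0, [sas_c3]) == 0.0
        partial = response_loglik([np.nan, 2], 0.0, [sas_c3, sas_c3_copy(sas_c3)])
        assert partial == pytest.approx(np.log(category_probs(0.0, sas_c3)[2]))


def sas_c3_copy(item):
    return ItemParams("copy", "S", Model.GRM, item.m, item.a, item.thresholds)


class TestContainers:
    def test_duplicate_ids_rejected(self, sas_c3):
        with pytest.raises(ValueError):
            ItemBank([sas_c3, sas_c3])

    def test_threshold_count_enforced(self):
        with pytest.raises(InvalidItemError):
            ItemParams("x", "S", Model.GRM, 5, 1.0, (0.0, 1.0))

    def test_nonpositive_discrimination_rejected(self):
        with pytest.raises(InvalidItemError):
            ItemParams("x", "S", Model.GRM, 2, 0.0, (0.0,))
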