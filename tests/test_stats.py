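import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as lifelines_logrank

from neoforge.errors import DegenerateInputError, ValidationError
from neoforge.stats import (CD8_EFFECTOR_SIGNATURE, CDC1_SIGNATURE, Signature,
                            TumorMeasurement, km_curve, logrank_test,
                            median_split, pearson_r, quartile_groups,
                            signature_score, tumor_volume)

# ---------------------------------------------------------------------------
# signature score
# ---------------------------------------------------------------------------


def test_signature_score_zero_for_zero_zscores():
    df = pd.DataFrame(0.0, index=["s1", "s2"], columns=list(CDC1_SIGNATURE.genes))
    assert signature_score(df, CDC1_SIGNATURE).tolist() == [0.0, 0.0]


def test_signature_score_mean_of_present_with_warning(caplog):
    sig = Signature("x", ("a", "b", "c"))
    df = pd.DataFrame({"a": [1.0], "b": [3.0]}, index=["s1"])
    with caplog.at_level("WARNING"):
        scores = signature_score(df, sig)
    assert scores["s1"] == 2.0
    assert "c" in caplog.text


def test_signature_score_no_genes_error():
    sig = Signature("x", ("zz",))
    with pytest.raises(DegenerateInputError):
        signature_score(pd.DataFrame({"a": [1.0]}), sig)


def test_signature_score_shift_linearity():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.normal(size=(5, 4)),
                      columns=list(CD8_EFFECTOR_SIGNATURE.genes))
    base = signature_score(df, CD8_EFFECTOR_SIGNATURE)
    shifted = signature_score(df + 2.5, CD8_EFFECTOR_SIGNATURE)
    assert np.allclose(shifted, base + 2.5)


def test_signature_score_ignores_extra_genes_and_order():
    sig = Signature("x", ("a", "b"))
    df1 = pd.DataFrame({"a": [1.0], "b": [2.0], "zz": [99.0]})
    df2 = pd.DataFrame({"b": [2.0], "a": [1.0]})
    assert signature_score(df1, sig)[0] == signature_score(df2, sig)[0] == 1.5


def test_signature_rejects_empty_and_duplicates():
    with pytest.raises(ValidationError):
        Signature("x", ())
    with pytest.raises(ValidationError):
        Signature("x", ("a", "a"))


# ---------------------------------------------------------------------------
# median split
# ---------------------------------------------------------------------------


def test_median_split_even():
    labels = median_split({"a": 1, "b": 2, "c": 3, "d": 4})  # median 2.5
    assert labels == {"a": "low", "b": "low", "c": "high", "d": "high"}


def test_median_split_ties_to_low():
    labels = median_split({"a": 1, "b": 2, "c": 2, "d": 3})  # median 2
    assert labels == {"a": "low", "b": "low", "c": "low", "d": "high"}


def test_median_split_ties_to_high_option():
    labels = median_split({"a": 1, "b": 2, "c": 2, "d": 3}, ties_to="high")
    assert labels == {"a": "low", "b": "high", "c": "high", "d": "high"}


def test_median_split_n2():
    assert median_split({"a": 1, "b": 9}) == {"a": "low", "b": "high"}


def test_median_split_degenerate_error():
    with pytest.raises(DegenerateInputError):
        median_split({"a": 2, "b": 2, "c": 2})


# ---------------------------------------------------------------------------
# quartile groups
# ---------------------------------------------------------------------------


def test_quartile_groups_1_to_8():
    g = quartile_groups({i: float(i) for i in range(1, 9)})
    # linear interpolation: Q1 = 2.75, Q3 = 6.25
    assert sorted(k for k, v in g.items() if v == "bottom") == [1, 2]
    assert sorted(k for k, v in g.items() if v == "top") == [7, 8]
    assert sorted(k for k, v in g.items() if v == "middle") == [3, 4, 5, 6]


def test_quartile_groups_all_equal_error():
    with pytest.raises(DegenerateInputError):
        quartile_groups({i: 1.0 for i in range(8)})


def test_quartile_groups_n_below_4_error():
    with pytest.raises(DegenerateInputError):
        quartile_groups({1: 1.0, 2: 2.0, 3: 3.0})


def test_quartile_bottom_top_disjoint_and_sized():
    rng = np.random.default_rng(1)
    for n in (8, 17, 100, 501):
        g = quartile_groups(dict(enumerate(rng.normal(size=n))))
        bottom = {k for k, v in g.items() if v == "bottom"}
        top = {k for k, v in g.items() if v == "top"}
        assert not bottom & top
        assert n // 4 <= len(bottom) <= n // 4 + 2
        assert n // 4 <= len(top) <= n // 4 + 2


# ---------------------------------------------------------------------------
# pearson
# ---------------------------------------------------------------------------


def test_pearson_perfect_positive():
    x = np.arange(10.0)
    r, p = pearson_r(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    assert p < 1e-10


def test_pearson_perfect_negative():
    x = np.arange(10.0)
    r, _ = pearson_r(x, -x)
    assert r == pytest.approx(-1.0)


def test_pearson_independent_near_zero():
    rng = np.random.default_rng(42)
    x, y = rng.standard_normal(10_000), rng.standard_normal(10_000)
    r, _ = pearson_r(x, y)
    assert abs(r) < 0.05


def test_pearson_zero_variance_error():
    with pytest.raises(DegenerateInputError):
        pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_pearson_matches_t_transform():
    rng = np.random.default_rng(3)
    x, y = rng.normal(size=30), rng.normal(size=30)
    r, p = pearson_r(x, y)
    from scipy import stats as sps

    t = r * np.sqrt(28 / (1 - r ** 2))
    assert p == pytest.approx(2 * sps.t.sf(abs(t), df=28), rel=1e-9)


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------


def test_logrank_identical_groups():
    g = [(1.0, 1), (2.0, 1), (3.0, 0)]
    chi2, p = logrank_test(g, g)
    assert chi2 == 0.0
    assert p == 1.0


def test_logrank_complete_separation():
    a = [(1.0, 1)] * 20
    b = [(10.0, 1)] * 20
    chi2, p = logrank_test(a, b)
    assert p < 0.001
    r = lifelines_logrank([1.0] * 20, [10.0] * 20,
                          event_observed_A=[1] * 20, event_observed_B=[1] * 20)
    assert chi2 == pytest.approx(r.test_statistic, rel=1e-9)


def test_logrank_symmetric_under_swap():
    rng = np.random.default_rng(5)
    a = [(t, int(e)) for t, e in zip(rng.exponential(5, 30),
                                     rng.integers(0, 2, 30))]
    b = [(t, int(e)) for t, e in zip(rng.exponential(9, 30),
                                     rng.integers(0, 2, 30))]
    assert logrank_test(a, b)[0] == pytest.approx(logrank_test(b, a)[0])


def test_logrank_matches_lifelines_with_ties_and_censoring():
    rng = np.random.default_rng(6)
    ta = np.round(rng.exponential(5, 40), 0) + 1
    tb = np.round(rng.exponential(8, 40), 0) + 1
    ea = rng.integers(0, 2, 40)
    eb = rng.integers(0, 2, 40)
    chi2, p = logrank_test(list(zip(ta, ea)), list(zip(tb, eb)))
    r = lifelines_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    assert chi2 == pytest.approx(r.test_statistic, rel=1e-9)
    assert p == pytest.approx(r.p_value, rel=1e-9)


def test_logrank_no_events_error():
    with pytest.raises(DegenerateInputError):
        logrank_test([(1.0, 0)], [(2.0, 0)])


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


def test_km_single_subject_event():
    km = km_curve([5.0], [1])
    assert km(4.9) == 1.0
    assert km(5.0) == 0.0


def test_km_all_censored():
    km = km_curve([1.0, 2.0, 3.0], [0, 0, 0])
    assert km(10.0) == 1.0


def test_km_four_subject_hand_example():
    km = km_curve([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 0])
    assert km(0.5) == 1.0
    assert km(1.0) == pytest.approx(0.75)
    assert km(2.0) == pytest.approx(0.5)
    assert km(100.0) == pytest.approx(0.5)  # plateau


def test_km_negative_times_error():
    with pytest.raises(ValidationError):
        km_curve([-1.0], [1])


def test_km_matches_lifelines():
    rng = np.random.default_rng(7)
    t = rng.exponential(5, 50)
    e = rng.integers(0, 2, 50)
    km = km_curve(t, e)
    fitter = KaplanMeierFitter().fit(t, e)
    for q in np.quantile(t, [0.1, 0.5, 0.9]):
        assert km(q) == pytest.approx(
            float(fitter.predict(q)), abs=1e-9)


# ---------------------------------------------------------------------------
# tumor volume
# ---------------------------------------------------------------------------


def test_tumor_volume_formula():
    assert tumor_volume(TumorMeasurement(2, 3)) == 6.0


def test_tumor_volume_degenerate_sphere():
    assert tumor_volume(TumorMeasurement(2, 2)) == 4.0


def test_tumor_volume_cubic_scaling():
    v1 = tumor_volume(TumorMeasurement(1.5, 2.5))
    v2 = tumor_volume(TumorMeasurement(3.0, 5.0))
    assert v2 == pytest.approx(8 * v1)


def test_tumor_volume_minor_exceeds_major_error():
    with pytest.raises(ValidationError):
        TumorMeasurement(3, 2)
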